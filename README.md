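# samdyn

Cell-population dynamics of the *Arabidopsis thaliana* shoot apical meristem
(SAM), with the quantification statistics used on segmented live-imaging data
and the genomic interval procedures used in transcription-factor
binding-site proximity analysis.

The package is aimed at plant developmental biologists and modellers who
want to (i) simulate and fit a compartmental model of stem-cell homeostasis
and lateral-organ initiation, (ii) compute reporter-domain, cell-age and
mitotic-index statistics from segmented nuclei tables, and (iii) quantify
motif co-occurrence (G-box vs auxin-response elements) around binding peaks.

## The model

Per cell layer, the SAM is partitioned into the central zone (CZ, slowly
dividing stem cells, `C`), the peripheral zone (PZ, transit-amplifying
cells, `P`) and a variable number of unseparated organ primordia `p_i`:

```
dC/dt   = r_C C − δ(C) C           δ(C) = s·r_C (C/C*)^m   (CZ→PZ exit)
dP/dt   = r_P P + δ(C) C − g P
dp_i/dt = r_prim p_i
```

with `r_X = ln2 / T_X`. Two kinds of discrete events punctuate the flow:
**initiation** — when the running integral of the initiation rate
`λ(C) = λ_ref · C/C_ref` crosses its next threshold, a new primordium is
created with `n0` cells recruited from the PZ (deterministic clock by
default, seeded Poisson optionally) — and **separation** — each primordium
leaves the meristem exactly `τ_sep` hours after initiation. The power-law
exit feedback makes `C*` a globally stable fixed point, so the calibrated
meristem settles into a unique state of balanced proliferation, organ
formation and separation.

Calibration: initiation 2.3 events/day, CZ doubling 39.8 h, PZ doubling
18.3 h, separation 2.2 days. The loss-of-function parameterisation of the
*hec1,2,3* mutant combines a 1.5-fold faster CZ exit (encoded as a smaller
homeostatic CZ), a 15% higher initiation rate and a separation delay
shortened from 52 h to 42 h. See `docs/methods.md` for every modelling
choice and its rationale.

## Worked example

Simulate the calibrated wild type for ten days and print the five
observables (cells per single layer; multiply by 3 for whole-SAM counts):

```
$ samdyn simulate --scenario calibration-wt --t-end 240 --dt-out 48 \
      --seed 0 --out wt
$ head -4 wt.trajectory.tsv
time_h  cz_cells  total_cells  cz_ratio      n_unseparated  organs_cum
0       40        200          0.2           0              0
48      40        202.2297752  0.1977948102  4              0
96      40        200.4626501  0.1995384177  5              4
```

The CZ holds at its homeostatic 40 cells, total SAM size breathes around
200 cells as primordia recruit cells and separate, about five unseparated
primordia are active at any time (initiation rate × residence time,
2.3/day × 2.2 days ≈ 5.1), and the first organs separate after ~2.2 days.

The promoter-enrichment arithmetic for a bound gene set — 23 of 25
auxin-signalling promoters bound, out of 5,250 bound genes in a
27,000-gene universe:

```
$ samdyn proximity enrich --k 23 --n 25 --big-k 5250 --big-n 27000
p_value	8.39753e-15
```

From Python, the same objects compose directly:

```python
import numpy as np, samdyn as sd

obs = sd.gen_observed_series("hec-lof-final", times=np.arange(13.0),
                             noise_cv=0.0)[0]
res = sd.fit(obs, ("lambda_ref", "tau_sep"),
             bounds=[(0.5, 6.0), (20.0, 80.0)], start=[2.3, 52.0],
             seed=1, fixed_params=sd.scenario_parameters("hec-lof-final"),
             init=sd.ModelState(C=40.0, P=160.0))
print(res.as_dict())   # {'lambda_ref': 2.645, 'tau_sep': 41.6}
```

## Acceptance script

`scripts/acceptance.py` recomputes the pipeline's headline quantities from
scratch: the realized initiation slope and mean separation age of a 60-day
calibrated wild-type run, the separation delay and initiation-rate increase
recovered by least squares from synthetic mutant observations, and the
realized CZ doubling time in the pure-proliferation limit.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It runs in under a minute on one CPU and writes one JSON entry per
quantity with the value and the problem size used.
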
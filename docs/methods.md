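# Methods

## The cell-population model

The shoot apical meristem (SAM) is modelled per cell layer as three coupled
pools: central-zone stem cells `C`, peripheral-zone transit-amplifying cells
`P`, and a time-varying set of unseparated organ primordia `p_i`. Whole-SAM
quantifications are three cell layers; all model numbers are single-layer
and are compared to quantified counts divided by 3.

Continuous dynamics between events:

```
dC/dt   = r_C C − δ(C) C + ρ P
dP/dt   = r_P P + δ(C) C − g P − ρ P
dp_i/dt = r_prim p_i
dE/dt   = g P                      (export to longitudinal stem growth)
```

`r_X = ln 2 / T_X` are per-cell proliferation rates. `ρ` (PZ→CZ
re-specification back-flux) is zero except in the rejected
`gof-respecification` scenario.

Discrete events:

* **Initiation.** The clock `dχ/dt = λ(C)/24` accumulates the initiation
  rate (per day → per hour). When it crosses its next threshold — successive
  integers in the default deterministic mode, cumulative unit-exponential
  increments in the seeded Poisson mode — a primordium is created with `n0`
  cells moved from the PZ. If the PZ holds fewer than `n0` cells the
  available cells are recruited and a warning is logged; robustness sweeps
  stay runnable.
* **Separation.** Exactly `τ_sep` hours after initiation a primordium
  leaves the active set and the cumulative organ count increments.
  Separation times are known a priori, so they are hit exactly by ending
  integration segments there; initiation times are located by the
  integrator's root finder.

### Feedback closures

The two feedbacks are only qualitatively constrained by the biology (both
the CZ→PZ exit and the initiation frequency increase with CZ size), so
their functional forms are package choices, each swappable behind its
accessor:

* Exit: `δ(C) = s · r_C (C/C*)^m` with `m = 2` and switch `s = 1`.
  `δ(C*) = r_C` makes `C*` a fixed point; the linearised decay rate is
  `−m r_C`, so the fixed point is stable for any `m > 0` and the CZ relaxes
  with a ~29 h time constant at calibration.
* Initiation: `λ(C) = λ_ref · C / C_ref`, the simplest form consistent with
  larger meristems initiating proportionally more organs.

`C_ref` defaults to *track* `C*`, which makes `λ_ref` the realised
homeostatic initiation rate. Consequently, scenario modifiers that change
the exit rate are encoded as replacements of the homeostatic CZ size
(`k`-fold faster exit ↦ `C* → C*·k^(−1/m)`, the identical change of `δ` at
any fixed `C`). This keeps the two experimentally anchored quantities —
the realised initiation rate and the realised CZ size — independently
controllable: the mutant scenario has a smaller CZ *and* a 15% higher
realised initiation rate, as measured. Had `C_ref` been pinned to the
wild-type value, the same exit increase would have silently depressed the
realised initiation by ~6% and no parameterisation matching both
observations would exist. A separate multiplier `exit_scale` switches the
exit off entirely for analytic-limit experiments.

### Parameters, units, defaults

| name | meaning | default | provenance |
|---|---|---|---|
| `T_C` | CZ doubling time (h) | 39.8 | calibration |
| `T_P` | PZ doubling time (h) | 18.3 | calibration |
| `T_prim` | primordium doubling time (h) | = `T_P` | not reported; primordia are young PZ-derived tissue |
| `C_star` | homeostatic CZ cells/layer | 40 | chosen once: whole-SAM ≈ 600 cells, CZ/total ≈ 0.2, three layers |
| `P_star` | PZ cells/layer used to close `g` | 160 | same reasoning |
| `m` | exit-feedback exponent | 2 | any m>0 stabilises `C*`; 2 gives a days-scale relaxation |
| `lambda_ref` | initiation rate (events/day) | 2.3 | calibration |
| `tau_sep` | initiation→separation delay (h) | 52.8 (2.2 d) | calibration; 52 in the wild-type fit, 42 in the mutant |
| `n0` | cells recruited per initiation | 4 | not reported; a few-cell incipient primordium |
| `g` | PZ export rate (1/h) | closed | steady-state balance, below |
| `layer_factor` | layers per quantified SAM | 3 | fixed |

`g` is closed so that the total cell number is stationary at calibration:
`g = r_P + (r_C C* − (λ_ref/24)·n0)/P*`. The closure is evaluated once on
the *base* parameters and the resulting number is held fixed under scenario
modification — re-closing per scenario would re-stationarise the PZ under
every perturbation and erase exactly the growth phenotypes the
gain-of-function scenarios are meant to show.

### Numerics

Adaptive RK45 between events, `rtol 1e-8`, `atol 1e-10`; event roots from
the integrator's Brent solver; observables sampled from the dense
interpolant of the enclosing segment. Organ counters are right-continuous
step functions of the event times (a primordium counts from the instant of
initiation). The pure-exponential limit is reproduced to <1e-6 relative
over ten doublings; mass bookkeeping (initial + proliferated = live +
exported + separated) closes to integrator tolerance.

## Scenarios

`calibration-wt` is the base. The mutant candidates scale the exit 1.5-fold
(`hec-lof-A` also shortens separation to 42 h; `hec-lof-B` also raises
initiation 15%; `hec-lof-final` does both and is the accepted
parameterisation). The gain-of-function set slows the exit 1.5-fold
(`gof-delay-only`), speeds PZ proliferation 1.1-fold
(`gof-proliferation-only`), combines both (`gof-cz`, accepted) or adds a
PZ→CZ back-flux of 0.005/h (`gof-respecification`). The unreported fold
changes (1.5, 1.1, 0.005/h) are package choices exposed in the registry;
analyses anchored to reported numbers do not depend on them. Scenario runs
start from the wild-type homeostatic state: they are perturbation
experiments on a calibrated meristem.

## Least-squares fitting

Loss: sum over observables and time points of squared residuals, each
observable divided by its mean absolute observed value so that counts
(~hundreds) and ratios (~0.2) weigh comparably. Optimiser: bounded
Nelder-Mead with five seeded multi-starts (the loss is piecewise smooth —
event counts change along the way — so derivative-free local search with
restarts is appropriate).

### Identifiability of the separation delay

The CZ trajectory is independent of `λ_ref` and `τ_sep`, and the total cell
count is independent of `τ_sep`; the delay is identified solely through the
integer organ counters at the observation times. Those counters change only
when a separation crosses an observation time, so with daily observations
over 12 days the loss is *exactly flat* in `τ_sep` over an interval of
roughly ±0.7 h around the truth. The fitter therefore refines each fitted
parameter to the midpoint of its flat-loss plateau (geometric edge search
plus bisection). With daily sampling this pins the delay to ~1%; a derived
quantity like the 10-h wild-type−mutant delay difference inherits the full
plateau width (~±7% of 10 h) and cannot be resolved better at that
sampling. Denser or irregular observation schedules shrink the plateau
(the irregular-schedule recovery test reaches 0.02%).

## Synthetic data

* **Observed series** — scenario trajectories with independent
  multiplicative log-normal noise of mean 1 (counts are positive and spread
  grows with the mean); CV defaults to 0.05, a typical few-percent
  quantification repeatability, and is swept in the recovery tests. Organ
  counts are re-integerised and made monotone after noising.
* **Nuclei tables** — L1 centroids area-uniform on a spherical cap (radius
  30 µm, half-angle 66.8° ≈ a 35 µm geodesic summit), two sub-epidermal
  shells 5 and 10 µm deeper; planted central/peripheral identity at the
  0.33·r rule, a CLV3-high disc (intensities 100 vs 10, straddling the 35%
  rule), and timer classes drawn per domain (Class-4 fractions 0.05
  centrally, 0.20 peripherally, echoing centre-vs-periphery division
  frequencies). This is a sampling stand-in: no cell packing, no wall
  geometry, no optical artefacts — green tests establish that the
  statistics recover planted truth, not that segmentation works.
* **Genome fixtures** — two 1.5 Mb chromosomes; open chromatin as regular
  blocks at 40% coverage; G-box/ARE pairs planted inside open blocks with
  gaps ~N(30, 10) under 200-bp peaks and ~N(420, 30) on the background
  (both means sit mid-bin for the 50-bp distance histograms); a 74.5% share
  of peaks gets a gene TSS placed so the peak falls in its 3-kb upstream
  window, the rest get decoy genes whose windows avoid all peaks. Ground
  truth (gaps, upstream labels, promoter counts) is emitted alongside.

## Statistical conventions

* "Higher than 35% of the maximum" (CLV3) and "higher than one quarter of
  the maximum" (profile domain size) are strict inequalities.
* Timer blue/green ratios are normalised by the sample maximum; class bins
  are lower-inclusive, `[0, 0.3) [0.3, 0.53) [0.53, 0.76) [0.76, 1]`.
* The summit sphere is fitted algebraically (linear least squares on
  `2x·c + (r²−|c|²) = |x|²`); central means distance-to-centre-point
  strictly below 0.33·r.
* Plastochron: emergence times by linear interpolation of integer crossings
  of the cumulative count; the mean interval telescopes to
  `(t_last − t_first)/(N−1)`.
* Hedges' g uses the pooled SD and the small-sample correction
  `J = 1 − 3/(4(n1+n2) − 9)`.
* Genomic coordinates are 0-based half-open throughout; motif distances are
  edge-to-edge gaps with 0 for overlap; "upstream" is strand-aware,
  `[TSS−3000, TSS)` on plus, `(TSS, TSS+3000]` on minus; the upper-tail
  hypergeometric p-value is accumulated in log space.
* Shared binding between two summit sets uses 50-bp summit windows and an
  ≥80% overlap rule, i.e. summit distance ≤ 10 bp for equal windows.

## Known limitations

* The model is compartmental: no tissue geometry, no phyllotaxis, no
  mechanics, no explicit WUS/CLV3 or hormone fields — those act through the
  two feedback closures.
* Whether the primordium cell counts should feed back on the meristem is
  unknown; here they are pure bookkeeping.
* The effect-size checks against the deposited SAM-size measurements
  require that table locally (`data/sam_size_source_data.csv`); the
  repository does not bundle it, so that check reports its requirement and
  fails offline.
* Sequencing-scale binding statistics (peak counts, bound-gene counts,
  genome-wide annotation fractions) depend on raw data and caller versions
  and are out of scope; the interval procedures are validated on planted
  fixtures instead.
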
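"""Seeded generators for every input the pipeline consumes.

Three families of fixtures:

* observed quantification series — model trajectories with multiplicative
  log-normal observation noise (counts are positive and their spread grows
  roughly with the mean);
* segmented-nuclei tables — L1 cells on a spherical cap with planted
  central/peripheral identity, CLV3 reporter intensity and fluorescent-timer
  age classes, plus sub-epidermal filler shells;
* genome fixtures — BED-style motif/peak/open-chromatin/gene sets with a
  planted short G-box↔ARE spacing under peaks and broad spacing on the
  background.

Every generator is bit-reproducible under a fixed seed and emits the ground
truth needed to score the downstream statistics without peeking at the
generator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import OBSERVABLES, ObservedSeries
from .scenarios import run_scenario

__all__ = [
    "gen_observed_series", "gen_nuclei_table",
    "GenomeFixtureConfig", "GenomeFixture", "gen_genome_fixture",
]


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def gen_observed_series(
    scenario: str = "calibration-wt",
    times=None,
    noise_cv: float = 0.05,
    n_replicates: int = 1,
    seed: int | None = None,
    observables=OBSERVABLES,
) -> list[ObservedSeries]:
    """Observed-quantification replicates for a scenario.

    Simulates the scenario once, samples the requested observables at
    ``times`` (days) and applies independent multiplicative log-normal noise
    with coefficient of variation ``noise_cv`` per point and replicate.
    Organ counts are rounded to integers and forced monotone afterwards,
    since cumulative counts cannot decrease.
    """
    times = np.arange(0.0, 13.0) if times is None else np.asarray(times, float)
    rng = np.random.default_rng(seed)
    res = run_scenario(scenario, t_end=float(times[-1] * 24.0) if times[-1] > 0
                       else 24.0, sample_times=times * 24.0, dt_out=None)
    traj = res.trajectory
    out = []
    for _ in range(n_replicates):
        values = {}
        for name in observables:
            clean = traj.observable(name).astype(float)
            noisy = clean * _lognormal_factors(rng, noise_cv, clean.shape)
            if name == "organs_cum":
                noisy = np.maximum.accumulate(np.round(noisy))
            elif name == "n_unseparated":
                noisy = np.maximum(np.round(noisy), 0.0)
            values[name] = noisy
        out.append(ObservedSeries(times=times.copy(), values=values))
    return out


def gen_nuclei_table(
    n_cells: int = 600,
    sphere_radius: float = 30.0,
    cap_halfangle_deg: float = 66.8,
    central_frac: float = 0.33,
    clv3_disc_frac: float = 0.30,
    clv3_high: float = 100.0,
    clv3_low: float = 10.0,
    class4_frac_central: float = 0.05,
    class4_frac_peripheral: float = 0.20,
    l1_frac: float = 0.55,
    intensity_jitter: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic segmented-nuclei table of a SAM summit.

    L1 nuclei sit area-uniformly on a spherical cap of the given radius
    (apex at (0, 0, sphere_radius), sphere centred at the origin); deeper
    nuclei fill two sub-epidermal shells.  Planted ground truth:

    * ``true_domain`` — central iff distance to the apex point is strictly
      below ``central_frac * sphere_radius``;
    * ``true_clv3`` — CLV3 intensity ``clv3_high`` inside a central disc
      covering ``clv3_disc_frac`` of the cap's geodesic radius, ``clv3_low``
      outside (10 < 35%% of 100, so the disc is exactly the positive set);
    * ``true_class`` — fluorescent-timer class drawn per domain so that the
      Class-4 (recently divided) fraction is ``class4_frac_central`` centrally
      and ``class4_frac_peripheral`` peripherally.

    This is a sampling stand-in for a segmented meristem, not a
    morphological model.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if not 0 < cap_halfangle_deg < 90:
        raise ValueError("cap_halfangle_deg must be in (0, 90)")
    rng = np.random.default_rng(seed)
    alpha = math.radians(cap_halfangle_deg)
    r = sphere_radius
    apex = np.array([0.0, 0.0, r])

    n_l1 = max(10, int(round(n_cells * l1_frac)))
    n_inner = n_cells - n_l1
    # area-uniform cap sampling: cos(theta) uniform on [cos(alpha), 1]
    def sample_shell(n, radius):
        cos_t = rng.uniform(math.cos(alpha), 1.0, size=n)
        theta = np.arccos(cos_t)
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        return np.column_stack([
            radius * np.sin(theta) * np.cos(phi),
            radius * np.sin(theta) * np.sin(phi),
            radius * np.cos(theta),
        ])

    pts_l1 = sample_shell(n_l1, r)
    layers = ["L1"] * n_l1
    inner_pts = []
    if n_inner > 0:
        half = n_inner // 2
        inner_pts.append(sample_shell(half, r - 5.0))
        inner_pts.append(sample_shell(n_inner - half, r - 10.0))
        layers += ["L2"] * half + ["L3"] * (n_inner - half)
    pts = np.vstack([pts_l1] + inner_pts) if inner_pts else pts_l1

    dist_apex = np.linalg.norm(pts - apex, axis=1)
    central = dist_apex < central_frac * r

    in_disc = dist_apex < clv3_disc_frac * r
    clv3 = np.where(in_disc, clv3_high, clv3_low).astype(float)

    cls = np.empty(len(pts), dtype=int)
    for mask, frac4 in ((central, class4_frac_central),
                        (~central, class4_frac_peripheral)):
        n = int(mask.sum())
        young = rng.random(n) < frac4
        old = rng.integers(1, 4, size=n)          # classes 1..3 for the rest
        cls[mask] = np.where(young, 4, old)
    # normalised-ratio targets at bin midpoints; the sample maximum sits in
    # class 4 so normalisation maps the midpoints into their own bins
    mid = {1: 0.15, 2: 0.415, 3: 0.645, 4: 1.0}
    green = np.full(len(pts), 1000.0)
    ratio = np.array([mid[c] for c in cls])
    if intensity_jitter > 0:
        ratio = np.clip(ratio * _lognormal_factors(rng, intensity_jitter,
                                                   len(ratio)), 0.0, None)
        clv3 = clv3 * _lognormal_factors(rng, intensity_jitter, len(clv3))
    blue = ratio * green

    return pd.DataFrame({
        "id": np.arange(len(pts)),
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        "layer": layers,
        "clv3": clv3,
        "timer_blue": blue,
        "timer_green": green,
        "true_domain": np.where(central, "central", "peripheral"),
        "true_clv3": in_disc,
        "true_class": cls,
    })


@dataclass
class GenomeFixtureConfig:
    """Planted genome-fixture layout (sizes in bp)."""
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_500_000,
                                                         "chr2": 1_500_000})
    n_peak_pairs: int = 150          # G-box/ARE pairs under peaks
    n_background_pairs: int = 300    # pairs on the genomic background
    peak_spacing_mean: float = 30.0  # bp, planted under-peak gap
    peak_spacing_sd: float = 10.0
    background_spacing_mean: float = 420.0   # mid-bin: modal bin [400, 450)
    background_spacing_sd: float = 30.0
    motif_len: int = 6
    open_coverage: float = 0.4       # fraction of the genome that is open
    n_genes: int = 200
    upstream_frac: float = 0.745     # peaks planted within 3 kb upstream
    upstream_window: int = 3000


@dataclass
class GenomeFixture:
    gbox: pd.DataFrame
    are: pd.DataFrame
    open_chromatin: pd.DataFrame
    peaks: pd.DataFrame
    genes: pd.DataFrame
    truth: dict

    def frames(self) -> dict:
        return {"gbox": self.gbox, "are": self.are,
                "open_chromatin": self.open_chromatin,
                "peaks": self.peaks, "genes": self.genes}


def gen_genome_fixture(
    config: GenomeFixtureConfig | None = None,
    seed: int | None = None,
) -> GenomeFixture:
    """Planted BED fixture for the motif-proximity operations.

    Open chromatin is laid out as regular blocks covering ``open_coverage``
    of each chromosome.  G-box/ARE pairs with short planted gaps are placed
    inside open blocks and covered by a 200 bp peak (summit at the pair
    midpoint); background pairs with broad gaps go into other open blocks.
    A ``upstream_frac`` share of the peaks gets a gene TSS placed so that
    the peak falls within the 3 kb upstream window; the rest are left distal.
    Raises when the requested content cannot be placed without overlap.
    """
    cfg = GenomeFixtureConfig() if config is None else config
    rng = np.random.default_rng(seed)
    if not 0 < cfg.open_coverage <= 1:
        raise ValueError("open_coverage must be in (0, 1]")

    # open blocks: period 5000 bp, open prefix of each period
    period = 5000
    block = int(period * cfg.open_coverage)
    slot = 2000                      # bp reserved per planted pair
    open_rows, slots = [], []
    for chrom, length in cfg.chrom_lengths.items():
        for s in range(0, length - period, period):
            open_rows.append((chrom, s, s + block))
            # the first period of each chromosome carries no planted pair so
            # that distal decoy-gene windows (placed left of a peak) never
            # run off the chromosome start
            if block >= slot and s > 0:
                for k in range(block // slot):
                    slots.append((chrom, s + k * slot))
    open_df = pd.DataFrame(open_rows, columns=["chrom", "start", "end"])

    n_need = cfg.n_peak_pairs + cfg.n_background_pairs
    if n_need > len(slots):
        raise ValueError(
            f"overcrowded planting: {n_need} pairs requested but only "
            f"{len(slots)} open slots available")
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[:n_need]]

    def plant(pairs, mean, sd):
        g_rows, a_rows, gaps = [], [], []
        for chrom, base in pairs:
            gap = max(0, int(round(rng.normal(mean, sd))))
            gap = min(gap, slot - 2 * cfg.motif_len - 300)
            # offset 150 keeps the 200 bp peak around the pair midpoint
            # non-negative even in the first block of a chromosome
            g_start = base + 150
            a_start = g_start + cfg.motif_len + gap
            g_rows.append((chrom, g_start, g_start + cfg.motif_len))
            a_rows.append((chrom, a_start, a_start + cfg.motif_len))
            gaps.append(gap)
        return g_rows, a_rows, gaps

    gp, ap, peak_gaps = plant(chosen[:cfg.n_peak_pairs],
                              cfg.peak_spacing_mean, cfg.peak_spacing_sd)
    gb, ab, bg_gaps = plant(chosen[cfg.n_peak_pairs:],
                            cfg.background_spacing_mean,
                            cfg.background_spacing_sd)
    gbox = pd.DataFrame(gp + gb, columns=["chrom", "start", "end"])
    are = pd.DataFrame(ap + ab, columns=["chrom", "start", "end"])

    peaks_rows = []
    for (chrom, g_start, _), (_, _, a_end) in zip(gp, ap):
        mid = (g_start + a_end) // 2
        peaks_rows.append((chrom, mid - 100, mid + 100, mid))
    peaks = pd.DataFrame(peaks_rows,
                         columns=["chrom", "start", "end", "summit"])

    # gene models: a planted fraction of peaks upstream of a TSS
    n_up = int(round(cfg.upstream_frac * len(peaks)))
    upstream_label = np.zeros(len(peaks), dtype=bool)
    upstream_label[rng.permutation(len(peaks))[:n_up]] = True
    gene_rows = []
    for i, row in enumerate(peaks.itertuples(index=False)):
        strand = "+" if rng.random() < 0.5 else "-"
        if upstream_label[i]:
            offset = int(rng.integers(200, cfg.upstream_window - 300))
            tss = row.end + offset if strand == "+" else row.start - offset
            if tss < 0:
                strand, tss = "+", row.end + offset
        else:
            # decoy gene whose upstream window fills the empty band just
            # left of its own peak, clear of every planted peak
            strand, tss = "+", row.start - 1000
        gene_rows.append((row.chrom, int(tss), strand, f"gene{i:04d}"))
    for j in range(len(peaks), cfg.n_genes):      # distal filler genes
        chrom = list(cfg.chrom_lengths)[int(rng.integers(len(cfg.chrom_lengths)))]
        # park filler TSS at period ends on the + strand: their upstream
        # windows cover the closed tail of their own period, clear of the
        # peak-bearing open blocks at period starts
        pos = int(rng.integers(0, cfg.chrom_lengths[chrom] // period - 1)) \
            * period + period - 10
        gene_rows.append((chrom, pos, "+", f"gene{j:04d}"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "strand", "name"])

    truth = {
        "peak_gaps": np.asarray(peak_gaps),
        "background_gaps": np.asarray(bg_gaps),
        "peak_upstream_label": upstream_label,
        "upstream_fraction": float(upstream_label.mean()),
        # the promoter-enrichment arithmetic of the bound-gene analysis
        "promoter_counts": {"k_hits": 23, "n_draws": 25,
                            "K_marked": 5250, "N_universe": 27000},
    }
    return GenomeFixture(gbox, are, open_df, peaks, genes, truth)
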
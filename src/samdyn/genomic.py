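"""Interval procedures for motif/peak proximity analysis.

All coordinates are 0-based half-open (BED convention).  Interval sets are
plain pandas DataFrames with at least ``chrom``, ``start`` and ``end``
columns; peaks may carry a ``summit`` column (absolute position), gene
models a ``tss`` and ``strand`` column.

The procedures implemented here mirror a ChIP-seq post-processing workflow:
fixed-width summit regions, replicate intersection, shared-binding detection
between factors, closest-motif distances restricted to open chromatin,
the fraction of binding events within a fixed window upstream of
transcription start sites, and hypergeometric enrichment of bound gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "validate_intervals", "summit_regions", "intersect_replicates",
    "shared_binding", "closest_motif_distance", "distance_histogram_compare",
    "upstream_fraction", "hypergeometric_enrichment", "gap_distance",
]


def validate_intervals(df: pd.DataFrame, require_summit: bool = False) -> pd.DataFrame:
    """Check BED-style invariants; returns the frame unchanged."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"missing interval column {col!r}")
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"invalid interval(s) at rows {list(bad[:5])}: "
                         "need 0 <= start < end")
    if require_summit:
        if "summit" not in df.columns:
            raise ValueError("summit column required")
        missing = df.index[df["summit"].isna()]
        if len(missing):
            raise ValueError(f"missing summit at rows {list(missing[:5])}")
        off = df.index[(df["summit"] < df["start"]) | (df["summit"] >= df["end"])]
        if len(off):
            raise ValueError(f"summit outside interval at rows {list(off[:5])}")
    return df


def summit_regions(peaks: pd.DataFrame, halfwidth: int = 100) -> pd.DataFrame:
    """Fixed-width regions centred on peak summits ([summit-hw, summit+hw),
    clipped at the chromosome start)."""
    validate_intervals(peaks, require_summit=True)
    s = peaks["summit"].to_numpy(int)
    out = pd.DataFrame({
        "chrom": peaks["chrom"].to_numpy(),
        "start": np.maximum(0, s - halfwidth),
        "end": s + halfwidth,
    })
    return out


def _merge_sorted(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping or book-ended sorted intervals."""
    m_starts, m_ends = [], []
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:                       # overlap or book-ended
            cur_e = max(cur_e, e)
        else:
            m_starts.append(cur_s)
            m_ends.append(cur_e)
            cur_s, cur_e = s, e
    m_starts.append(cur_s)
    m_ends.append(cur_e)
    return np.asarray(m_starts), np.asarray(m_ends)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of an interval set, merged per chromosome (book-ended joined)."""
    validate_intervals(df)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        s, e = _merge_sorted(grp["start"].to_numpy(), grp["end"].to_numpy())
        rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    return pd.concat(rows, ignore_index=True)


def intersect_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Base-pair intersection of two replicate region sets.

    Equivalent to intersecting the merged unions of the two replicates;
    book-ended fragments are merged per locus.
    """
    a = merge_intervals(rep1)
    b = merge_intervals(rep2)
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a.loc[a["chrom"] == chrom]
        sb = b.loc[b["chrom"] == chrom]
        i = j = 0
        s1, e1 = sa["start"].to_numpy(), sa["end"].to_numpy()
        s2, e2 = sb["start"].to_numpy(), sb["end"].to_numpy()
        out_s, out_e = [], []
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if lo < hi:
                out_s.append(lo)
                out_e.append(hi)
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
        if out_s:
            ms, me = _merge_sorted(np.asarray(out_s), np.asarray(out_e))
            rows.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def shared_binding(
    summits_a: pd.DataFrame,
    summits_b: pd.DataFrame,
    window: int = 50,
    min_overlap_frac: float = 0.80,
) -> pd.Series:
    """Shared-binding flags for set A against set B.

    ``window``-bp regions are centred on every summit; a region of A is
    shared when some region of B overlaps it by at least
    ``min_overlap_frac * window`` bases.  For equal windows that is a summit
    distance of at most ``window - ceil(min_overlap_frac * window)`` bp.
    """
    validate_intervals(summits_a, require_summit=True)
    validate_intervals(summits_b, require_summit=True)
    max_dist = window - int(np.ceil(min_overlap_frac * window))
    flags = np.zeros(len(summits_a), dtype=bool)
    b_by_chrom = {c: np.sort(g["summit"].to_numpy(float))
                  for c, g in summits_b.groupby("chrom")}
    for pos, (idx, row) in zip(range(len(summits_a)), summits_a.iterrows()):
        arr = b_by_chrom.get(row["chrom"])
        if arr is None or len(arr) == 0:
            continue
        k = np.searchsorted(arr, row["summit"])
        near = min(
            abs(row["summit"] - arr[max(k - 1, 0)]),
            abs(row["summit"] - arr[min(k, len(arr) - 1)]),
        )
        flags[pos] = near <= max_dist
    return pd.Series(flags, index=summits_a.index)


def gap_distance(start_a, end_a, start_b, end_b) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 when overlapping."""
    if start_b >= end_a:
        return int(start_b - end_a)
    if start_a >= end_b:
        return int(start_a - end_b)
    return 0


def _overlaps_any(df: pd.DataFrame, open_regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask: interval overlaps at least one open-chromatin region."""
    merged = merge_intervals(open_regions)
    mask = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom"):
        reg = merged.loc[merged["chrom"] == chrom]
        if reg.empty:
            continue
        rs = reg["start"].to_numpy()
        re_ = reg["end"].to_numpy()
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        # merged regions are disjoint and sorted: the only candidate is the
        # last region starting before the interval's end
        k = np.searchsorted(rs, e, side="left") - 1
        ok = (k >= 0) & (re_[np.clip(k, 0, None)] > s)
        mask[df.index.get_indexer(grp.index)] = ok
    return mask


def closest_motif_distance(
    gboxes: pd.DataFrame,
    ares: pd.DataFrame,
    open_chromatin: pd.DataFrame,
) -> pd.Series:
    """Distance (bp) from each G-box to its nearest ARE in open chromatin.

    Motifs not overlapping open chromatin are discarded (G-boxes get a
    missing value; AREs are removed from the search set).  The distance is
    the edge-to-edge gap, 0 for overlapping motifs; G-boxes on chromosomes
    without any retained ARE get a missing value.
    """
    validate_intervals(gboxes)
    validate_intervals(ares)
    g_open = _overlaps_any(gboxes, open_chromatin)
    a_open = _overlaps_any(ares, open_chromatin)
    ares_kept = ares.loc[a_open]
    out = np.full(len(gboxes), np.nan)
    by_chrom = {}
    for chrom, grp in ares_kept.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(float)
        ends = grp["end"].to_numpy(float)
        by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends),
                           np.sort(ends))
    for pos, (idx, row) in enumerate(gboxes.iterrows()):
        if not g_open[pos]:
            continue
        entry = by_chrom.get(row["chrom"])
        if entry is None:
            continue
        starts, ends, prefix_max_end, ends_sorted = entry
        s, e = row["start"], row["end"]
        best = np.inf
        # overlap: some ARE starting before e reaches past s
        k = np.searchsorted(starts, e, side="left")
        if k > 0 and prefix_max_end[k - 1] > s:
            best = 0.0
        else:
            if k < len(starts):                       # nearest on the right
                best = min(best, starts[k] - e)
            j = np.searchsorted(ends_sorted, s, side="right")
            if j > 0:                                 # nearest on the left
                best = min(best, s - ends_sorted[j - 1])
        out[pos] = best if np.isfinite(best) else np.nan
    return pd.Series(out, index=gboxes.index)


def distance_histogram_compare(
    distances_under_peaks,
    distances_background,
    bin_width: int = 50,
) -> dict:
    """Normalised distance histograms with fixed bins [0,50), [50,100), ...

    Returns the bin edges, per-set frequencies and each set's modal bin.
    """
    d1 = np.asarray(distances_under_peaks, dtype=float)
    d2 = np.asarray(distances_background, dtype=float)
    d1 = d1[~np.isnan(d1)]
    d2 = d2[~np.isnan(d2)]
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("distance vectors must be non-empty")
    top = max(d1.max(), d2.max())
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    f1, _ = np.histogram(d1, bins=edges)
    f2, _ = np.histogram(d2, bins=edges)
    f1 = f1 / f1.sum()
    f2 = f2 / f2.sum()
    m1, m2 = int(np.argmax(f1)), int(np.argmax(f2))
    return {
        "bin_edges": edges,
        "freq_peaks": f1,
        "freq_background": f2,
        "modal_bin_peaks": (int(edges[m1]), int(edges[m1 + 1])),
        "modal_bin_background": (int(edges[m2]), int(edges[m2 + 1])),
    }


def upstream_fraction(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 3000,
) -> float:
    """Fraction of regions overlapping a window upstream of any TSS.

    The upstream window is [TSS - max_dist, TSS) for + strand genes and
    (TSS, TSS + max_dist] for - strand genes (half-open toward the gene);
    regions are unstranded.
    """
    validate_intervals(regions)
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    for col in ("chrom", "tss", "strand"):
        if col not in genes.columns:
            raise ValueError(f"gene models need column {col!r}")
    if not set(genes["strand"]) <= {"+", "-"}:
        raise ValueError("gene strand must be '+' or '-'")
    if max_dist == 0 or len(genes) == 0:
        return 0.0
    tss = genes["tss"].to_numpy(int)
    plus = (genes["strand"] == "+").to_numpy()
    up = pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": np.where(plus, np.maximum(0, tss - max_dist), tss + 1),
        "end": np.where(plus, tss, tss + max_dist + 1),
    })
    up = up.loc[up["start"] < up["end"]]
    counted = _overlaps_any(regions, up)
    return float(counted.sum() / len(regions))


def hypergeometric_enrichment(
    k_hits: int, n_draws: int, K_marked: int, N_universe: int
) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), computed in log space.

    X counts marked items among ``n_draws`` draws without replacement from a
    universe of ``N_universe`` items of which ``K_marked`` are marked.
    """
    k, n, K, N = int(k_hits), int(n_draws), int(K_marked), int(N_universe)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(n, K)):
        raise ValueError("need 0 <= k <= min(n, K)")
    if k == 0:
        return 1.0
    js = np.arange(k, min(n, K) + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(js, N, K, n))))
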
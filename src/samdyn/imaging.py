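"""Quantification statistics for segmented SAM nuclei and intensity profiles.

All operations consume already-segmented data: tables with one row per
nucleus (3D centroid, layer label, per-channel mean intensities) or 1D
intensity profiles along a line through the meristem centre.  No raw-image
processing happens here.

Conventions, as stated by the underlying quantification protocol:

* reporter *domain size* is the span of profile points whose intensity is
  strictly above one quarter of the profile maximum;
* a nucleus is *CLV3-positive* when its mean intensity is strictly above 35%
  of the maximum mean intensity in the sample;
* fluorescent-timer blue/green ratios are normalised to the sample maximum
  and binned into four age classes (lower-inclusive bins 0-0.3, 0.3-0.53,
  0.53-0.76, 0.76-1); Class 4 marks recently divided ("young") cells;
* the central/peripheral split fits a sphere through the L1 centroids of the
  meristem summit (<= 35 um from a chosen centre point P) and calls a cell
  central when its distance to P is strictly below 0.33 * fitted radius.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "domain_size", "clv3_positive", "timer_classes", "fit_sphere",
    "central_peripheral_split", "mitotic_index", "plastochron", "hedges_g",
    "TIMER_BIN_EDGES",
]

#: upper edges of timer classes 1..3 (class 4 is [0.76, 1])
TIMER_BIN_EDGES = (0.3, 0.53, 0.76)


def domain_size(positions, values) -> float:
    """Size of an expression domain from a 1D intensity profile, in microns.

    Returns the distance between the first and the last profile point whose
    intensity is strictly greater than max(values)/4.  A profile with no
    positive signal yields 0 with a warning.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape or positions.ndim != 1:
        raise ValueError("positions and values must be equal-length 1D arrays")
    if len(positions) < 2:
        raise ValueError("profile needs at least 2 points")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    vmax = values.max()
    if vmax <= 0:
        warnings.warn("profile has no positive signal; domain size 0",
                      RuntimeWarning)
        return 0.0
    above = values > vmax / 4.0
    idx = np.flatnonzero(above)
    return float(positions[idx[-1]] - positions[idx[0]])


def clv3_positive(table: pd.DataFrame, channel: str = "clv3"):
    """Flag CLV3-positive nuclei (mean intensity > 35% of the sample max).

    Returns ``(flags, count)`` where ``flags`` is a boolean Series aligned
    with the table index.
    """
    if channel not in table.columns:
        raise KeyError(
            f"channel {channel!r} not in table; available columns: "
            f"{list(table.columns)}")
    if len(table) == 0:
        raise ValueError("table must contain at least one nucleus")
    intensity = table[channel].to_numpy(float)
    if np.any(intensity < 0):
        raise ValueError("intensities must be >= 0")
    flags = pd.Series(intensity > 0.35 * intensity.max(), index=table.index)
    return flags, int(flags.sum())


def timer_classes(
    table: pd.DataFrame,
    blue: str = "timer_blue",
    green: str = "timer_green",
) -> pd.Series:
    """Assign each nucleus a fluorescent-timer age class in {1, 2, 3, 4}.

    The blue/green ratio is normalised by the sample maximum to [0, 1] and
    binned with lower-inclusive edges (0.53 falls in class 3, etc.).  Nuclei
    with non-positive green signal get a missing class and a warning instead
    of aborting the sample.
    """
    for col in (blue, green):
        if col not in table.columns:
            raise KeyError(f"channel {col!r} not in table")
    if len(table) == 0:
        raise ValueError("table must contain at least one nucleus")
    b = table[blue].to_numpy(float)
    g = table[green].to_numpy(float)
    bad = g <= 0
    if bad.all():
        raise ValueError("no nucleus has positive green signal")
    if bad.any():
        warnings.warn(f"{int(bad.sum())} nuclei with non-positive green "
                      "signal excluded from timer classification",
                      RuntimeWarning)
    ratio = np.full(len(table), np.nan)
    ratio[~bad] = b[~bad] / g[~bad]
    rmax = np.nanmax(ratio)
    if rmax <= 0:
        # degenerate all-zero blue: every ratio is 0 -> class 1
        norm = np.where(np.isnan(ratio), np.nan, 0.0)
    else:
        norm = ratio / rmax
    cls = np.full(len(table), np.nan)
    ok = ~np.isnan(norm)
    cls[ok] = np.digitize(norm[ok], TIMER_BIN_EDGES) + 1.0
    return pd.Series(cls, index=table.index).astype("Int64")


def fit_sphere(points: np.ndarray):
    """Algebraic least-squares sphere fit through 3D points.

    Solves ||x - c||^2 = r^2 as the linear system
    2 x.c + (r^2 - |c|^2) = |x|^2.  Returns ``(center, radius)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need at least 4 points of dimension 3")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("degenerate geometry: points are coplanar")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate geometry: non-positive fitted radius")
    return center, float(np.sqrt(r2))


def central_peripheral_split(
    table: pd.DataFrame,
    center,
    cap_radius_um: float = 35.0,
    frac: float = 0.33,
    layer_col: str = "layer",
    l1_label: str = "L1",
):
    """Label each nucleus central or peripheral.

    A sphere is fitted through the L1 centroids within ``cap_radius_um`` of
    the manually chosen centre point P; a nucleus is *central* iff its
    distance to P is strictly smaller than ``frac`` times the fitted radius.

    Returns ``(labels, radius)`` with ``labels`` a Series of
    'central'/'peripheral'.
    """
    for col in ("x", "y", "z"):
        if col not in table.columns:
            raise KeyError(f"missing coordinate column {col!r}")
    center = np.asarray(center, dtype=float)
    if center.shape != (3,):
        raise ValueError("center must be a 3D point")
    pts = table[["x", "y", "z"]].to_numpy(float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    dist_P = np.linalg.norm(pts - center, axis=1)
    summit = (table[layer_col].to_numpy() == l1_label) & (dist_P <= cap_radius_um)
    if summit.sum() < 4:
        raise ValueError("fewer than 4 L1 centroids within the summit cap")
    _, radius = fit_sphere(pts[summit])
    labels = np.where(dist_P < frac * radius, "central", "peripheral")
    return pd.Series(labels, index=table.index), radius


def mitotic_index(classes: pd.Series, labels: pd.Series, domain: str) -> float:
    """Fraction of Class-4 (recently divided) nuclei within a domain."""
    classes = pd.Series(classes)
    labels = pd.Series(labels)
    if len(classes) != len(labels):
        raise ValueError("classes and labels must be aligned")
    in_dom = (labels == domain) & classes.notna().to_numpy()
    n = int(in_dom.sum())
    if n == 0:
        raise ValueError(f"no classified nuclei in domain {domain!r}")
    return float((classes[in_dom] == 4).sum() / n)


def plastochron(times, counts) -> float:
    """Mean interval between successive organ emergences, in the time unit
    of ``times``.

    Emergence times are assigned by linear interpolation of the cumulative
    count at integer crossings; the plastochron is the mean of successive
    differences, i.e. (t_last - t_first) / (N - 1).
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times.shape != counts.shape or times.ndim != 1:
        raise ValueError("times and counts must be equal-length 1D arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(np.diff(counts) < 0):
        raise ValueError("cumulative counts must be non-decreasing")
    first = int(np.floor(counts[0]))
    last = int(np.floor(counts[-1]))
    ks = np.arange(first + 1, last + 1)
    if len(ks) < 2:
        raise ValueError("at least 2 organ emergences are required")
    emergence = np.empty(len(ks), dtype=float)
    for j, k in enumerate(ks):
        i = int(np.searchsorted(counts, k, side="left"))
        if i == 0:
            emergence[j] = times[0]
            continue
        c0, c1 = counts[i - 1], counts[i]
        t0, t1 = times[i - 1], times[i]
        emergence[j] = t0 + (k - c0) / (c1 - c0) * (t1 - t0)
    return float((emergence[-1] - emergence[0]) / (len(ks) - 1))


def hedges_g(group1, group2) -> float:
    """Hedges' g: bias-corrected standardised mean difference.

    g = J * (mean1 - mean2) / s_pooled with
    s_pooled^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2) and the
    small-sample correction J = 1 - 3 / (4 (n1 + n2) - 9).
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    s2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("pooled variance is zero")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(J * (x1.mean() - x2.mean()) / np.sqrt(s2))
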
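"""Least-squares estimation of SAM model parameters from observed series.

The loss is a scale-normalised sum of squares over any subset of the five
observables (CZ cells, total cells, CZ/total ratio, unseparated primordia,
cumulative organs), each observable divided by its mean absolute observed
value so that counts (~hundreds) and ratios (~0.2) contribute comparably.

Minimisation uses bounded Nelder-Mead with seeded multi-starts.  Because the
organ counters are integer-valued step functions of time, the loss can be
exactly flat over an interval of the separation delay when observations are
sparse in time; after convergence the fitter therefore locates the edges of
the flat region for each free parameter by bisection and reports the
midpoint of the plateau (see docs/methods.md, "Flat-plateau tie-break").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .model import ModelState, simulate
from .parameters import ModelParameters

__all__ = ["ObservedSeries", "FitResult", "objective", "fit",
           "robustness_sweep"]

logger = logging.getLogger(__name__)

OBSERVABLES = ("cz_cells", "total_cells", "cz_ratio",
               "n_unseparated", "organs_cum")

#: loss returned when a simulation fails inside the objective
PENALTY_LOSS = 1e12


@dataclass
class ObservedSeries:
    """Observed quantification time series.

    times are in days; ``values`` maps observable names to vectors aligned
    with ``times``; ``sigma`` optionally carries per-point uncertainties.
    """
    times: np.ndarray                       # days
    values: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.values:
            raise ValueError("at least one observable is required")
        clean = {}
        for name, vec in self.values.items():
            if name not in OBSERVABLES:
                raise ValueError(f"unknown observable {name!r}; "
                                 f"expected one of {OBSERVABLES}")
            vec = np.asarray(vec, dtype=float)
            if vec.shape != self.times.shape:
                raise ValueError(f"observable {name!r} not aligned with times")
            clean[name] = vec
        self.values = clean

    @property
    def times_h(self) -> np.ndarray:
        return self.times * 24.0


@dataclass
class FitResult:
    names: tuple[str, ...]
    values: np.ndarray
    loss: float
    converged: bool
    n_evaluations: int
    seed: int | None = None
    start_losses: tuple[float, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _params_with(base: ModelParameters, names, values) -> ModelParameters:
    return replace(base, **dict(zip(names, values)))


def objective(
    free_values,
    free_names,
    fixed_params: ModelParameters,
    observed: ObservedSeries,
    weights: dict[str, float] | None = None,
    init: ModelState | None = None,
    _counter: list | None = None,
) -> float:
    """Scale-normalised weighted least-squares loss.

    loss = sum over observables o of w_o * sum_t ((model - observed)/scale_o)^2
    with scale_o = mean(|observed_o|) (falling back to 1 for an all-zero
    series).  Simulation failures yield a large finite penalty and a log
    message rather than an exception, keeping optimisers runnable.
    """
    if _counter is not None:
        _counter[0] += 1
    try:
        params = _params_with(fixed_params, free_names, free_values)
        t_obs = observed.times_h
        t0 = 0.0 if init is None else init.t
        sample = t_obs
        if t_obs[0] > t0 + 1e-9:
            sample = np.concatenate(([t0], t_obs))
        res = simulate(params, init=init, t_end=float(t_obs[-1]),
                       sample_times=sample, dt_out=None)
        traj = res.trajectory
        sel = slice(1, None) if sample is not t_obs else slice(None)
        loss = 0.0
        for name, obs in observed.values.items():
            w = 1.0 if weights is None else weights.get(name, 1.0)
            if w == 0.0:
                continue
            scale = np.mean(np.abs(obs))
            if scale == 0.0:
                scale = 1.0
            model = traj.observable(name)[sel]
            loss += w * float(np.sum(((model - obs) / scale) ** 2))
        return loss
    except Exception as exc:          # noqa: BLE001 - penalty policy
        logger.warning("simulation failed inside objective (%s); "
                       "returning penalty", exc)
        return PENALTY_LOSS


def _plateau_midpoint(fun, x, idx, loss0, bounds, xtol):
    """Midpoint of the contiguous flat-loss interval through x[idx].

    Steps outward geometrically until the loss leaves the plateau (or a bound
    is hit), then bisects the edge to ``xtol``.  Returns x[idx] unchanged when
    no flat extent is detectable.
    """
    lo, hi = bounds[idx]
    tol = 1e-9 * (1.0 + abs(loss0))

    def on_plateau(v):
        xx = np.array(x, dtype=float)
        xx[idx] = v
        return fun(xx) <= loss0 + tol

    edges = []
    for sign in (-1.0, 1.0):
        step = max(xtol, 1e-4 * (hi - lo))
        inside = x[idx]
        outside = None
        while True:
            cand = x[idx] + sign * step
            cand = min(max(cand, lo), hi)
            if on_plateau(cand):
                inside = cand
                if cand in (lo, hi):
                    break
                step *= 2.0
            else:
                outside = cand
                break
        if outside is not None:
            while abs(outside - inside) > xtol:
                mid = 0.5 * (inside + outside)
                if on_plateau(mid):
                    inside = mid
                else:
                    outside = mid
        edges.append(inside)
    mid = 0.5 * (edges[0] + edges[1])
    return mid if on_plateau(mid) else x[idx]


def fit(
    observed: ObservedSeries,
    free_names,
    bounds,
    start,
    seed: int | None = None,
    fixed_params: ModelParameters | None = None,
    weights: dict[str, float] | None = None,
    init: ModelState | None = None,
    n_starts: int = 5,
    maxfev: int = 400,
    xatol: float = 1e-3,
    refine_plateau: bool = True,
) -> FitResult:
    """Bounded multi-start local minimisation of :func:`objective`.

    ``start`` is always the first start; ``n_starts - 1`` further starts are
    drawn uniformly from ``bounds`` with the given seed.  The best local
    optimum is refined by the flat-plateau midpoint rule.
    """
    free_names = tuple(free_names)
    bounds = [tuple(map(float, b)) for b in bounds]
    start = np.asarray(start, dtype=float)
    if len(bounds) != len(free_names) or start.shape != (len(free_names),):
        raise ValueError("free_names, bounds and start must align")
    for (lo, hi), s in zip(bounds, start):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be finite with lo < hi")
        if not (lo <= s <= hi):
            raise ValueError("start must lie within bounds")
    fixed_params = ModelParameters() if fixed_params is None else fixed_params

    counter = [0]

    def fun(x):
        return objective(x, free_names, fixed_params, observed,
                         weights=weights, init=init, _counter=counter)

    rng = np.random.default_rng(seed)
    starts = [start]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    start_losses = []
    for x0 in starts:
        res = minimize(fun, x0, method="Nelder-Mead", bounds=bounds,
                       options={"xatol": xatol, "fatol": 1e-12,
                                "maxfev": maxfev})
        start_losses.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res

    x = np.array(best.x, dtype=float)
    loss = float(best.fun)
    if refine_plateau and loss < PENALTY_LOSS:
        for idx in range(len(free_names)):
            x[idx] = _plateau_midpoint(fun, x, idx, loss, bounds,
                                       xtol=max(xatol, 1e-4))
        loss = float(fun(x))

    return FitResult(
        names=free_names, values=x, loss=loss,
        converged=bool(best.success and loss < PENALTY_LOSS),
        n_evaluations=counter[0], seed=seed,
        start_losses=tuple(start_losses),
    )


def robustness_sweep(
    params: ModelParameters,
    scale_grid=((0.5, 1.0, 2.0), (0.5, 1.0, 2.0)),
    t_end: float = 3600.0,
    drift_window_days: float = 10.0,
    drift_tol: float = 0.01,
    attractor_tol: float = 0.02,
) -> dict:
    """Convergence report over a grid of perturbed initial conditions.

    Initial C and P are scaled by each combination of the two factor lists;
    a run is *converged* when every continuous observable drifts by less than
    ``drift_tol`` (relative) over the final ``drift_window_days``.  The sweep
    also reports whether all converged runs share one attractor (terminal
    C, P and unseparated-primordium count within ``attractor_tol`` of each
    other).
    """
    c_scales, p_scales = scale_grid
    rows = []
    for sc in c_scales:
        for sp in p_scales:
            init = ModelState(C=params.C_star * sc, P=params.P_star * sp)
            res = simulate(params, init=init, t_end=t_end, dt_out=24.0)
            traj = res.trajectory
            win = traj.times >= t_end - drift_window_days * 24.0
            # the attractor is a limit cycle (each initiation recruits n0
            # cells out of the PZ), so drift is the change between the means
            # of the two halves of the final window, which cancels the
            # stationary sawtooth
            drift = 0.0
            for arr in (traj.C_t, traj.total_t):
                seg = arr[win]
                h = len(seg) // 2
                m1, m2 = np.mean(seg[:h]), np.mean(seg[h:])
                drift = max(drift, float(abs(m2 - m1) / np.mean(seg)))
            # steady-state values are final-window time averages: the
            # unseparated-primordium count is an integer staircase whose
            # instantaneous terminal value would alias the event phase
            a, b = t_end - drift_window_days * 24.0, t_end
            ninit = res.initiation_times
            nsep = res.separation_times
            n_integral = (np.maximum(0.0, b - np.maximum(a, ninit)).sum()
                          - np.maximum(0.0, b - np.maximum(a, nsep)).sum())
            rows.append({
                "c_scale": sc, "p_scale": sp,
                "terminal_C": float(np.mean(traj.C_t[win])),
                "terminal_P": float(np.mean(traj.total_t[win] - traj.C_t[win])),
                "terminal_n_unsep": float(n_integral / (b - a)),
                "drift": drift,
                "converged": bool(drift < drift_tol),
            })
    conv = [r for r in rows if r["converged"]]
    single = bool(conv)
    for key in ("terminal_C", "terminal_P", "terminal_n_unsep"):
        vals = np.array([r[key] for r in conv])
        if len(vals) and vals.mean() > 0:
            if np.ptp(vals) / vals.mean() > attractor_tol:
                single = False
        elif len(vals) and np.ptp(vals) > attractor_tol:
            single = False
    return {"grid": rows,
            "all_converged": all(r["converged"] for r in rows),
            "single_attractor": single}
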
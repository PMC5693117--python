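"""Event-driven ODE simulation of the SAM cell-population model.

Between events the system obeys

    dC/dt   = r_C*C - delta(C)*C + rho_back*P
    dP/dt   = r_P*P + delta(C)*C - g*P - rho_back*P
    dp_i/dt = r_prim * p_i                (each active primordium i)
    dE/dt   = g*P                         (export to longitudinal growth)
    dclock/dt = lambda(C)/24              (initiation clock, per hour)

Two kinds of discrete events interleave with the continuous dynamics:

* initiation — when the clock crosses its next threshold (successive integers
  in deterministic-clock mode; seeded unit-exponential increments in poisson
  mode) a new primordium is created with n0 cells recruited from the PZ;
* separation — a primordium is removed exactly tau_sep hours after its
  initiation and counted as a separated organ.

The dimension of the ODE system therefore varies in time.  Integration uses
an adaptive Runge-Kutta scheme (rtol 1e-8, atol 1e-10) restarted at every
event; initiation times are located by the integrator's root finder,
separation times are known exactly.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ModelParameters, exit_rate, initiation_rate

__all__ = [
    "PrimordiumRecord", "ModelState", "Trajectory", "SimulationResult",
    "rhs", "simulate", "homeostatic_state",
]


@dataclass
class PrimordiumRecord:
    """One incipient lateral organ: identity, initiation time, cell count."""
    id: int
    t_init: float          # hours
    p: float               # current cell count
    separated: bool = False
    t_sep: float | None = None


@dataclass
class ModelState:
    """Instantaneous model state (cell numbers per single layer)."""
    t: float = 0.0
    C: float = 40.0
    P: float = 160.0
    primordia: list[PrimordiumRecord] = field(default_factory=list)
    O_cum: int = 0          # separated organs
    E_cum: float = 0.0      # cells exported to longitudinal growth
    clock: float = 0.0      # accumulated initiation integral

    def validate(self) -> None:
        if self.C < 0 or self.P < 0:
            raise ValueError("cell numbers must be non-negative")
        if self.O_cum < 0:
            raise ValueError("O_cum must be non-negative")

    @property
    def n_unseparated(self) -> int:
        return len(self.primordia)

    @property
    def total(self) -> float:
        """Total SAM cells per layer (CZ + PZ; primordia counted separately)."""
        return self.C + self.P


@dataclass
class Trajectory:
    """The five observables of the model sampled on an output grid."""
    times: np.ndarray       # hours
    C_t: np.ndarray
    total_t: np.ndarray
    ratio_t: np.ndarray
    n_unsep_t: np.ndarray
    O_cum_t: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            "cz_cells": self.C_t,
            "total_cells": self.total_t,
            "cz_ratio": self.ratio_t,
            "n_unseparated": self.n_unsep_t,
            "organs_cum": self.O_cum_t,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            times=df["time_h"].to_numpy(float),
            C_t=df["cz_cells"].to_numpy(float),
            total_t=df["total_cells"].to_numpy(float),
            ratio_t=df["cz_ratio"].to_numpy(float),
            n_unsep_t=df["n_unseparated"].to_numpy(float),
            O_cum_t=df["organs_cum"].to_numpy(float),
        )

    def observable(self, name: str) -> np.ndarray:
        return {
            "cz_cells": self.C_t, "total_cells": self.total_t,
            "cz_ratio": self.ratio_t, "n_unseparated": self.n_unsep_t,
            "organs_cum": self.O_cum_t,
        }[name]


@dataclass
class SimulationResult:
    trajectory: Trajectory
    final_state: ModelState
    events: pd.DataFrame            # columns event, time_h, primordium_id
    conservation: dict              # bookkeeping totals

    @property
    def initiation_times(self) -> np.ndarray:
        ev = self.events
        return ev.loc[ev["event"] == "initiation", "time_h"].to_numpy(float)

    @property
    def separation_times(self) -> np.ndarray:
        ev = self.events
        return ev.loc[ev["event"] == "separation", "time_h"].to_numpy(float)


def homeostatic_state(params: ModelParameters) -> ModelState:
    """State with C and P at the calibrated homeostatic sizes, no primordia."""
    return ModelState(t=0.0, C=params.C_star, P=params.P_star)


def rhs(t: float, y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivatives of the continuous part of the state.

    Layout of ``y``: [C, P, E_cum, clock, B, p_1..p_k] where B is the running
    integral of all proliferation (used for mass bookkeeping only).
    Recruitment into primordia and organ separation are events, not flows.
    """
    C, P = y[0], y[1]
    C = max(C, 0.0)
    P = max(P, 0.0)
    prim = y[5:]
    d = exit_rate(C, params)
    back = params.rho_back * P
    dC = params.r_C * C - d * C + back
    dP = params.r_P * P + d * C - params.g_eff * P - back
    dE = params.g_eff * P
    dclock = initiation_rate(C, params) / 24.0
    dprim = params.r_prim * prim
    dB = params.r_C * C + params.r_P * P + params.r_prim * prim.sum()
    return np.concatenate(([dC, dP, dE, dclock, dB], dprim))


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, message: str, last_state: ModelState):
        super().__init__(message)
        self.last_state = last_state


def simulate(
    params: ModelParameters,
    init: ModelState | None = None,
    t_end: float = 1440.0,
    dt_out: float | None = 24.0,
    sample_times: np.ndarray | None = None,
    seed: int | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the model from ``init`` to ``t_end`` (hours).

    Parameters
    ----------
    params : ModelParameters
    init : ModelState, optional
        Defaults to the homeostatic state (C_star, P_star, no primordia).
    t_end : float
        Simulation horizon in hours (> initial time).
    dt_out : float, optional
        Output grid spacing in hours (ignored if ``sample_times`` given).
    sample_times : array, optional
        Explicit output times in hours (must lie in [t0, t_end]).
    seed : int, optional
        Only used in poisson initiation mode.

    Returns
    -------
    SimulationResult
        Trajectory on the output grid, final state, event log and a
        conservation/bookkeeping summary.

    Notes
    -----
    Continuous observables are sampled from the dense interpolant of the
    integration segment ending at (or after) the sample time; the organ
    counters n_unseparated and organs_cum are right-continuous step
    functions of the event times.
    """
    state = homeostatic_state(params) if init is None else init
    state.validate()
    t0 = state.t
    if t_end <= t0:
        raise ValueError("t_end must exceed the initial time")
    if sample_times is None:
        if dt_out is None or dt_out <= 0:
            raise ValueError("dt_out must be > 0")
        sample_times = np.arange(t0, t_end + 1e-9 * max(1.0, dt_out), dt_out)
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.ndim != 1 or np.any(np.diff(sample_times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if sample_times[0] < t0 - 1e-9 or sample_times[-1] > t_end + 1e-9:
        raise ValueError("sample_times must lie within [t0, t_end]")

    rng = np.random.default_rng(seed)
    deterministic = params.initiation_mode == "deterministic-clock"

    def next_threshold(clock_now: float) -> float:
        if deterministic:
            return np.floor(clock_now + 1e-12) + 1.0
        return clock_now + rng.exponential()

    # working copies -------------------------------------------------------
    active: list[PrimordiumRecord] = [
        PrimordiumRecord(pr.id, pr.t_init, pr.p) for pr in state.primordia
    ]
    sep_heap: list[tuple[float, int]] = []   # (separation time, index key)
    recs: dict[int, PrimordiumRecord] = {}
    next_id = max((pr.id for pr in active), default=-1) + 1
    for pr in active:
        recs[pr.id] = pr
        heapq.heappush(sep_heap, (pr.t_init + params.tau_sep, pr.id))

    y = np.concatenate((
        [state.C, state.P, state.E_cum, state.clock, 0.0],
        [pr.p for pr in active],
    ))
    order: list[int] = [pr.id for pr in active]   # id per slot of y[5:]
    t = t0
    threshold = next_threshold(y[3])

    init_times: list[float] = []
    sep_times: list[float] = []
    sep_cells_total = 0.0
    recruited_total = 0.0
    recruit_warned = False
    event_rows: list[tuple[str, float, int]] = []
    O_cum0 = state.O_cum
    C0_total = state.C + state.P + sum(pr.p for pr in active)

    # sampled continuous observables
    samp_C = np.empty_like(sample_times)
    samp_P = np.empty_like(sample_times)
    s_ptr = 0
    if sample_times[0] <= t0 + 1e-12:
        samp_C[0], samp_P[0] = y[0], y[1]
        s_ptr = 1

    def clock_event(ti, yi, *args):
        return yi[3] - threshold
    clock_event.terminal = True
    clock_event.direction = 1.0

    max_events = int(1e6)
    n_events = 0
    while t < t_end - 1e-12:
        t_sep_next = sep_heap[0][0] if sep_heap else np.inf
        t_stop = min(t_sep_next, t_end)
        if t_stop > t + 1e-13:
            sol = solve_ivp(
                rhs, (t, t_stop), y, args=(params,), method="RK45",
                events=clock_event, dense_output=True, rtol=rtol, atol=atol,
            )
            if not sol.success:
                last = _assemble_state(sol.t[-1], sol.y[:, -1], order, recs,
                                       O_cum0 + len(sep_times))
                raise IntegrationError(f"integrator failed: {sol.message}", last)
            t_new = sol.t[-1]
            # sample the dense interpolant on grid points inside (t, t_new]
            while s_ptr < len(sample_times) and sample_times[s_ptr] <= t_new + 1e-12:
                ys = sol.sol(min(sample_times[s_ptr], t_new))
                samp_C[s_ptr], samp_P[s_ptr] = ys[0], ys[1]
                s_ptr += 1
            y = sol.y[:, -1].copy()
            t = t_new
            fired_initiation = len(sol.t_events[0]) > 0
        else:
            fired_initiation = False

        if fired_initiation:
            n_events += 1
            recruit = min(y[1], params.n0)
            if recruit < params.n0 and not recruit_warned:
                warnings.warn(
                    f"PZ has only {y[1]:.3g} cells at initiation; recruiting "
                    f"{recruit:.3g} instead of n0={params.n0:g}",
                    RuntimeWarning,
                )
                recruit_warned = True
            y[1] -= recruit
            pr = PrimordiumRecord(next_id, t, recruit)
            recs[next_id] = pr
            order.append(next_id)
            y = np.append(y, recruit)
            heapq.heappush(sep_heap, (t + params.tau_sep, next_id))
            init_times.append(t)
            event_rows.append(("initiation", t, next_id))
            recruited_total += recruit
            next_id += 1
            threshold = next_threshold(y[3])
        elif sep_heap and abs(t - sep_heap[0][0]) <= 1e-9:
            n_events += 1
            _, pid = heapq.heappop(sep_heap)
            slot = order.index(pid)
            pr = recs[pid]
            pr.p = y[5 + slot]
            pr.separated = True
            pr.t_sep = t
            sep_cells_total += pr.p
            y = np.delete(y, 5 + slot)
            order.pop(slot)
            sep_times.append(t)
            event_rows.append(("separation", t, pid))
        if n_events > max_events:
            raise IntegrationError("event budget exceeded",
                                   _assemble_state(t, y, order, recs,
                                                   O_cum0 + len(sep_times)))

    # flush any samples at exactly t_end
    while s_ptr < len(sample_times):
        samp_C[s_ptr], samp_P[s_ptr] = y[0], y[1]
        s_ptr += 1

    init_arr = np.asarray(init_times)
    sep_arr = np.asarray(sep_times)
    pre_exist = np.asarray([pr.t_init for pr in state.primordia])
    n_unsep_t = (
        len(pre_exist)
        + np.searchsorted(init_arr, sample_times, side="right")
        - np.searchsorted(sep_arr, sample_times, side="right")
    )
    O_cum_t = O_cum0 + np.searchsorted(sep_arr, sample_times, side="right")
    total = samp_C + samp_P
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, samp_C / total, np.nan)
    traj = Trajectory(sample_times, samp_C, total, ratio,
                      n_unsep_t.astype(float), O_cum_t.astype(float))

    final = _assemble_state(t_end, y, order, recs, O_cum0 + len(sep_times))
    events = pd.DataFrame(event_rows,
                          columns=["event", "time_h", "primordium_id"])
    prolif_integral = y[4]
    conservation = {
        "initiations": len(init_times),
        "separations": len(sep_times),
        "recruited_cells": recruited_total,
        "exported_cells": final.E_cum - state.E_cum,
        "separated_organ_cells": sep_cells_total,
        "proliferated_cells": prolif_integral,
        "initial_cells": C0_total,
        "final_cells": final.C + final.P + sum(p.p for p in final.primordia),
        "mass_residual": (final.C + final.P + sum(p.p for p in final.primordia)
                          + (final.E_cum - state.E_cum) + sep_cells_total
                          - C0_total - prolif_integral),
    }
    return SimulationResult(traj, final, events, conservation)


def _assemble_state(t, y, order, recs, O_cum) -> ModelState:
    prims = []
    for slot, pid in enumerate(order):
        pr = recs[pid]
        prims.append(PrimordiumRecord(pid, pr.t_init, float(y[5 + slot])))
    return ModelState(t=float(t), C=float(y[0]), P=float(y[1]),
                      primordia=prims, O_cum=int(O_cum),
                      E_cum=float(y[2]), clock=float(y[3]))
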
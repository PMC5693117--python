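"""Model parameters for the SAM cell-population model.

The model tracks, per cell layer, the central zone (CZ, slowly dividing stem
cells), the peripheral zone (PZ, transit-amplifying cells) and a variable set
of unseparated organ primordia.  Cell numbers are per single layer; quantified
whole-meristem counts are ``layer_factor`` (= 3) times larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields

LN2 = math.log(2.0)

#: Calibration values: initiation 2.3 events/day, CZ/PZ doubling 39.8/18.3 h,
#: separation 2.2 days after initiation.
CALIBRATION = dict(T_C=39.8, T_P=18.3, lambda_ref=2.3, tau_sep=2.2 * 24.0)


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, feedback constants and delays of the SAM model.

    Parameters
    ----------
    T_C, T_P : float
        CZ and PZ cell doubling times in hours (calibration 39.8 and 18.3).
    T_prim : float or None
        Primordium-cell doubling time in hours; ``None`` means "same as T_P".
    C_star : float
        Homeostatic CZ cell number per layer.  The CZ-exit feedback
        ``delta(C) = exit_scale * (ln2/T_C) * (C/C_star)**m`` makes C_star a
        stable fixed point of the CZ dynamics.
    m : float
        CZ-exit feedback exponent (> 0).
    lambda_ref : float
        Primordium initiation rate, events per day, realised when C = C_ref.
    C_ref : float or None
        Reference CZ size of the linear initiation feedback
        ``lambda(C) = lambda_ref * C / C_ref``; ``None`` tracks C_star so that
        lambda_ref is the realised homeostatic initiation rate.
    tau_sep : float
        Delay from primordium initiation to separation, hours.
    n0 : float
        Cells recruited from the PZ into a new incipient primordium.
    g : float or None
        Per-cell rate (per hour) at which PZ cells exit to longitudinal stem
        growth.  ``None`` closes g by steady-state balance for ``P_star``:
        g = r_P + (r_C*C_star - (lambda_ref/24)*n0) / P_star.
    P_star : float
        PZ cell number used to close g (per layer).
    exit_scale : float
        Direct multiplier on the CZ-exit rate (1 = calibrated; 0 switches the
        CZ->PZ transition off for analytic-limit experiments).
    rho_back : float
        PZ->CZ re-specification back-flux rate (per hour per PZ cell);
        0 in all accepted scenarios.
    layer_factor : float
        Conversion from single-layer model counts to quantified whole-SAM
        counts (fixed at 3).
    initiation_mode : str
        'deterministic-clock' (event when the integral of lambda crosses the
        next integer) or 'poisson' (exponential thresholds, seeded).
    """

    T_C: float = CALIBRATION["T_C"]
    T_P: float = CALIBRATION["T_P"]
    T_prim: float | None = None
    C_star: float = 40.0
    m: float = 2.0
    lambda_ref: float = CALIBRATION["lambda_ref"]
    C_ref: float | None = None
    tau_sep: float = CALIBRATION["tau_sep"]
    n0: float = 4.0
    g: float | None = None
    P_star: float = 160.0
    exit_scale: float = 1.0
    rho_back: float = 0.0
    layer_factor: float = 3.0
    initiation_mode: str = "deterministic-clock"

    def __post_init__(self) -> None:
        for name in ("T_C", "T_P"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.T_prim is not None and self.T_prim <= 0:
            raise ValueError("T_prim must be > 0")
        if self.C_star <= 0:
            raise ValueError("C_star must be > 0")
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if self.lambda_ref < 0:
            raise ValueError("lambda_ref must be >= 0")
        if self.C_ref is not None and self.C_ref <= 0:
            raise ValueError("C_ref must be > 0")
        if self.tau_sep <= 0:
            raise ValueError("tau_sep must be > 0")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.g is not None and self.g < 0:
            raise ValueError("g must be >= 0")
        if self.P_star <= 0:
            raise ValueError("P_star must be > 0")
        if self.exit_scale < 0:
            raise ValueError("exit_scale must be >= 0")
        if self.rho_back < 0:
            raise ValueError("rho_back must be >= 0")
        if self.layer_factor != 3.0:
            raise ValueError("layer_factor is fixed at 3")
        if self.initiation_mode not in ("deterministic-clock", "poisson"):
            raise ValueError(
                "initiation_mode must be 'deterministic-clock' or 'poisson'"
            )

    # ---- derived rates ---------------------------------------------------
    @property
    def r_C(self) -> float:
        """Per-cell CZ proliferation rate, per hour."""
        return LN2 / self.T_C

    @property
    def r_P(self) -> float:
        """Per-cell PZ proliferation rate, per hour."""
        return LN2 / self.T_P

    @property
    def r_prim(self) -> float:
        """Per-cell primordium proliferation rate, per hour."""
        return LN2 / (self.T_P if self.T_prim is None else self.T_prim)

    @property
    def C_ref_eff(self) -> float:
        return self.C_star if self.C_ref is None else self.C_ref

    @property
    def g_eff(self) -> float:
        """Export rate; closed by steady-state balance when g is None.

        At homeostasis (C = C_star, exit_scale = 1) the PZ balance
        r_P*P* + r_C*C* - g*P* - (lambda_ref/24)*n0 = 0 fixes g so that the
        total cell number is stationary.
        """
        if self.g is not None:
            return self.g
        g = self.r_P + (self.r_C * self.C_star
                        - (self.lambda_ref / 24.0) * self.n0) / self.P_star
        if g < 0:
            raise ValueError("steady-state closure yields negative g; "
                             "set g explicitly")
        return g

    def resolved(self) -> "ModelParameters":
        """Return a copy with T_prim, C_ref and g materialised to numbers."""
        return replace(
            self,
            T_prim=self.T_P if self.T_prim is None else self.T_prim,
            C_ref=self.C_ref_eff,
            g=self.g_eff,
        )

    def with_exit_fold(self, fold: float) -> "ModelParameters":
        """Change the CZ->PZ transition rate ``fold``-fold at fixed C.

        Encoded as a replacement of the homeostatic CZ size,
        C_star -> C_star * fold**(-1/m), which multiplies
        delta(C) = r_C (C/C_star)^m by ``fold`` for every C.  Because C_ref
        tracks C_star, lambda_ref remains the realised homeostatic initiation
        rate under the modified transition.
        """
        if fold <= 0:
            raise ValueError("fold must be > 0")
        if self.C_ref is not None:
            raise ValueError("with_exit_fold requires C_ref tracking C_star")
        return replace(self, C_star=self.C_star * fold ** (-1.0 / self.m))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def exit_rate(C: float, params: ModelParameters) -> float:
    """Per-cell CZ->PZ transition rate (per hour) at CZ size ``C``.

    delta(C) = exit_scale * (ln2/T_C) * (C/C_star)**m; strictly increasing in
    C with delta(C_star) = ln2/T_C at exit_scale 1, so C_star is a steady
    state of the CZ balance r_C*C - delta(C)*C.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    return params.exit_scale * params.r_C * (C / params.C_star) ** params.m


def initiation_rate(C: float, params: ModelParameters) -> float:
    """Primordium initiation rate (events per day) at CZ size ``C``.

    Linear feedback lambda(C) = lambda_ref * C / C_ref: larger meristems
    initiate organs proportionally faster.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    return params.lambda_ref * C / params.C_ref_eff
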
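"""Preset in-silico experiments for the SAM model.

Each scenario is the calibrated wild-type parameter set plus a small list of
named modifiers.  Transition-rate ("exit") changes are encoded as
replacements of the homeostatic CZ size C_star (a k-fold exit increase maps
C_star to C_star * k**(-1/m), which changes delta(C) k-fold at every fixed
C); the initiation reference C_ref tracks C_star, so lambda_ref remains the
realised homeostatic initiation rate under a modified transition.

The registry covers the wild-type calibration, the candidate loss-of-function
parameterisations (of which only the final one — faster CZ exit, 15% higher
initiation, separation shortened to 42 h — reproduces all observables), and
the gain-of-function alternatives, of which only the combination of slower
CZ exit with faster PZ proliferation is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import ModelState, SimulationResult, homeostatic_state, simulate
from .parameters import ModelParameters

__all__ = ["Scenario", "SCENARIOS", "get_scenario", "run_scenario",
           "scenario_parameters"]

#: Fold-change defaults not printed in the source study (see docs/methods.md).
HEC_EXIT_FOLD = 1.5        # hec loss of function: faster CZ->PZ transition
HEC_LAMBDA_FOLD = 1.15     # 15% higher initiation rate
HEC_TAU_SEP = 42.0         # hours (wild-type reference 52 h)
WT_TAU_SEP_FIT = 52.0      # hours, wild-type value used in the mutant fit
GOF_EXIT_FOLD = 1.0 / 1.5  # gain of function: slower CZ->PZ transition
GOF_TP_FOLD = 1.0 / 1.1    # gain of function: faster PZ proliferation
GOF_RHO_BACK = 0.005       # PZ->CZ re-specification back-flux, per hour


@dataclass(frozen=True)
class Scenario:
    """A named modifier set on top of a base parameterisation.

    ``modifiers`` maps ModelParameters field names to ``("scale", factor)``
    or ``("set", value)``; the pseudo-field ``"exit"`` scales the CZ->PZ
    transition rate via the C_star encoding described in the module docstring.
    """
    name: str
    modifiers: tuple[tuple[str, str, float], ...] = ()
    description: str = ""

    def apply(self, base: ModelParameters) -> ModelParameters:
        # materialise g from the base closure first: export capacity is a
        # property of the plant, not re-tuned by the perturbation
        params = replace(base, g=base.g_eff)
        for name, mode, value in self.modifiers:
            if name == "exit":
                if mode != "scale":
                    raise ValueError("'exit' modifier must be a scale")
                params = params.with_exit_fold(value)
                continue
            if name not in params.to_dict():
                raise ValueError(f"unknown parameter {name!r} in scenario "
                                 f"{self.name!r}")
            old = getattr(params, name)
            if mode == "scale":
                if old is None:
                    raise ValueError(f"cannot scale unset parameter {name!r}")
                params = replace(params, **{name: old * value})
            elif mode == "set":
                params = replace(params, **{name: value})
            else:
                raise ValueError(f"unknown modifier mode {mode!r}")
        return params


SCENARIOS: dict[str, Scenario] = {s.name: s for s in [
    Scenario("calibration-wt", (),
             "calibrated wild type (initiation 2.3/day, T_C 39.8 h, "
             "T_P 18.3 h, separation 2.2 days)"),
    Scenario("wt-fit", (("tau_sep", "set", WT_TAU_SEP_FIT),),
             "wild type with the fitted 52 h separation delay"),
    Scenario("hec-lof-A", (("exit", "scale", HEC_EXIT_FOLD),
                           ("tau_sep", "set", HEC_TAU_SEP)),
             "rejected hec1,2,3 candidate: faster CZ exit, shorter "
             "separation, unchanged initiation"),
    Scenario("hec-lof-B", (("exit", "scale", HEC_EXIT_FOLD),
                           ("lambda_ref", "scale", HEC_LAMBDA_FOLD)),
             "rejected hec1,2,3 candidate: faster CZ exit, higher "
             "initiation, unchanged separation"),
    Scenario("hec-lof-final", (("exit", "scale", HEC_EXIT_FOLD),
                               ("lambda_ref", "scale", HEC_LAMBDA_FOLD),
                               ("tau_sep", "set", HEC_TAU_SEP)),
             "accepted hec1,2,3 parameterisation: faster CZ exit, 15% "
             "higher initiation, separation 42 h"),
    Scenario("gof-cz", (("exit", "scale", GOF_EXIT_FOLD),
                        ("T_P", "scale", GOF_TP_FOLD)),
             "accepted CZ gain of function: slower CZ exit plus faster "
             "PZ proliferation"),
    Scenario("gof-delay-only", (("exit", "scale", GOF_EXIT_FOLD),),
             "rejected gain-of-function alternative: slower CZ exit only"),
    Scenario("gof-proliferation-only", (("T_P", "scale", GOF_TP_FOLD),),
             "rejected gain-of-function alternative: faster PZ "
             "proliferation only"),
    Scenario("gof-respecification", (("rho_back", "set", GOF_RHO_BACK),),
             "rejected gain-of-function alternative: PZ->CZ "
             "re-specification back-flux"),
]}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        options = ", ".join(sorted(SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; options: {options}") from None


def scenario_parameters(
    scenario: str | Scenario,
    base: ModelParameters | None = None,
) -> ModelParameters:
    """Parameters of a scenario applied to ``base`` (default: calibration)."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    return scenario.apply(ModelParameters() if base is None else base)


def run_scenario(
    scenario: str | Scenario,
    t_end: float = 1440.0,
    dt_out: float | None = 24.0,
    sample_times=None,
    seed: int | None = None,
    base: ModelParameters | None = None,
    init: ModelState | None = None,
) -> SimulationResult:
    """Simulate a scenario.

    Runs start from the wild-type homeostatic state (a perturbation
    experiment on a calibrated meristem) unless ``init`` is given.
    """
    base = ModelParameters() if base is None else base
    params = scenario_parameters(scenario, base)
    if init is None:
        init = homeostatic_state(base)
    return simulate(params, init=init, t_end=t_end, dt_out=dt_out,
                    sample_times=sample_times, seed=seed)
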
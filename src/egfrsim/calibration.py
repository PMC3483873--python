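"""Calibration of under-specified rate constants against printed kinetic features.

The reconstructed (non-SBML) model build leaves a small set of constants
under-determined: the mutant autophosphorylation scale, the erlotinib
effective dissociation constant, and the cascade phosphatase/catalytic rates.
This module bundles the printed kinetic-feature targets (peak times, the
internalization rate ratio, the PTEN-loss late-pAkt flag), scores a constant
set against them, and runs a seeded multi-start local optimization over the
declared free subset.  Calibration edits constants only — never topology.
When models are loaded from supplementary SBML files, calibration is a no-op
pass-through and the targets are evaluated as a pure check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ValidationError
from .kinetics_features import extract_features, internalization_ratio
from .model_library import (
    CALIBRATED_MUTANT_PHOS_SCALE,
    DEFAULT_CONSTANTS,
    MUTANT_INTERNALIZATION_FACTOR,
    Scenario,
    build_normal_model,
    build_scenario,
    set_egf,
    standard_observables,
)
from .simulation import SolverOptions, Trajectory, simulate

#: Free constants of the fallback build, with (lower, upper) bounds.
FREE_PARAMETERS: dict[str, tuple[float, float]] = {
    "mutant_phos_scale": (1e-3, 1.0),
    "kon_erl": (1e-6, 1e-2),
    "k_mkp_induce": (1e-3, 1.0),
    "kcat_mkp": (1e-3, 1.0),
    "k_mkp_decay": (1e-4, 0.1),
    "kcat_erk": (1e-3, 1.0),
    "kcat_mek": (1e-3, 1.0),
    "k_mekptase": (1e-4, 0.1),
    "kcat_raf": (1e-3, 1.0),
    "k_rafdeact": (1e-4, 0.1),
    "k_gap": (1e-4, 0.5),
    "kcat_akt": (1e-2, 10.0),
    "k_aktptase": (1e-3, 1.0),
    "kcat_stat": (1e-2, 10.0),
    "k_import": (1e-4, 0.1),
    "k_int": (1e-4, 0.1),
}


@dataclass
class CalibrationTarget:
    """A printed kinetic feature with its comparison rule.

    ``feature`` is one of ``peak_time`` (s), ``rate_ratio`` (dimensionless,
    wt over mutant internalization) or ``late_level_flag`` (value at 2000 s
    over the running maximum).  ``comparison``: ``le``/``ge`` bound or
    ``eq_within`` a relative ``tolerance``.
    """

    observable: str
    feature: str
    scenario: str
    value: float
    units: str
    comparison: str
    tolerance: float = 0.25
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.comparison not in ("le", "ge", "eq_within"):
            raise ValidationError(f"unknown comparison {self.comparison!r}")
        if self.comparison == "eq_within" and not self.tolerance > 0:
            raise ValidationError("eq_within requires tolerance > 0")
        if not self.provenance:
            raise ValidationError("provenance must be non-empty")

    def residual(self, measured: float) -> float:
        """Scaled residual: 0 when satisfied (bounds) or exact (eq_within);
        1 at the tolerance edge for eq_within."""
        if self.comparison == "eq_within":
            return (measured - self.value) / (self.tolerance * self.value)
        if self.comparison == "le":
            return max(0.0, (measured - self.value) / (self.tolerance * self.value))
        return max(0.0, (self.value - measured) / (self.tolerance * self.value))

    def passes(self, measured: float) -> bool:
        if self.comparison == "eq_within":
            return abs(measured - self.value) <= self.tolerance * self.value
        if self.comparison == "le":
            return measured <= self.value
        return measured >= self.value


@dataclass
class TargetResult:
    target: CalibrationTarget
    measured: float
    residual: float
    passed: bool


@dataclass
class CalibrationResult:
    """Outcome of :func:`calibrate` (or of a pure target evaluation)."""

    parameters: dict[str, float]
    results: list[TargetResult]
    loss: float
    seed: int | None = None
    trace: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def n_passed(self) -> int:
        return sum(r.passed for r in self.results)


def default_targets() -> list[CalibrationTarget]:
    """The bundled eight-target set of printed kinetic features."""
    return [
        CalibrationTarget("ppERK", "peak_time", "normal", 600.0, "s", "le",
                          provenance="normal ERK phosphorylation peak occurs within 600 seconds"),
        CalibrationTarget("pAkt", "peak_time", "normal", 50.0, "s", "eq_within",
                          provenance="Akt shows the phosphorylation peak at about 50 seconds"),
        CalibrationTarget("STAT3c_dimer", "peak_time", "normal", 200.0, "s", "eq_within",
                          provenance="highest dimer STAT3 concentration is at the 200th second"),
        CalibrationTarget("ppMEK", "peak_time", "normal", 500.0, "s", "eq_within",
                          provenance="normal-model MEK phosphorylation peak is about 500 seconds"),
        CalibrationTarget("ppMEK", "peak_time", "nsclc", 1000.0, "s", "eq_within",
                          provenance="MEK phosphorylation peak in NSCLC in about 1000 seconds"),
        CalibrationTarget("ppERK", "peak_time", "nsclc", 2000.0, "s", "eq_within",
                          provenance="NSCLC ERK phosphorylation peak is nearly 2000 seconds"),
        CalibrationTarget("surface_EGFR", "rate_ratio", "internalization", 2.0, "", "eq_within",
                          provenance="wtEGFR internalization rate is roughly two times that of the mutant"),
        CalibrationTarget("pAkt", "late_level_flag", "nsclc_pten_loss", 0.99, "", "ge",
                          provenance="under PTEN loss, after 2000 s pAkt is at its highest level"),
    ]


def build_mutant_receptor_model(constants: Mapping[str, float] | None = None):
    """Normal-expression model with mutant (L858R) receptor kinetics only —
    the wild-type vs mutant contrast used for the internalization comparison."""
    net = build_normal_model(constants=constants)
    net.reactions["autophosphorylation"].rate_law.k1 *= _mutant_scale(constants)
    for rid, rxn in net.reactions.items():
        if rid.startswith("internalization_"):
            rxn.rate_law.k1 *= MUTANT_INTERNALIZATION_FACTOR
    net.name = "mutant_receptor"
    net.touch()
    set_egf(net, 50.0)
    return net


def _mutant_scale(constants: Mapping[str, float] | None) -> float:
    if constants and "mutant_phos_scale" in constants:
        return constants["mutant_phos_scale"]
    return CALIBRATED_MUTANT_PHOS_SCALE


def evaluate_targets(
    targets: Sequence[CalibrationTarget] | None = None,
    constants: Mapping[str, float] | None = None,
    options: SolverOptions | None = None,
    trajectories: Mapping[str, Trajectory] | None = None,
) -> list[TargetResult]:
    """Measure every target from fresh simulations (or supplied trajectories)."""
    targets = list(targets) if targets is not None else default_targets()
    options = options or SolverOptions()
    cache: dict[str, Trajectory] = dict(trajectories or {})

    def traj(scenario: str) -> Trajectory:
        if scenario not in cache:
            if scenario == "internalization":
                raise KeyError(scenario)
            mps = constants.get("mutant_phos_scale") if constants else None
            extra = {k: v for k, v in (constants or {}).items() if k != "mutant_phos_scale"}
            net = build_scenario(Scenario(scenario), constants=extra or None)
            if mps is not None and scenario.startswith("nsclc"):
                scale = mps / CALIBRATED_MUTANT_PHOS_SCALE
                net.reactions["autophosphorylation"].rate_law.k1 *= scale
                net.set_parameter("mutant_phos_scale", mps)
                net.touch()
            cache[scenario] = simulate(net, options)
        return cache[scenario]

    out: list[TargetResult] = []
    for tgt in targets:
        if tgt.feature == "rate_ratio":
            extra = {k: v for k, v in (constants or {}).items() if k != "mutant_phos_scale"}
            window = 100.0
            opts = SolverOptions(method=options.method, rel_tol=options.rel_tol,
                                 abs_tol=options.abs_tol, t_end=max(200.0, 2 * window),
                                 grid_dt=options.grid_dt)
            if "internalization_wt" not in cache:
                wt = build_normal_model(constants=extra or None)
                set_egf(wt, 50.0)
                cache["internalization_wt"] = simulate(wt, opts)
                cache["internalization_mut"] = simulate(
                    build_mutant_receptor_model(constants), opts
                )
            measured = internalization_ratio(
                cache["internalization_wt"], cache["internalization_mut"], window
            )
        elif tgt.feature == "late_level_flag":
            trajectory = traj(tgt.scenario)
            obs = standard_observables_for_traj(trajectory, tgt.observable)
            series = trajectory.observable(obs)
            i2000 = int(np.searchsorted(trajectory.times, 2000.0))
            i2000 = min(i2000, len(series) - 1)
            running_max = float(series[: i2000 + 1].max())
            measured = float(series[i2000] / running_max) if running_max > 0 else 0.0
        elif tgt.feature == "peak_time":
            trajectory = traj(tgt.scenario)
            obs = standard_observables_for_traj(trajectory, tgt.observable)
            measured = extract_features(trajectory.observable(obs), trajectory.times).peak_time
        else:
            raise ValidationError(f"unknown target feature {tgt.feature!r}")
        res = tgt.residual(measured)
        out.append(TargetResult(tgt, float(measured), float(res), tgt.passes(measured)))
    return out


def standard_observables_for_traj(trajectory: Trajectory, name: str):
    from .simulation import Observable

    defs = {
        "ppERK": {"ppERK": 1.0},
        "ppMEK": {"ppMEK": 1.0},
        "pAkt": {"pAkt": 1.0},
        "STAT3c_dimer": {"STAT3dim_c": 1.0},
        "STAT3n_dimer": {"STAT3dim_n": 1.0},
    }
    if name in defs:
        return Observable(name, defs[name])
    from .kinetics_features import standard_observables_for

    return standard_observables_for(trajectory)


def feature_loss(
    constants: Mapping[str, float],
    targets: Sequence[CalibrationTarget] | None = None,
    options: SolverOptions | None = None,
    penalty: float = 1e3,
) -> float:
    """Scalar calibration loss: Σ residual² over eq_within targets plus hinge
    penalties for le/ge/flag targets; 0 iff every target passes exactly.
    Simulation failures yield a large finite penalty."""
    try:
        results = evaluate_targets(targets, constants=constants, options=options)
    except Exception as exc:  # solver blow-up in a bad region of constant space
        import logging

        logging.getLogger(__name__).warning("feature_loss: simulation failed (%s)", exc)
        return penalty
    return float(sum(r.residual**2 for r in results))


def calibrate(
    initial: Mapping[str, float] | None = None,
    targets: Sequence[CalibrationTarget] | None = None,
    seed: int = 0,
    free: Iterable[str] | None = None,
    n_starts: int = 16,
    max_evals: int = 500,
    options: SolverOptions | None = None,
) -> CalibrationResult:
    """Seeded multi-start Nelder–Mead over the declared free constants.

    Returns immediately when the initial constant set already passes every
    target.  The result never passes fewer targets than the initial vector;
    on optimizer stagnation the best-found vector is returned with
    ``converged=False`` rather than raising.
    """
    targets = list(targets) if targets is not None else default_targets()
    free = list(free) if free is not None else list(FREE_PARAMETERS)
    unknown = [f for f in free if f not in FREE_PARAMETERS]
    if unknown:
        raise ValidationError(f"not in the declared free subset: {unknown}")
    base = {**DEFAULT_CONSTANTS, "mutant_phos_scale": CALIBRATED_MUTANT_PHOS_SCALE}
    if initial:
        base.update(initial)

    init_results = evaluate_targets(targets, constants=base, options=options)
    init_loss = float(sum(r.residual**2 for r in init_results))
    if all(r.passed for r in init_results):
        return CalibrationResult(dict(base), init_results, init_loss, seed, [], True)

    rng = np.random.default_rng(seed)
    bounds = np.array([FREE_PARAMETERS[f] for f in free])
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    x0 = np.log(np.array([base[f] for f in free]))

    trace: list[dict] = []

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, log_lo, log_hi)
        consts = {**base, **{f: float(np.exp(v)) for f, v in zip(free, x)}}
        loss = feature_loss(consts, targets, options=options)
        trace.append({"loss": loss, **{f: consts[f] for f in free}})
        return loss

    best_x, best_loss = x0.copy(), init_loss
    budget = max(1, max_evals)
    for start in range(max(1, n_starts)):
        if start == 0:
            guess = x0
        else:
            guess = x0 + rng.normal(0.0, 0.5, size=len(free))
            guess = np.clip(guess, log_lo, log_hi)
        res = minimize(objective, guess, method="Nelder-Mead",
                       options={"maxfev": budget, "xatol": 1e-3, "fatol": 1e-4})
        if res.fun < best_loss:
            best_loss, best_x = float(res.fun), np.clip(res.x, log_lo, log_hi)
        if best_loss == 0.0:
            break

    fitted = {**base, **{f: float(np.exp(v)) for f, v in zip(free, best_x)}}
    results = evaluate_targets(targets, constants=fitted, options=options)
    if sum(r.passed for r in results) < sum(r.passed for r in init_results):
        fitted, results, best_loss = dict(base), init_results, init_loss
    converged = all(r.passed for r in results)
    return CalibrationResult(fitted, results, float(best_loss), seed, trace, converged)
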
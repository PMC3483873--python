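"""Kinetic summary statistics of simulated time courses and scenario comparison.

Features per observable: peak time (earliest global maximum), peak amplitude,
area under the curve, sustainment index (fraction of the horizon spent at or
above half the peak) and final-over-peak ratio.  The internalization rate is
operationalized as a log-linear least-squares decay fit of the
surface-receptor observable over an early window (default 100 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitDegeneracyError, ResolutionError, ValidationError
from .simulation import Observable, Trajectory


@dataclass
class KineticFeatures:
    """Summary of one observable's time course."""

    peak_time: float
    peak_amplitude: float
    auc: float
    sustainment_index: float
    final_over_peak: float

    def as_dict(self) -> dict:
        return {
            "peak_time": self.peak_time,
            "peak_amplitude": self.peak_amplitude,
            "auc": self.auc,
            "sustainment_index": self.sustainment_index,
            "final_over_peak": self.final_over_peak,
        }


def extract_features(
    series: np.ndarray, times: np.ndarray, t_end: float | None = None
) -> KineticFeatures:
    """Extract :class:`KineticFeatures` from a time series on a grid.

    Peak time is the earliest time attaining the global maximum (deterministic
    on plateaus).  An all-zero series yields amplitude 0 and, by documented
    convention, sustainment index 0 and final/peak 0.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size == 0 or series.shape != times.shape:
        raise ValidationError("series must be non-empty and aligned to the time grid")
    if t_end is not None:
        keep = times <= t_end
        series, times = series[keep], times[keep]
    peak_idx = int(np.argmax(series))
    peak = float(series[peak_idx])
    auc = float(np.trapezoid(series, times))
    if peak <= 0:
        return KineticFeatures(float(times[peak_idx]), peak, auc, 0.0, 0.0)
    above = series >= 0.5 * peak
    # fraction of the horizon, measured as integrated time above half-peak
    sustainment = float(np.trapezoid(above.astype(float), times) / (times[-1] - times[0]))
    return KineticFeatures(
        peak_time=float(times[peak_idx]),
        peak_amplitude=peak,
        auc=auc,
        sustainment_index=sustainment,
        final_over_peak=float(series[-1] / peak),
    )


def exponential_decay_rate(
    series: np.ndarray, times: np.ndarray, window: float
) -> float:
    """Single-exponential decay rate (s⁻¹) over ``[0, window]`` by log-linear
    least squares on the normalized series.

    Raises :class:`FitDegeneracyError` when the series does not decay or is
    non-positive on the window.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = times <= window
    y, t = series[keep], times[keep]
    if y.size < 3:
        raise FitDegeneracyError("window too short for a decay fit")
    if np.any(y <= 0):
        raise FitDegeneracyError("series must be positive on the fit window")
    slope = np.polyfit(t, np.log(y / y[0]), 1)[0]
    if slope >= 0:
        raise FitDegeneracyError("series does not decay over the window")
    return float(-slope)


def internalization_ratio(
    traj_wt: Trajectory,
    traj_mut: Trajectory,
    window: float = 100.0,
    observable: Observable | None = None,
) -> float:
    """Ratio of fitted surface-receptor decay rates, wild type over mutant.

    Both trajectories must expose the surface-receptor observable; the window
    (default 100 s) must lie within both horizons.
    """
    if window > traj_wt.times[-1] or window > traj_mut.times[-1]:
        raise ValidationError("fit window exceeds a trajectory horizon")
    rates = []
    for traj in (traj_wt, traj_mut):
        obs = observable if observable is not None else standard_observables_for(traj)
        rates.append(exponential_decay_rate(traj.observable(obs), traj.times, window))
    return rates[0] / rates[1]


def standard_observables_for(trajectory: Trajectory) -> Observable:
    """Surface-receptor observable restricted to the trajectory's species."""
    from .model_library import _SURFACE_COMPLEXES

    weights = {"EGFR": 1.0, "EGF_EGFR": 1.0}
    weights.update(
        {sid: float(n) for sid, (n, _) in _SURFACE_COMPLEXES.items() if sid != "EGF_EGFR"}
    )
    weights["EGF_EGFR2_erl"] = 2.0
    weights = {sid: w for sid, w in weights.items() if sid in trajectory.species_ids}
    if not weights:
        raise ResolutionError("trajectory has no surface-receptor species")
    return Observable("surface_EGFR", weights)


@dataclass
class ObservableComparison:
    """Feature pair plus derived ratios for one observable, scenario A vs B."""

    observable: str
    features_a: KineticFeatures
    features_b: KineticFeatures
    peak_shift: float = field(init=False)
    amplitude_fold: float | None = field(init=False)
    sustainment_difference: float = field(init=False)
    dominance: str = field(init=False, default="crossing")

    def __post_init__(self) -> None:
        self.peak_shift = self.features_a.peak_time - self.features_b.peak_time
        self.amplitude_fold = (
            self.features_a.peak_amplitude / self.features_b.peak_amplitude
            if self.features_b.peak_amplitude > 0
            else None
        )
        self.sustainment_difference = (
            self.features_a.sustainment_index - self.features_b.sustainment_index
        )


@dataclass
class ScenarioComparison:
    """Per-observable comparison of two runs on a shared time grid."""

    label_a: str
    label_b: str
    observables: dict[str, ObservableComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, comp in self.observables.items():
            rows.append({
                "observable": name,
                f"peak_time_{self.label_a}": comp.features_a.peak_time,
                f"peak_time_{self.label_b}": comp.features_b.peak_time,
                f"peak_amplitude_{self.label_a}": comp.features_a.peak_amplitude,
                f"peak_amplitude_{self.label_b}": comp.features_b.peak_amplitude,
                "peak_shift": comp.peak_shift,
                "amplitude_fold": comp.amplitude_fold,
                "sustainment_difference": comp.sustainment_difference,
                "dominance": comp.dominance,
            })
        return pd.DataFrame(rows)


def compare_scenarios(
    traj_a: Trajectory,
    traj_b: Trajectory,
    observables: dict[str, Observable],
    labels: tuple[str, str] = ("A", "B"),
    dominance_rtol: float = 1e-6,
) -> ScenarioComparison:
    """Compare two trajectories observable by observable.

    Trajectory B is linearly re-interpolated onto A's grid when the grids
    differ.  The dominance flag is ``"A"`` when A ≥ B pointwise (within a
    relative tolerance of the shared maximum), ``"B"`` symmetrically,
    ``"tie"`` when both hold, else ``"crossing"``.
    """
    out: dict[str, ObservableComparison] = {}
    for name, obs in observables.items():
        series_a = traj_a.observable(obs)
        series_b = traj_b.observable(obs)
        if traj_b.times.shape != traj_a.times.shape or np.any(traj_b.times != traj_a.times):
            series_b = np.interp(traj_a.times, traj_b.times, series_b)
        comp = ObservableComparison(
            name,
            extract_features(series_a, traj_a.times),
            extract_features(series_b, traj_a.times),
        )
        tol = dominance_rtol * max(series_a.max(), series_b.max(), 1e-300)
        a_dom = bool(np.all(series_a >= series_b - tol))
        b_dom = bool(np.all(series_b >= series_a - tol))
        comp.dominance = "tie" if (a_dom and b_dom) else "A" if a_dom else "B" if b_dom else "crossing"
        out[name] = comp
    return ScenarioComparison(labels[0], labels[1], out)
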
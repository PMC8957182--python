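"""Cardiac-cycle timing and its scaling with heart rate.

Septal rebound stretch is defined on the systolic window between mitral
valve closure (MVC) and aortic valve closure (AVC).  Valve events are
measured at rest (Doppler, or visually from a parasternal view); during
exercise no Doppler is available, so the systolic duration is rescaled
using a reference relation between heart rate and systolic/diastolic
phase durations, fitted with smoothing splines.

The packaged default reference follows the classic systolic-time-interval
literature, where total electromechanical systole shortens approximately
linearly with heart rate (QS2 ~ 0.546 - 0.0021*HR seconds) while the
cardiac cycle shortens as 60/HR, so the systolic *fraction* of the cycle
grows with rate.  Any user table with columns (hr_bpm, systolic_s,
diastolic_s) can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

from .errors import (
    ExtrapolationWarning,
    InsufficientReferenceError,
    TimingInfeasibleError,
)

__all__ = [
    "CardiacTiming",
    "PhaseDurationModel",
    "default_reference_table",
    "fit_phase_duration_splines",
    "scale_timing",
    "ejection_frame_count",
    "resting_timing",
]

_TIMING_SOURCES = ("doppler", "visual", "scaled")


@dataclass(frozen=True)
class CardiacTiming:
    """Valve-event timing for one cardiac cycle.

    Times are in seconds from the start of the cine-loop; ``mvc_time`` <
    ``avc_time`` < ``cycle_length`` and the cycle length must agree with
    60/heart_rate to within 2%.
    """

    heart_rate: float
    cycle_length: float
    mvc_time: float
    avc_time: float
    source: str = "doppler"

    def __post_init__(self) -> None:
        if self.source not in _TIMING_SOURCES:
            raise ValueError(f"unknown timing source {self.source!r}")
        if not 0.0 <= self.mvc_time < self.avc_time < self.cycle_length:
            raise ValueError(
                "require 0 <= mvc_time < avc_time < cycle_length, got "
                f"mvc={self.mvc_time}, avc={self.avc_time}, "
                f"cycle={self.cycle_length}"
            )
        nominal = 60.0 / self.heart_rate
        if abs(self.cycle_length - nominal) > 0.02 * nominal:
            raise ValueError(
                f"cycle_length {self.cycle_length:.4f}s inconsistent with "
                f"heart rate {self.heart_rate} bpm (60/HR = {nominal:.4f}s)"
            )

    @property
    def systolic_duration(self) -> float:
        return self.avc_time - self.mvc_time

    def to_dict(self) -> dict:
        return {
            "heart_rate": self.heart_rate,
            "cycle_length": self.cycle_length,
            "mvc_time": self.mvc_time,
            "avc_time": self.avc_time,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CardiacTiming":
        return cls(**d)


def default_reference_table(
    hr_min: float = 50.0, hr_max: float = 130.0, step: float = 5.0
) -> pd.DataFrame:
    """Reference systolic/diastolic durations versus heart rate.

    Linear electromechanical-systole relation; diastole is the cycle
    remainder, so systolic + diastolic = 60/HR exactly.
    """
    hr = np.arange(hr_min, hr_max + step / 2, step, dtype=float)
    systolic = 0.546 - 0.0021 * hr
    diastolic = 60.0 / hr - systolic
    return pd.DataFrame(
        {"hr_bpm": hr, "systolic_s": systolic, "diastolic_s": diastolic}
    )


@dataclass
class PhaseDurationModel:
    """Smoothing-spline fits of phase durations versus heart rate."""

    reference_table: pd.DataFrame
    hr_range: tuple[float, float]
    _systolic_spline: BSpline = field(repr=False)
    _diastolic_spline: BSpline = field(repr=False)

    def _clamped(self, hr: float) -> float:
        lo, hi = self.hr_range
        if hr < lo or hr > hi:
            warnings.warn(
                f"heart rate {hr} bpm outside fitted range [{lo}, {hi}]; "
                "clamping to range endpoint",
                ExtrapolationWarning,
                stacklevel=3,
            )
            return float(np.clip(hr, lo, hi))
        return float(hr)

    def systolic_time(self, hr: float) -> float:
        """Systolic duration (s) at the given heart rate, clamped to range."""
        return float(self._systolic_spline(self._clamped(hr)))

    def diastolic_time(self, hr: float) -> float:
        return float(self._diastolic_spline(self._clamped(hr)))

    def systolic_fraction(self, hr: float) -> float:
        """Systolic share of the cycle, systolic_time * HR / 60."""
        hr = self._clamped(hr)
        return self.systolic_time(hr) * hr / 60.0


def fit_phase_duration_splines(
    reference_table: pd.DataFrame, lam: float | None = None
) -> PhaseDurationModel:
    """Fit smoothing splines of systolic/diastolic duration vs heart rate.

    Parameters
    ----------
    reference_table:
        Columns ``hr_bpm``, ``systolic_s``, ``diastolic_s``; at least 4
        distinct heart rates with positive durations.
    lam:
        Smoothing parameter. ``None`` selects it by generalized
        cross-validation; ``0`` interpolates the tabulated values.
    """
    required = {"hr_bpm", "systolic_s", "diastolic_s"}
    if not required.issubset(reference_table.columns):
        raise ValueError(f"reference table must have columns {sorted(required)}")
    table = (
        reference_table[list(required)]
        .dropna()
        .drop_duplicates(subset="hr_bpm")
        .sort_values("hr_bpm")
        .reset_index(drop=True)
    )
    if len(table) < 4:
        raise InsufficientReferenceError(
            f"need >= 4 distinct heart rates, got {len(table)}"
        )
    if (table["systolic_s"] <= 0).any() or (table["diastolic_s"] <= 0).any():
        raise ValueError("phase durations must be positive")
    hr = table["hr_bpm"].to_numpy(float)
    sys_spl = make_smoothing_spline(hr, table["systolic_s"].to_numpy(float), lam=lam)
    dia_spl = make_smoothing_spline(hr, table["diastolic_s"].to_numpy(float), lam=lam)
    return PhaseDurationModel(
        reference_table=table,
        hr_range=(float(hr[0]), float(hr[-1])),
        _systolic_spline=sys_spl,
        _diastolic_spline=dia_spl,
    )


_DEFAULT_MODEL: PhaseDurationModel | None = None


def default_phase_model() -> PhaseDurationModel:
    """The packaged reference model (cached)."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = fit_phase_duration_splines(default_reference_table())
    return _DEFAULT_MODEL


def resting_timing(
    heart_rate: float,
    systolic_duration: float | None = None,
    source: str = "doppler",
    model: PhaseDurationModel | None = None,
) -> CardiacTiming:
    """Convenience constructor for a resting timing with MVC at t=0.

    When ``systolic_duration`` is omitted it is taken from the phase
    duration model at the resting heart rate.
    """
    if systolic_duration is None:
        model = model or default_phase_model()
        systolic_duration = model.systolic_time(heart_rate)
    cycle = 60.0 / heart_rate
    if systolic_duration >= cycle:
        raise TimingInfeasibleError(
            f"systolic duration {systolic_duration:.3f}s >= cycle {cycle:.3f}s"
        )
    return CardiacTiming(
        heart_rate=heart_rate,
        cycle_length=cycle,
        mvc_time=0.0,
        avc_time=systolic_duration,
        source=source,
    )


def scale_timing(
    rest: CardiacTiming, exercise_hr: float, model: PhaseDurationModel
) -> CardiacTiming:
    """Scale resting valve timing to an exercise heart rate.

    The new systolic duration is the resting systolic duration multiplied
    by the model ratio ``systolic_time(exercise_hr) /
    systolic_time(rest_hr)``; the cycle length becomes ``60/exercise_hr``
    and AVC follows MVC by the scaled systolic duration.
    """
    if rest.source not in ("doppler", "visual"):
        raise ValueError("rest timing must come from Doppler or visual annotation")
    ratio = model.systolic_time(exercise_hr) / model.systolic_time(rest.heart_rate)
    new_cycle = 60.0 / exercise_hr
    new_sys = rest.systolic_duration * ratio
    avc = rest.mvc_time + new_sys
    if avc >= new_cycle or rest.mvc_time >= new_cycle:
        raise TimingInfeasibleError(
            f"scaled AVC {avc:.3f}s does not fit in cycle {new_cycle:.3f}s"
        )
    return CardiacTiming(
        heart_rate=exercise_hr,
        cycle_length=new_cycle,
        mvc_time=rest.mvc_time,
        avc_time=avc,
        source="scaled",
    )


def ejection_frame_count(timing: CardiacTiming, frame_rate: float) -> int:
    """Number of frame samples in the ejection window at ``frame_rate``.

    Frames are sampled at t = k/frame_rate (k = 0, 1, ...); a sample is
    counted when ``mvc_time <= t < avc_time`` (half-open window; the AVC
    sample itself opens the next phase).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    eps = 1e-9
    k_first = int(np.ceil(timing.mvc_time * frame_rate - eps))
    k_last = int(np.floor(timing.avc_time * frame_rate - eps))
    # half-open: a sample exactly at AVC is excluded
    if abs(k_last / frame_rate - timing.avc_time) < eps:
        k_last -= 1
    return max(0, k_last - k_first + 1)


def identity_scaled(rest: CardiacTiming, model: PhaseDurationModel) -> CardiacTiming:
    """Rest timing re-labelled as scaled (no-op scaling)."""
    return replace(rest, source="scaled")
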
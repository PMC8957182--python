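"""Mechanical discoordination indices of the septum.

The systolic portion of a septal longitudinal strain curve is decomposed
into alternating shortening and stretching components. From these:

- SRSsept (systolic rebound stretch): the summed positive strain change
  over stretch segments that occur *after* shortening has begun - stretch
  that interrupts shortening, an index of wasted septal work.
- SS (systolic shortening): the absolute summed negative strain change
  over shortening segments - effective work.
- SDI (septal discoordination index): SRSsept / SS, a dimensionless ratio
  of wasted to constructive deformation. Because it is a ratio, SDI is
  insensitive to the global strain-amplitude reduction that higher
  afterload causes during exercise, so only SDI is labelled comparable
  across exercise intensities.

Stretch occurring before the first shortening onset (pre-shortening
stretch, typical of early septal motion in left bundle branch block) is
flagged and excluded from SRSsept by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import StrainCurve
from .errors import UndefinedSDIError, WindowTooShortError

__all__ = [
    "Segment",
    "SystolicSegments",
    "DiscoordinationResult",
    "segment_systole",
    "compute_srs",
    "compute_ss",
    "compute_sdi",
    "analyze_curve",
    "classify_sdi_response",
]


@dataclass(frozen=True)
class Segment:
    """One monotone run of the systolic strain curve."""

    kind: str  # "shortening" | "stretch"
    start: int  # sample index (within the systolic window) of run start
    end: int  # sample index of run end (inclusive)
    change: float  # signed strain change over the run, %
    pre_shortening: bool = False  # stretch before the first shortening onset


@dataclass
class SystolicSegments:
    """Decomposition of the closed systolic window into sign runs.

    ``indices`` are the curve sample indices of the systolic window; the
    segment start/end fields index into that window.
    """

    segments: list[Segment]
    indices: np.ndarray
    strain: np.ndarray  # systolic strain samples, %

    @property
    def pre_shortening_stretch(self) -> float:
        """Total stretch before the first shortening onset, %."""
        return sum(
            s.change for s in self.segments if s.kind == "stretch" and s.pre_shortening
        )

    @property
    def n_rebound_segments(self) -> int:
        return sum(
            1 for s in self.segments if s.kind == "stretch" and not s.pre_shortening
        )


@dataclass(frozen=True)
class DiscoordinationResult:
    """SRSsept, SS and SDI for one strain curve."""

    srs_sept: float
    ss: float
    sdi: float
    n_rebound_segments: int

    def to_dict(self) -> dict:
        return {
            "srs_sept": self.srs_sept,
            "ss": self.ss,
            "sdi": self.sdi,
            "n_rebound_segments": self.n_rebound_segments,
        }


def segment_systole(curve: StrainCurve, noise_floor: float = 0.0) -> SystolicSegments:
    """Group the systolic strain samples into shortening/stretch runs.

    Consecutive sample increments of equal sign are merged into one
    segment; zero increments (and increments with magnitude below
    ``noise_floor``) extend the preceding segment. The default
    ``noise_floor = 0`` is the literal definition: every increment counts.
    Segment ``change`` always sums the raw increments, so the telescoping
    identity SS - (SRS + pre-shortening stretch) = -(strain(AVC) -
    strain(MVC)) holds exactly regardless of the floor.
    """
    idx = curve.systolic_indices()
    if len(idx) < 3:
        raise WindowTooShortError(
            f"systolic window holds {len(idx)} samples; need >= 3"
        )
    y = curve.strain[idx]
    dy = np.diff(y)
    # sign classification with dead zone; 0 = extend previous run
    sign = np.where(dy > noise_floor, 1, np.where(dy < -noise_floor, -1, 0))

    segments: list[Segment] = []
    seen_shortening = False
    run_sign = 0
    run_start = 0
    run_sum = 0.0

    def close_run(end_sample: int) -> None:
        nonlocal seen_shortening
        if run_sign == 0:
            return
        kind = "stretch" if run_sign > 0 else "shortening"
        pre = kind == "stretch" and not seen_shortening
        segments.append(
            Segment(kind=kind, start=run_start, end=end_sample, change=run_sum, pre_shortening=pre)
        )
        if kind == "shortening":
            seen_shortening = True

    for k, (s, d) in enumerate(zip(sign, dy)):
        if s != 0 and s != run_sign:
            if run_sign != 0:
                close_run(k)
                run_start = k
                run_sum = 0.0
            # leading sub-floor increments fold into the first real run
            run_sign = int(s)
        run_sum += float(d)
    close_run(len(dy))

    return SystolicSegments(segments=segments, indices=idx, strain=y)


def compute_srs(segments: SystolicSegments, include_pre_stretch: bool = False) -> float:
    """Systolic rebound stretch: summed stretch after shortening onset, %.

    ``include_pre_stretch=True`` switches to counting all systolic stretch.
    """
    total = 0.0
    for s in segments.segments:
        if s.kind != "stretch":
            continue
        if s.pre_shortening and not include_pre_stretch:
            continue
        total += s.change
    return max(0.0, total)


def compute_ss(segments: SystolicSegments) -> float:
    """Systolic shortening: absolute summed shortening during systole, %."""
    return -sum(s.change for s in segments.segments if s.kind == "shortening")


def compute_sdi(srs: float, ss: float) -> float:
    """Septal discoordination index SRSsept / SS (dimensionless)."""
    if srs < 0 or ss < 0:
        raise ValueError("srs and ss must be non-negative")
    if ss == 0:
        raise UndefinedSDIError("SDI undefined: systolic shortening is zero")
    return srs / ss


def analyze_curve(
    curve: StrainCurve,
    noise_floor: float = 0.0,
    include_pre_stretch: bool = False,
) -> DiscoordinationResult:
    """Full decomposition of one curve into SRSsept, SS and SDI."""
    segs = segment_systole(curve, noise_floor=noise_floor)
    srs = compute_srs(segs, include_pre_stretch=include_pre_stretch)
    ss = compute_ss(segs)
    sdi = compute_sdi(srs, ss)
    return DiscoordinationResult(
        srs_sept=srs, ss=ss, sdi=sdi, n_rebound_segments=segs.n_rebound_segments
    )


def classify_sdi_response(rest_sdi: float, sdi_30: float, sdi_60: float) -> str:
    """Classify the exercise-induced SDI response relative to rest.

    Improvement at an intensity means SDI below the resting value. Both
    intensities improved -> ``consistent_improvement``; both worsened (or
    unchanged, counted conservatively as worsening) ->
    ``consistent_worsening``; otherwise ``reciprocal``.
    """
    for v in (rest_sdi, sdi_30, sdi_60):
        if v is None or not np.isfinite(v):
            raise UndefinedSDIError("all three SDI values must be defined")
    improved_30 = sdi_30 < rest_sdi
    improved_60 = sdi_60 < rest_sdi
    if improved_30 and improved_60:
        return "consistent_improvement"
    if not improved_30 and not improved_60:
        return "consistent_worsening"
    return "reciprocal"
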
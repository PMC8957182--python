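"""Septal longitudinal strain curves.

A :class:`StrainCurve` holds uniformly sampled longitudinal strain (in %,
negative = shortening) for one cardiac cycle, referenced to zero at the
first frame, together with the valve timing that bounds systole.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .timing import CardiacTiming

__all__ = ["StrainCurve"]


@dataclass
class StrainCurve:
    """Longitudinal strain versus time for one cardiac cycle.

    Attributes
    ----------
    time:
        Sample times in seconds, uniformly spaced at the frame interval.
    strain:
        Strain in percent; negative values are shortening. Zero at the
        reference (first) frame.
    timing:
        Valve timing delimiting the systolic window [MVC, AVC].
    """

    time: np.ndarray
    strain: np.ndarray
    timing: CardiacTiming

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.strain.shape:
            raise ValueError("time and strain must be 1-D arrays of equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - dt[0]) > 1e-6):
                raise ValueError("sampling must be uniform (within 1e-6 s)")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt if self.dt > 0 else float("nan")

    @property
    def heart_rate(self) -> float:
        return self.timing.heart_rate

    def systolic_indices(self) -> np.ndarray:
        """Sample indices inside the closed systolic window [MVC, AVC]."""
        eps = 1e-9
        mask = (self.time >= self.timing.mvc_time - eps) & (
            self.time <= self.timing.avc_time + eps
        )
        return np.nonzero(mask)[0]

    def systolic_strain(self) -> np.ndarray:
        return self.strain[self.systolic_indices()]

    def scaled(self, factor: float) -> "StrainCurve":
        """Curve with strain amplitude multiplied by ``factor``."""
        return replace(self, strain=self.strain * factor)

    def resampled(self, n_samples: int) -> "StrainCurve":
        """Linear resampling of the cycle to ``n_samples`` points.

        Timing is preserved; only the sample grid changes.
        """
        if n_samples < 2:
            raise ValueError("need at least 2 samples")
        new_time = np.linspace(self.time[0], self.time[-1], n_samples)
        new_strain = np.interp(new_time, self.time, self.strain)
        return StrainCurve(time=new_time, strain=new_strain, timing=self.timing)
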
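"""Synthetic septal strain data with known ground truth.

No public dataset of exercise septal cine-loops exists, so every
downstream stage is exercised against synthetic data built here:

1. *Strain curves* with prescribed systolic shortening (SS), systolic
   rebound stretch (SRS), pre-shortening stretch and post-systolic
   behaviour. Curves are piecewise smooth (cubic smoothstep segments
   between knots placed exactly on the frame grid), so decomposing the
   sampled curve into sign runs recovers the targets to machine
   precision.
2. *Speckle cine-loops*: a curved septal band of random point
   scatterers rendered with a Gaussian point-spread function, advected
   frame-by-frame by the ground-truth deformation, with additive noise
   and optional frame occlusions ("dropout") emulating the image-quality
   degradation of exercise imaging.
3. *Cohorts*: subjects x 2 visits x exercise intensities, with
   subject-level baseline parameters and independent per-visit
   perturbations emulating physiological test-retest variability.

The deformation model stretches the band's centerline arc by the
longitudinal stretch ratio lambda(t) = 1 + strain/100 about the mid-arc,
with incompressible thickness compensation (radial offsets divided by
lambda), so ground-truth longitudinal strain along the centerline is
exactly the prescribed curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import StrainCurve
from .discoordination import DiscoordinationResult, analyze_curve
from .errors import (
    InfeasiblePatternError,
    InvalidPatternError,
    OutOfFieldError,
    UndefinedSDIError,
    WindowTooShortError,
)
from .mesh import SeptalMesh
from .timing import (
    CardiacTiming,
    default_phase_model,
    resting_timing,
    scale_timing,
)
from .tracking import ImageSequence

__all__ = [
    "StrainPattern",
    "AcquisitionCondition",
    "SeptalGeometry",
    "GroundTruthCycle",
    "CohortDataset",
    "generate_strain_curve",
    "make_ground_truth",
    "ground_truth_from_curve",
    "synthesize_cine_loop",
    "simulate_cohort",
    "INTENSITY_LEVELS",
    "DEFAULT_HEART_RATES",
    "DEFAULT_DEGRADATION",
]

INTENSITY_LEVELS = ("baseline", "vt30", "vt60", "vt90", "recovery")

# Cohort median heart rates (bpm) per exercise intensity.
DEFAULT_HEART_RATES = {
    "baseline": 60.0,
    "vt30": 79.0,
    "vt60": 90.0,
    "vt90": 97.0,
    "recovery": 78.0,
}

# Intensity -> (noise_level, dropout_fraction). Image degradation rises
# with exercise intensity (body motion, breathing); recovery remains
# degraded by residual motion. Values chosen so that, with the per-loop
# noise jitter applied by the cohort simulator, the good/moderate/poor
# mix shifts toward poor (and exclusions rise) from rest to 90% VT.
DEFAULT_DEGRADATION = {
    "baseline": (0.40, 0.01),
    "vt30": (0.60, 0.03),
    "vt60": (1.00, 0.05),
    "vt90": (1.60, 0.10),
    "recovery": (1.20, 0.07),
}

_FAMILIES = ("lbbb_type", "non_lbbb_type", "custom")
_POST_SYSTOLIC = ("recoil_to_zero", "plateau")

# Exercise modulation of the truth targets. Higher afterload during
# exercise reduces overall systolic strain magnitude (hence the ratio
# index SDI, not raw SRS, is compared across intensities); rebound
# stretch itself responds heterogeneously: most subjects improve
# (coordination recovers during mild/moderate exercise), some worsen,
# a few respond reciprocally at the two intensities.
_SS_EXERCISE_MULT = {
    "baseline": 1.00,
    "vt30": 0.95,
    "vt60": 0.90,
    "vt90": 0.85,
    "recovery": 0.95,
}
_SRS_RESPONSE_MULT = {
    "improve": {"baseline": 1.0, "vt30": 0.40, "vt60": 0.59, "vt90": 0.70, "recovery": 0.85},
    "worsen": {"baseline": 1.0, "vt30": 1.25, "vt60": 1.48, "vt90": 1.60, "recovery": 1.25},
    "reciprocal": {"baseline": 1.0, "vt30": 0.60, "vt60": 1.40, "vt90": 1.40, "recovery": 1.10},
}
_RESPONSE_PROBS = (8 / 15, 4 / 15, 3 / 15)  # improve / worsen / reciprocal


@dataclass(frozen=True)
class StrainPattern:
    """Target morphology of one septal strain curve.

    ``target_ss`` and ``target_srs`` are the systolic shortening and
    rebound stretch (both >= 0, % strain) that the generated curve's
    decomposition must reproduce. ``pre_stretch`` is stretch before the
    first shortening onset (excluded from SRS). ``peak_systolic_strain``
    (negative, %) optionally pins the deepest systolic trough; when
    omitted it is derived from the other targets.
    """

    family: str
    target_ss: float
    target_srs: float = 0.0
    pre_stretch: float = 0.0
    peak_systolic_strain: float | None = None
    post_systolic_behavior: str = "recoil_to_zero"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidPatternError(f"unknown pattern family {self.family!r}")
        if self.post_systolic_behavior not in _POST_SYSTOLIC:
            raise InvalidPatternError(
                f"unknown post-systolic behaviour {self.post_systolic_behavior!r}"
            )
        if self.target_ss < 0 or self.target_srs < 0 or self.pre_stretch < 0:
            raise InvalidPatternError("SS, SRS and pre-stretch must be >= 0")
        if self.family == "non_lbbb_type" and self.target_srs > 0:
            raise InvalidPatternError(
                "non-LBBB pattern has monotone systolic shortening; target_srs must be 0"
            )
        if self.peak_systolic_strain is not None:
            if self.target_ss < abs(self.peak_systolic_strain):
                raise InfeasiblePatternError(
                    "target_ss smaller than |peak_systolic_strain|: trough unreachable"
                )


@dataclass(frozen=True)
class AcquisitionCondition:
    """One acquisition setting (intensity, rate and image degradation)."""

    intensity: str
    heart_rate: float
    frame_rate: float = 90.0
    noise_level: float = 0.0
    dropout_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 50.0 <= self.frame_rate <= 90.0:
            raise ValueError("frame_rate must lie in [50, 90] Hz")
        if self.noise_level < 0 or not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("invalid degradation parameters")

    @classmethod
    def for_intensity(
        cls,
        intensity: str,
        heart_rate: float | None = None,
        frame_rate: float = 90.0,
        degradation: dict | None = None,
    ) -> "AcquisitionCondition":
        table = degradation or DEFAULT_DEGRADATION
        noise, dropout = table.get(intensity, (0.0, 0.0))
        if heart_rate is None:
            heart_rate = DEFAULT_HEART_RATES.get(intensity, 70.0)
        return cls(
            intensity=intensity,
            heart_rate=heart_rate,
            frame_rate=frame_rate,
            noise_level=noise,
            dropout_fraction=dropout,
        )


# ---------------------------------------------------------------------------
# strain-curve generation
# ---------------------------------------------------------------------------


def _systolic_knots(pattern: StrainPattern) -> list[tuple[float, float]]:
    """Knot (time-fraction of systole, strain value) pairs after (0, 0)."""
    ss, srs, pre = pattern.target_ss, pattern.target_srs, pattern.pre_stretch
    if srs <= 0:
        e = pre - ss
        knots = []
        if pre > 0:
            knots.append((0.10, pre))
        if ss > 0:
            knots.append((0.55, pre - 0.65 * ss))
        knots.append((1.0, e))
        return knots

    e = pre + srs - ss  # strain at AVC (telescoping)
    upper = ss - srs / 2.0 - pre
    if pattern.peak_systolic_strain is not None:
        p_depth = abs(pattern.peak_systolic_strain)
        if p_depth < max(0.0, -e) - 1e-9 or p_depth > ss - pre + 1e-9:
            raise InfeasiblePatternError(
                "peak_systolic_strain incompatible with SS/SRS/pre-stretch targets"
            )
    else:
        p_depth = max(-e, 0.6 * ss)
        p_depth = min(max(p_depth, max(0.0, -e)), max(upper, max(0.0, -e)))

    r1 = r2 = srs / 2.0
    d3 = ss - srs / 2.0 - pre - p_depth
    if d3 < 1e-9:
        # deepest trough followed by a final rebound to the AVC value
        r2 = e + p_depth
        r1 = srs - r2
        if r1 < -1e-9 or r2 < -1e-9:
            raise InfeasiblePatternError("rebound split infeasible for these targets")
        r1, r2 = max(r1, 0.0), max(r2, 0.0)
        d3 = 0.0
    d12 = pre + r1 + p_depth
    d1 = min(0.62 * d12, pre + p_depth)
    d2 = d12 - d1
    if d1 <= 1e-9 or d2 < -1e-9:
        raise InfeasiblePatternError("no valid initial shortening for these targets")

    s1 = pre - d1
    s2 = s1 + r1
    s3 = -p_depth
    s4 = s3 + r2
    knots = []
    if pre > 0:
        knots.append((0.08, pre))
    knots.append((0.32, s1))
    if r1 > 1e-9:
        knots.append((0.45, s2))
    knots.append((0.68, s3))
    if r2 > 1e-9:
        knots.append((0.80, s4))
    if d3 > 1e-9:
        knots.append((1.0, e))
    else:
        # promote the last knot to the AVC sample
        frac, val = knots[-1]
        knots[-1] = (1.0, val)
    return knots


def _smoothstep_eval(knot_idx: np.ndarray, knot_val: np.ndarray, n: int) -> np.ndarray:
    """Evaluate cubic-smoothstep segments between integer-sample knots."""
    y = np.empty(n, dtype=float)
    y[: knot_idx[0] + 1] = knot_val[0]
    for (ka, va), (kb, vb) in zip(
        zip(knot_idx[:-1], knot_val[:-1]), zip(knot_idx[1:], knot_val[1:])
    ):
        k = np.arange(ka, kb + 1)
        u = (k - ka) / (kb - ka)
        y[ka : kb + 1] = va + (vb - va) * u * u * (3.0 - 2.0 * u)
    y[knot_idx[-1] :] = knot_val[-1]
    return y


def generate_strain_curve(
    pattern: StrainPattern,
    timing: CardiacTiming,
    frame_rate: float,
    seed: int = 0,
    time_jitter: float = 0.02,
) -> StrainCurve:
    """Generate one septal strain curve matching the pattern targets.

    The curve starts at 0% at MVC (sample 0), is piecewise smooth with
    zero slope at every turning point, and has its turning points placed
    exactly on the frame grid, so the sign-run decomposition of the
    sampled systolic curve reproduces ``target_ss`` / ``target_srs``
    exactly. ``seed`` jitters the knot *times* only (by up to
    ``time_jitter`` of the systolic duration), never the strain targets.
    """
    if not 50.0 <= frame_rate <= 90.0:
        raise ValueError("frame_rate must lie in [50, 90] Hz")
    dt = 1.0 / frame_rate
    if timing.mvc_time > dt / 2:
        raise ValueError("generator requires MVC at the first frame (mvc_time ~ 0)")
    n = int(round(timing.cycle_length * frame_rate))
    k_end = int(math.floor(timing.avc_time * frame_rate + 1e-9))
    if k_end >= n - 2:
        raise InfeasiblePatternError("systole leaves no room for diastole")

    knots = _systolic_knots(pattern)
    rng = np.random.default_rng(seed)
    jit = rng.uniform(-time_jitter, time_jitter, size=len(knots))
    jit[-1] = 0.0  # AVC knot stays put

    idx = [0]
    val = [0.0]
    for (frac, v), j in zip(knots, jit):
        idx.append(int(round(min(max(frac + j, 0.02), 1.0) * k_end)))
        val.append(v)
    # enforce strictly increasing sample indices
    for i in range(1, len(idx)):
        if idx[i] <= idx[i - 1]:
            idx[i] = idx[i - 1] + 1
    if idx[-1] > k_end:
        raise WindowTooShortError(
            f"systolic window of {k_end + 1} samples cannot hold {len(idx)} knots"
        )
    idx[-1] = k_end
    for i in range(len(idx) - 2, 0, -1):
        if idx[i] >= idx[i + 1]:
            idx[i] = idx[i + 1] - 1
    if idx[0] != 0 or idx[1] <= 0:
        raise WindowTooShortError("systolic window too short for the knot layout")

    # diastolic return
    e = val[-1]
    rest = (n - 1) - k_end
    if pattern.post_systolic_behavior == "recoil_to_zero":
        k_zero = k_end + max(1, int(round(0.45 * rest)))
        if k_zero < n - 1:
            idx += [k_zero, n - 1]
            val += [0.0, 0.0]
        else:
            idx += [n - 1]
            val += [0.0]
    else:  # plateau: hold the end-systolic value, late rapid recoil
        k_hold = k_end + max(1, int(round(0.6 * rest)))
        if k_hold < n - 1:
            idx += [k_hold, n - 1]
            val += [e, 0.0]
        else:
            idx += [n - 1]
            val += [0.0]

    strain = _smoothstep_eval(np.asarray(idx), np.asarray(val, dtype=float), n)
    time = np.arange(n) / frame_rate
    return StrainCurve(time=time, strain=strain, timing=timing)


# ---------------------------------------------------------------------------
# geometry and ground-truth kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeptalGeometry:
    """Annular-band model of the septum in the image plane.

    The band is the set of points at distance ``radius + r`` from
    ``center`` (|r| <= thickness/2) over an angular span of
    ``arc_span`` radians centred on ``angle_center``.
    """

    center: tuple[float, float]
    radius: float
    angle_center: float
    arc_span: float
    thickness: float

    @classmethod
    def for_image(cls, width: int = 800, height: int = 600) -> "SeptalGeometry":
        return cls(
            center=(width * 0.5, height * 0.93),
            radius=height * 0.55,
            angle_center=-np.pi / 2,
            arc_span=1.1,
            thickness=height * 0.055,
        )

    def to_xy(
        self, theta: np.ndarray, r: np.ndarray, strain_pct: float = 0.0
    ) -> np.ndarray:
        """Map band coordinates (theta, r) to (x, y) under deformation.

        The arc is stretched by lambda = 1 + strain/100 about the
        mid-arc angle; radial offsets shrink by 1/lambda (area
        preservation).
        """
        lam = 1.0 + strain_pct / 100.0
        th = self.angle_center + lam * (np.asarray(theta) - self.angle_center)
        rad = self.radius + np.asarray(r) / lam
        x = self.center[0] + rad * np.cos(th)
        y = self.center[1] + rad * np.sin(th)
        return np.stack([x, y], axis=-1)

    def band_polygon(self, n_arc: int = 48, inflate: float = 1.0) -> np.ndarray:
        """Closed outline of the undeformed band (outer arc + inner arc)."""
        th = np.linspace(
            self.angle_center - self.arc_span / 2,
            self.angle_center + self.arc_span / 2,
            n_arc,
        )
        half = self.thickness / 2 + inflate
        outer = self.to_xy(th, np.full_like(th, half))
        inner = self.to_xy(th[::-1], np.full_like(th, -half))
        return np.concatenate([outer, inner], axis=0)

    def analytic_mesh(
        self, n_radial: int = 11, n_longitudinal: int = 31, inset: float = 0.8
    ) -> tuple[SeptalMesh, np.ndarray, np.ndarray]:
        """Reference-frame mesh plus its band coordinates (theta, r)."""
        th = np.linspace(
            self.angle_center - self.arc_span / 2,
            self.angle_center + self.arc_span / 2,
            n_longitudinal,
        )
        rr = np.linspace(
            -(self.thickness / 2 - inset), self.thickness / 2 - inset, n_radial
        )
        tgrid, rgrid = np.meshgrid(th, rr)
        points = self.to_xy(tgrid, rgrid)
        mesh = SeptalMesh.from_grid(points, self.band_polygon())
        return mesh, tgrid, rgrid


@dataclass
class GroundTruthCycle:
    """A generated cycle: strain curve, mesh kinematics and indices."""

    strain_curve: StrainCurve
    timing: CardiacTiming
    geometry: SeptalGeometry
    mesh: SeptalMesh
    mesh_theta: np.ndarray
    mesh_r: np.ndarray
    mesh_trajectory: np.ndarray | None
    analytic_indices: DiscoordinationResult | None
    pattern: StrainPattern | None = None

    @property
    def segmentation(self) -> np.ndarray:
        return self.mesh.segmentation

    @property
    def n_frames(self) -> int:
        return self.strain_curve.n_samples


def ground_truth_from_curve(
    curve: StrainCurve,
    geometry: SeptalGeometry | None = None,
    image_size: tuple[int, int] = (800, 600),
    pattern: StrainPattern | None = None,
    with_trajectory: bool = True,
) -> GroundTruthCycle:
    """Build mesh kinematics and analytic indices for a given curve."""
    geometry = geometry or SeptalGeometry.for_image(*image_size)
    mesh, tgrid, rgrid = geometry.analytic_mesh()
    trajectory = None
    if with_trajectory:
        trajectory = np.stack(
            [geometry.to_xy(tgrid, rgrid, s) for s in curve.strain], axis=0
        )
    try:
        indices = analyze_curve(curve)
    except (UndefinedSDIError, WindowTooShortError):
        indices = None
    return GroundTruthCycle(
        strain_curve=curve,
        timing=curve.timing,
        geometry=geometry,
        mesh=mesh,
        mesh_theta=tgrid,
        mesh_r=rgrid,
        mesh_trajectory=trajectory,
        analytic_indices=indices,
        pattern=pattern,
    )


def make_ground_truth(
    pattern: StrainPattern,
    timing: CardiacTiming,
    frame_rate: float,
    geometry: SeptalGeometry | None = None,
    image_size: tuple[int, int] = (800, 600),
    seed: int = 0,
    with_trajectory: bool = True,
) -> GroundTruthCycle:
    """Generate a strain curve and its full mesh ground truth."""
    curve = generate_strain_curve(pattern, timing, frame_rate, seed=seed)
    return ground_truth_from_curve(
        curve,
        geometry=geometry,
        image_size=image_size,
        pattern=pattern,
        with_trajectory=with_trajectory,
    )


# ---------------------------------------------------------------------------
# speckle cine-loop synthesis
# ---------------------------------------------------------------------------


def _splat_gaussians(
    xs: np.ndarray,
    ys: np.ndarray,
    amps: np.ndarray,
    shape: tuple[int, int],
    sigma: float,
    radius: int,
) -> np.ndarray:
    """Render point scatterers with an exact sub-pixel Gaussian PSF."""
    h, w = shape
    xi = np.round(xs).astype(np.int64)
    yi = np.round(ys).astype(np.int64)
    offs = np.arange(-radius, radius + 1)
    dx = offs[None, :] - (xs - xi)[:, None]
    dy = offs[None, :] - (ys - yi)[:, None]
    gx = np.exp(-(dx**2) / (2.0 * sigma**2))
    gy = np.exp(-(dy**2) / (2.0 * sigma**2))
    patch = amps[:, None, None] * gy[:, :, None] * gx[:, None, :]
    rows = (yi[:, None] + offs[None, :])[:, :, None] + np.zeros(
        (1, 1, len(offs)), dtype=np.int64
    )
    cols = (xi[:, None] + offs[None, :])[:, None, :] + np.zeros(
        (1, len(offs), 1), dtype=np.int64
    )
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    flat = rows[ok] * w + cols[ok]
    img = np.bincount(flat, weights=patch[ok], minlength=h * w)
    return img.reshape(h, w)


def synthesize_cine_loop(
    truth: GroundTruthCycle,
    condition: AcquisitionCondition,
    image_size: tuple[int, int] = (800, 600),
    seed: int = 0,
    n_scatterers: int = 2000,
    n_background: int = 3000,
    psf_sigma: float = 2.0,
) -> ImageSequence:
    """Render a speckle cine-loop deformed by the ground-truth cycle.

    Frame 0 shows the undeformed septal band; every later frame is the
    same scatterer field advected by the deformation at that frame's
    strain value, plus Gaussian noise of standard deviation
    ``noise_level`` times the noise-free signal SD. A fraction
    ``dropout_fraction`` of frames (never frame 0) receives a randomly
    placed occlusion disc zeroing part of the septum.
    """
    if truth.mesh_trajectory is None:
        raise ValueError("ground truth lacks a mesh trajectory")
    w, h = image_size
    traj = truth.mesh_trajectory
    if (
        traj[..., 0].min() < 1
        or traj[..., 0].max() > w - 2
        or traj[..., 1].min() < 1
        or traj[..., 1].max() > h - 2
    ):
        raise OutOfFieldError("mesh trajectory leaves the image bounds")

    geom = truth.geometry
    rng = np.random.default_rng(seed)
    theta = rng.uniform(
        geom.angle_center - geom.arc_span / 2,
        geom.angle_center + geom.arc_span / 2,
        n_scatterers,
    )
    r = rng.uniform(-geom.thickness / 2, geom.thickness / 2, n_scatterers)
    amps = rng.rayleigh(1.0, n_scatterers)

    bg_xy_x = rng.uniform(0, w, n_background)
    bg_xy_y = rng.uniform(0, h, n_background)
    bg_amp = 0.12 * rng.rayleigh(1.0, n_background)
    radius = max(3, int(np.ceil(3.0 * psf_sigma)))
    background = _splat_gaussians(bg_xy_x, bg_xy_y, bg_amp, (h, w), psf_sigma, radius)

    n_frames = truth.n_frames
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for k, strain in enumerate(truth.strain_curve.strain):
        xy = geom.to_xy(theta, r, strain)
        img = _splat_gaussians(
            xy[:, 0], xy[:, 1], amps, (h, w), psf_sigma, radius
        )
        frames[k] = (img + background).astype(np.float32)
    scale = float(frames.max())
    if scale > 0:
        frames /= scale

    if condition.noise_level > 0:
        sigma_ref = float(frames.std())
        frames += rng.normal(
            0.0, condition.noise_level * sigma_ref, frames.shape
        ).astype(np.float32)

    n_drop = int(round(condition.dropout_fraction * n_frames))
    if condition.dropout_fraction > 0:
        n_drop = max(1, n_drop)
    if n_drop > 0 and n_frames > 1:
        drop_frames = rng.choice(np.arange(1, n_frames), size=min(n_drop, n_frames - 1), replace=False)
        arc_len = geom.arc_span * geom.radius
        yy, xx = np.mgrid[0:h, 0:w]
        for fidx in np.sort(drop_frames):
            occ_radius = rng.uniform(0.06, 0.16) * arc_len
            th_c = rng.uniform(
                geom.angle_center - geom.arc_span / 2,
                geom.angle_center + geom.arc_span / 2,
            )
            cx, cy = geom.to_xy(np.array(th_c), np.array(0.0), truth.strain_curve.strain[fidx])
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 < occ_radius**2
            frames[fidx][mask] = 0.0

    return ImageSequence(
        frames=frames,
        frame_rate=condition.frame_rate,
        pixel_spacing=0.30,
        )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """A simulated multi-visit cohort with its manifest."""

    manifest: pd.DataFrame
    truths: dict[tuple[int, int, str], GroundTruthCycle]
    images: dict[tuple[int, int, str], ImageSequence] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _subject_heart_rates(rng: np.random.Generator, intensities: list[str]) -> dict:
    """Monotone-in-intensity heart rates for one subject (bpm)."""
    rest = rng.normal(60.0, 5.0)
    rest = float(np.clip(rest, 50.0, 75.0))
    hr = {
        "baseline": rest,
        "vt30": rest + rng.uniform(12.0, 22.0),
        "vt60": None,
        "vt90": None,
        "recovery": rest + rng.uniform(10.0, 28.0),
    }
    hr["vt60"] = hr["vt30"] + rng.uniform(6.0, 14.0)
    hr["vt90"] = hr["vt60"] + rng.uniform(4.0, 12.0)
    out = {}
    for name in intensities:
        if name in hr:
            out[name] = float(hr[name])
        else:
            out[name] = float(DEFAULT_HEART_RATES.get(name, 70.0) + rng.normal(0, 3))
    return out


def simulate_cohort(
    n_subjects: int,
    conditions: list[AcquisitionCondition] | list[str] | None = None,
    visit_noise_sd: float = 1.0,
    observer_noise_sd: float = 0.5,
    seed: int = 0,
    lbbb_fraction: float = 0.44,
    frame_rate: float = 90.0,
    image_size: tuple[int, int] = (800, 600),
    synthesize_images: bool = False,
    srs_range: tuple[float, float] = (2.5, 5.5),
    ss_range: tuple[float, float] = (10.0, 18.0),
) -> CohortDataset:
    """Simulate a two-visit exercise-echo cohort with known truth.

    Each subject carries base strain targets (SS, and SRS when the
    subject has an LBBB-type pattern); each visit's targets are the base
    plus independent zero-mean Gaussian noise of SD ``visit_noise_sd``
    (physiological day-to-day variability), so the test-retest difference
    of a truth parameter has SD sqrt(2) x ``visit_noise_sd``.
    ``observer_noise_sd`` is recorded for the analysis stage, which adds
    independent reading noise per observer.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if visit_noise_sd < 0 or observer_noise_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    if conditions is None:
        conditions = list(INTENSITY_LEVELS)
    cond_objs: list[AcquisitionCondition] = []
    for c in conditions:
        if isinstance(c, str):
            cond_objs.append(AcquisitionCondition.for_intensity(c, frame_rate=frame_rate))
        else:
            cond_objs.append(c)

    rng = np.random.default_rng(seed)
    model = default_phase_model()
    rows = []
    truths: dict[tuple[int, int, str], GroundTruthCycle] = {}
    images: dict[tuple[int, int, str], ImageSequence] = {}

    for subj in range(n_subjects):
        is_lbbb = rng.random() < lbbb_fraction
        base_ss = rng.uniform(*ss_range)
        base_srs = rng.uniform(*srs_range) if is_lbbb else 0.0
        response = ("improve", "worsen", "reciprocal")[
            int(rng.choice(3, p=_RESPONSE_PROBS))
        ]
        hr_map = _subject_heart_rates(rng, [c.intensity for c in cond_objs])
        rest_hr = hr_map.get("baseline", 60.0)
        rest = resting_timing(rest_hr, model=model)
        for visit in (1, 2):
            ss_v = base_ss + rng.normal(0.0, visit_noise_sd)
            srs_v = base_srs + rng.normal(0.0, visit_noise_sd) if is_lbbb else 0.0
            srs_v = max(0.0, srs_v)
            hr_shift = float(np.clip(rng.normal(0.0, 3.0), -8.0, 8.0))
            family = "lbbb_type" if is_lbbb else "non_lbbb_type"
            for cond in cond_objs:
                ss_c = ss_v * _SS_EXERCISE_MULT.get(cond.intensity, 1.0)
                srs_c = srs_v * _SRS_RESPONSE_MULT[response].get(cond.intensity, 1.0)
                ss_c = max(ss_c, srs_c + 2.0, 5.0)
                pattern = StrainPattern(
                    family=family,
                    target_ss=ss_c,
                    target_srs=srs_c if is_lbbb else 0.0,
                )
                hr = float(np.clip(hr_map[cond.intensity] + hr_shift, 50.0, 128.0))
                timing = scale_timing(rest, hr, model)
                loop_seed = int(rng.integers(0, 2**31))
                truth = make_ground_truth(
                    pattern,
                    timing,
                    cond.frame_rate,
                    image_size=image_size,
                    seed=loop_seed,
                    with_trajectory=synthesize_images,
                )
                key = (subj, visit, cond.intensity)
                truths[key] = truth
                # per-loop acquisition variability: the configured noise level
                # is the intensity's median, individual loops scatter around it
                loop_noise = cond.noise_level * float(rng.lognormal(0.0, 0.35))
                loop_cond = AcquisitionCondition(
                    intensity=cond.intensity,
                    heart_rate=hr,
                    frame_rate=cond.frame_rate,
                    noise_level=loop_noise,
                    dropout_fraction=cond.dropout_fraction,
                )
                if synthesize_images:
                    images[key] = synthesize_cine_loop(
                        truth, loop_cond, image_size=image_size, seed=loop_seed
                    )
                idx = truth.analytic_indices
                rows.append(
                    {
                        "subject": subj,
                        "visit": visit,
                        "intensity": cond.intensity,
                        "heart_rate": hr,
                        "frame_rate": cond.frame_rate,
                        "noise_level": loop_noise,
                        "dropout_fraction": cond.dropout_fraction,
                        "loop_seed": loop_seed,
                        "family": family,
                        "response": response,
                        "truth_ss": idx.ss if idx else np.nan,
                        "truth_srs": idx.srs_sept if idx else np.nan,
                        "truth_sdi": idx.sdi if idx else np.nan,
                    }
                )

    manifest = pd.DataFrame(rows)
    params = {
        "n_subjects": n_subjects,
        "conditions": [c.intensity for c in cond_objs],
        "visit_noise_sd": visit_noise_sd,
        "observer_noise_sd": observer_noise_sd,
        "seed": seed,
        "lbbb_fraction": lbbb_fraction,
        "frame_rate": frame_rate,
        "image_size": list(image_size),
        "synthesize_images": synthesize_images,
    }
    return CohortDataset(manifest=manifest, truths=truths, images=images, params=params)
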
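"""End-to-end study pipeline.

Orchestrates simulate -> track -> time-scale -> discoordination indices
-> agreement statistics, mirroring the structure of a two-visit exercise
echocardiography reproducibility study: a cohort of subjects is imaged
at rest, three exercise intensities and recovery on two visits; loops
are quality-graded and excluded when the septum is not trackable; SRSsept
and SDI are measured by two observers (one reading twice); and the
report collects feasibility tallies, Bland-Altman / ICC agreement per
condition, and the classification of exercise-induced SDI changes.

Everything is driven by a serializable :class:`RunConfig`; a fixed seed
makes the whole run bit-reproducible, and the config hash is embedded in
the report provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from .discoordination import analyze_curve, classify_sdi_response
from .errors import (
    SegmentationError,
    SeptostrainError,
    StrainUndefinedError,
    TrackingFailureError,
    UndefinedKappaError,
    UndefinedSDIError,
)
from .mesh import build_mesh
from .synthetic import (
    INTENSITY_LEVELS,
    AcquisitionCondition,
    simulate_cohort,
)
from .tracking import accumulate_strain, estimate_displacements, grade_quality

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "analyze_existing"]

_METRICS = ("srs", "sdi")
_CONTEXTS = ("test_retest", "intra_observer", "inter_observer")


@dataclass
class RunConfig:
    """Full parameterization of a pipeline run."""

    seed: int = 0
    n_subjects: int = 12
    conditions: list[str] = field(default_factory=lambda: list(INTENSITY_LEVELS))
    visit_noise_sd: float = 1.0
    observer_noise_sd: float = 0.5
    lbbb_fraction: float = 0.44
    frame_rate: float = 90.0
    image_size: tuple[int, int] = (800, 600)
    analytic_only: bool = False
    noise_level: float | None = None  # global degradation override
    dropout_fraction: float | None = None
    block_size: int = 21
    search_radius: int = 10
    corr_threshold: float = 0.4
    out_dir: str | None = None
    make_plots: bool = False
    verbosity: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class StudyReport:
    """Aggregated results of one pipeline run."""

    feasibility: pd.DataFrame
    agreement: dict  # metric -> context -> condition -> report dict
    sdi_response: dict
    per_loop: list[dict]
    excluded: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return _jsonify(
            {
                "feasibility": self.feasibility.to_dict(orient="records"),
                "agreement": self.agreement,
                "sdi_response": self.sdi_response,
                "per_loop": self.per_loop,
                "excluded": self.excluded,
                "provenance": self.provenance,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "report.json"
        path.write_text(self.to_json())
        self.feasibility.to_csv(out_dir / "feasibility.csv", index=False)
        pd.DataFrame(self.per_loop).to_csv(out_dir / "per_loop.csv", index=False)
        return path


def _measure_loop(cohort, key, config: RunConfig) -> dict:
    """Track one loop (or take its analytic indices) and grade quality."""
    truth = cohort.truths[key]
    out: dict = {
        "subject": key[0],
        "visit": key[1],
        "intensity": key[2],
        "excluded": False,
        "exclusion_reason": None,
        "grade": "good",
    }
    if config.analytic_only:
        idx = truth.analytic_indices
        if idx is None:
            out.update(excluded=True, exclusion_reason="undefined analytic indices")
            return out
        out.update(srs=idx.srs_sept, ss=idx.ss, sdi=idx.sdi)
        return out
    seq = cohort.images[key]
    try:
        mesh = build_mesh(truth.segmentation)
        fld = estimate_displacements(
            seq,
            mesh,
            block_size=config.block_size,
            search_radius=config.search_radius,
            corr_threshold=config.corr_threshold,
        )
        quality = grade_quality(seq, fld)
        out["grade"] = quality.grade
        out["component_scores"] = quality.component_scores
        if quality.excluded:
            out.update(
                excluded=True,
                exclusion_reason="incomplete view of the septum (invalid-match rule)",
            )
            return out
        curve = accumulate_strain(
            fld, mesh, timing=truth.timing, frame_rate=seq.frame_rate
        )
        idx = analyze_curve(curve)
        out.update(srs=idx.srs_sept, ss=idx.ss, sdi=idx.sdi)
    except (SegmentationError, TrackingFailureError, StrainUndefinedError, UndefinedSDIError) as exc:
        out.update(
            excluded=True,
            exclusion_reason=f"{type(exc).__name__}: {exc}",
            grade=out.get("grade") if "component_scores" in out else None,
        )
    return out


def _observer_readings(
    measured: dict, config: RunConfig, rng: np.random.Generator
) -> dict:
    """Per-(observer, reading) indices with additive reading noise.

    Observer variability in the study design stems from independent
    cycle selection and re-segmentation; it is modelled here as additive
    zero-mean noise of SD ``observer_noise_sd`` on SRS and SS (SDI is
    recomputed from the noisy pair).
    """
    readings = {}
    for obs, reading in (("A", 1), ("A", 2), ("B", 1)):
        srs = measured["srs"] + rng.normal(0.0, config.observer_noise_sd)
        ss = measured["ss"] + rng.normal(0.0, config.observer_noise_sd)
        srs = max(0.0, srs)
        ss = max(ss, 0.5)
        readings[(obs, reading)] = {"srs": srs, "ss": ss, "sdi": srs / ss}
    return readings


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full synthetic study and aggregate its report."""
    conditions = []
    for name in config.conditions:
        cond = AcquisitionCondition.for_intensity(name, frame_rate=config.frame_rate)
        if config.noise_level is not None or config.dropout_fraction is not None:
            cond = AcquisitionCondition(
                intensity=cond.intensity,
                heart_rate=cond.heart_rate,
                frame_rate=cond.frame_rate,
                noise_level=(
                    config.noise_level
                    if config.noise_level is not None
                    else cond.noise_level
                ),
                dropout_fraction=(
                    config.dropout_fraction
                    if config.dropout_fraction is not None
                    else cond.dropout_fraction
                ),
            )
        conditions.append(cond)

    cohort = simulate_cohort(
        n_subjects=config.n_subjects,
        conditions=conditions,
        visit_noise_sd=config.visit_noise_sd,
        observer_noise_sd=config.observer_noise_sd,
        seed=config.seed,
        lbbb_fraction=config.lbbb_fraction,
        frame_rate=config.frame_rate,
        image_size=config.image_size,
        synthesize_images=not config.analytic_only,
    )

    obs_rng = np.random.default_rng([config.seed, 0x5EB7])
    per_loop: list[dict] = []
    excluded: list[dict] = []
    results: dict[tuple, dict] = {}
    for key in sorted(cohort.truths.keys()):
        rec = _measure_loop(cohort, key, config)
        if not rec["excluded"]:
            rec["readings"] = _observer_readings(rec, config, obs_rng)
        else:
            # keep the generator stream aligned across runs with the same seed
            obs_rng.normal(0.0, config.observer_noise_sd, size=6)
            excluded.append(
                {k: rec[k] for k in ("subject", "visit", "intensity", "exclusion_reason")}
            )
        results[key] = rec
        per_loop.append(
            {
                k: rec.get(k)
                for k in (
                    "subject", "visit", "intensity", "grade", "excluded",
                    "exclusion_reason", "srs", "ss", "sdi",
                )
            }
        )

    # ---- feasibility accounting ------------------------------------------
    feas_rows = []
    for key, rec in results.items():
        other = (key[0], 3 - key[1], key[2])
        feas_rows.append(
            {
                "condition": key[2],
                "acquired": True,
                "attended_both_visits": other in results,
                "sufficient_quality": not rec["excluded"],
                "grade": rec.get("grade") if not rec["excluded"] else rec.get("grade"),
            }
        )
    feasibility = agr.feasibility_tally(pd.DataFrame(feas_rows))

    # ---- paired agreement -------------------------------------------------
    def _reading(key, obs, nr, metric):
        rec = results.get(key)
        if rec is None or rec["excluded"]:
            return np.nan
        return rec["readings"][(obs, nr)][metric]

    agreement: dict = {m: {c: {} for c in _CONTEXTS} for m in _METRICS}
    subjects = sorted({k[0] for k in results})
    for cond in config.conditions:
        for metric in _METRICS:
            pairings = {
                "test_retest": (
                    [_reading((s, 1, cond), "A", 1, metric) for s in subjects],
                    [_reading((s, 2, cond), "A", 1, metric) for s in subjects],
                ),
                "intra_observer": (
                    [_reading((s, 1, cond), "A", 1, metric) for s in subjects],
                    [_reading((s, 1, cond), "A", 2, metric) for s in subjects],
                ),
                "inter_observer": (
                    [_reading((s, 1, cond), "A", 1, metric) for s in subjects],
                    [_reading((s, 1, cond), "B", 1, metric) for s in subjects],
                ),
            }
            for context, (a, b) in pairings.items():
                try:
                    pairs = agr.PairedMeasurements(
                        value_a=np.asarray(a),
                        value_b=np.asarray(b),
                        subject_ids=np.asarray(subjects),
                        condition=cond,
                        context=context,
                    )
                    report = agr.agreement_report(pairs)
                    agreement[metric][context][cond] = report.to_dict()
                except SeptostrainError as exc:
                    agreement[metric][context][cond] = {"error": str(exc)}

    # ---- exercise-induced SDI response ------------------------------------
    sdi_response: dict = {"counts": {}, "kappa_30_vs_60": {}}
    needed = {"baseline", "vt30", "vt60"}
    if needed.issubset(set(config.conditions)):
        labels = []
        improve = {"A": {"vt30": [], "vt60": []}, "B": {"vt30": [], "vt60": []}}
        for s in subjects:
            vals = {
                c: _reading((s, 1, c), "A", 1, "sdi")
                for c in ("baseline", "vt30", "vt60")
            }
            if not all(np.isfinite(v) for v in vals.values()):
                continue
            labels.append(
                classify_sdi_response(vals["baseline"], vals["vt30"], vals["vt60"])
            )
            for obs in ("A", "B"):
                rest = _reading((s, 1, "baseline"), obs, 1, "sdi")
                for c in ("vt30", "vt60"):
                    v = _reading((s, 1, c), obs, 1, "sdi")
                    if np.isfinite(rest) and np.isfinite(v):
                        # zero change counts as worsening (conservative)
                        improve[obs][c].append("improved" if v < rest else "worsened")
        for kind in ("consistent_improvement", "consistent_worsening", "reciprocal"):
            sdi_response["counts"][kind] = int(labels.count(kind))
        for obs in ("A", "B"):
            a, b = improve[obs]["vt30"], improve[obs]["vt60"]
            if len(a) >= 2 and len(a) == len(b):
                try:
                    sdi_response["kappa_30_vs_60"][obs] = agr.cohen_kappa(a, b)
                except UndefinedKappaError:
                    sdi_response["kappa_30_vs_60"][obs] = None

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "package": "septostrain",
    }
    # strip non-serializable reading dicts from per_loop output
    report = StudyReport(
        feasibility=feasibility,
        agreement=agreement,
        sdi_response=sdi_response,
        per_loop=per_loop,
        excluded=excluded,
        provenance=provenance,
    )
    if config.out_dir:
        report.write(config.out_dir)
        if config.make_plots:
            _write_plots(report, Path(config.out_dir))
    return report


def _write_plots(report: StudyReport, out_dir: Path) -> None:
    """Bland-Altman panels per metric and context (never parsed; audit only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, contexts in report.agreement.items():
        fig, axes = plt.subplots(len(contexts), 1, figsize=(6, 3 * len(contexts)))
        axes = np.atleast_1d(axes)
        for ax, (context, conds) in zip(axes, contexts.items()):
            for cond, rep in conds.items():
                ba = rep.get("bland_altman")
                if not ba:
                    continue
                ax.errorbar(
                    [cond],
                    [ba["bias"]],
                    yerr=[1.96 * ba["sd"]],
                    fmt="o",
                    capsize=4,
                )
            ax.axhline(0.0, color="k", lw=0.5)
            ax.set_title(f"{metric} - {context}")
            ax.set_ylabel("difference")
        fig.tight_layout()
        fig.savefig(out_dir / f"bland_altman_{metric}.svg")
        plt.close(fig)


def analyze_existing(loops: list[dict], config: RunConfig) -> StudyReport:
    """Run the tracking/index stages on externally provided loops.

    ``loops`` is a list of dicts with keys ``image`` (an
    :class:`~septostrain.tracking.ImageSequence`, a DICOM path, or a PNG
    stack directory), ``segmentation`` ((m, 2) array or JSON path) and
    ``timing`` (:class:`~septostrain.timing.CardiacTiming` or JSON
    path), plus optional labels (``subject``, ``visit``, ``intensity``).
    Loops missing a segmentation or timing are skipped with a logged
    reason; no ground-truth comparison is possible here.
    """
    from . import io as sio

    per_loop: list[dict] = []
    excluded: list[dict] = []
    for n, loop in enumerate(loops):
        label = {
            "subject": loop.get("subject", n),
            "visit": loop.get("visit", 1),
            "intensity": loop.get("intensity", "unknown"),
        }
        if loop.get("segmentation") is None or loop.get("timing") is None:
            excluded.append({**label, "exclusion_reason": "missing segmentation or timing"})
            continue
        image = loop["image"]
        if isinstance(image, (str, Path)):
            p = Path(image)
            image, tm = sio.read_png_stack(p) if p.is_dir() else sio.read_dicom(p)
        seg = loop["segmentation"]
        if isinstance(seg, (str, Path)):
            seg = sio.read_segmentation_json(seg)
        timing = loop["timing"]
        if isinstance(timing, (str, Path)):
            timing = sio.read_timing_json(timing)
        rec = {**label, "excluded": False, "exclusion_reason": None, "grade": None}
        try:
            mesh = build_mesh(np.asarray(seg))
            fld = estimate_displacements(
                image,
                mesh,
                block_size=config.block_size,
                search_radius=config.search_radius,
                corr_threshold=config.corr_threshold,
            )
            quality = grade_quality(image, fld)
            rec["grade"] = quality.grade
            if quality.excluded:
                rec.update(
                    excluded=True,
                    exclusion_reason="incomplete view of the septum (invalid-match rule)",
                )
            else:
                curve = accumulate_strain(
                    fld, mesh, timing=timing, frame_rate=image.frame_rate
                )
                idx = analyze_curve(curve)
                rec.update(srs=idx.srs_sept, ss=idx.ss, sdi=idx.sdi)
        except SeptostrainError as exc:
            rec.update(excluded=True, exclusion_reason=f"{type(exc).__name__}: {exc}")
        if rec["excluded"]:
            excluded.append({**label, "exclusion_reason": rec["exclusion_reason"]})
        per_loop.append(rec)

    if not loops:
        warnings.warn("no loops provided; report is empty", stacklevel=2)
    feas = pd.DataFrame(
        [
            {
                "condition": r["intensity"],
                "acquired": True,
                "attended_both_visits": True,
                "sufficient_quality": not r["excluded"],
                "grade": r.get("grade"),
            }
            for r in per_loop
        ]
    )
    return StudyReport(
        feasibility=agr.feasibility_tally(feas),
        agreement={},
        sdi_response={},
        per_loop=per_loop,
        excluded=excluded,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
            "package": "septostrain",
        },
    )
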
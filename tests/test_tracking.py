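"""Block-matching displacement estimation, strain accumulation, grading."""

import numpy as np
import pytest

import septostrain as st
from septostrain._blockmatch import ncc_planes
from septostrain.errors import StrainUndefinedError
from septostrain.synthetic import (
    AcquisitionCondition,
    SeptalGeometry,
    _splat_gaussians,
)
from septostrain.tracking import DisplacementField

from conftest import SMALL


def speckle_frame(rng, shape, n=2500):
    h, w = shape
    xs = rng.uniform(0, w, n)
    ys = rng.uniform(0, h, n)
    amps = rng.rayleigh(1.0, n)
    return _splat_gaussians(xs, ys, amps, shape, 2.0, 6).astype(np.float32)


def brute_force_ncc(f0, f1, cx, cy, half, sr):
    """Reference integer-offset NCC by direct evaluation."""
    t = f0[cy - half : cy + half + 1, cx - half : cx + half + 1].astype(float)
    t0 = t - t.mean()
    best, arg = -2.0, (0, 0)
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            w = f1[
                cy + dy - half : cy + dy + half + 1,
                cx + dx - half : cx + dx + half + 1,
            ].astype(float)
            w0 = w - w.mean()
            denom = np.sqrt((t0**2).sum() * (w0**2).sum())
            c = (t0 * w0).sum() / denom if denom > 0 else -1.0
            if c > best:
                best, arg = c, (dx, dy)
    return arg, best


class TestBlockMatching:
    def test_static_loop_gives_zero_displacement(self):
        rng = np.random.default_rng(0)
        frame = speckle_frame(rng, (160, 220))
        seq = st.ImageSequence(frames=np.stack([frame] * 4), frame_rate=60.0)
        grid = np.stack(
            np.meshgrid(np.linspace(60, 160, 11), np.linspace(40, 120, 5)), axis=-1
        ).transpose(1, 0, 2)
        mesh = st.SeptalMesh.from_grid(
            grid, np.array([[30, 20], [190, 20], [190, 140], [30, 140]], float)
        )
        fld = st.estimate_displacements(seq, mesh, search_radius=4)
        assert np.abs(fld.displacements).max() < 0.1

    def test_uniform_integer_translation_recovered(self):
        rng = np.random.default_rng(1)
        base = speckle_frame(rng, (160, 260))
        frames = np.stack([np.roll(base, 2 * k, axis=1) for k in range(4)])
        seq = st.ImageSequence(frames=frames, frame_rate=60.0)
        grid = np.stack(
            np.meshgrid(np.linspace(80, 160, 9), np.linspace(50, 110, 5)), axis=-1
        ).transpose(1, 0, 2)
        mesh = st.SeptalMesh.from_grid(
            grid, np.array([[40, 30], [220, 30], [220, 130], [40, 130]], float)
        )
        fld = st.estimate_displacements(seq, mesh, search_radius=5)
        assert fld.displacements[..., 0].mean() == pytest.approx(2.0, abs=0.2)
        assert fld.displacements[..., 1].mean() == pytest.approx(0.0, abs=0.2)

    def test_integer_peak_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        f0 = speckle_frame(rng, (120, 150))
        f1 = np.roll(np.roll(f0, 3, axis=0), -2, axis=1)
        centers = np.array(
            [[[40.0, 40.0], [70.0, 55.0], [100.0, 70.0], [60.0, 80.0]]]
        )
        planes, _covs, ok = ncc_planes(f0, f1, centers, 10, 6)
        assert ok.all()
        for p, (cx, cy) in enumerate(centers[0].astype(int)):
            (dx_o, dy_o), best_o = brute_force_ncc(f0, f1, cx, cy, 10, 6)
            iy, ix = np.unravel_index(planes[p].argmax(), planes[p].shape)
            assert (ix - 6, iy - 6) == (dx_o, dy_o)
            assert planes[p].max() == pytest.approx(best_o, abs=1e-6)

    def test_synthetic_loop_trajectory_recovered(self, lbbb_truth_small, tracked_small):
        err = tracked_small.trajectory - lbbb_truth_small.mesh_trajectory
        rmse = np.sqrt((err**2).sum(-1).mean())
        assert rmse < 0.5

    def test_tracking_deterministic(self, lbbb_truth_small, lbbb_loop_small, tracked_small):
        again = st.estimate_displacements(
            lbbb_loop_small, lbbb_truth_small.mesh, block_size=21, search_radius=5
        )
        assert np.array_equal(again.displacements, tracked_small.displacements)
        assert np.array_equal(again.scores, tracked_small.scores)

    def test_noise_monotonically_degrades_correlation(self, lbbb_truth_small):
        means = []
        for noise in (0.0, 0.8, 2.0):
            scores = []
            for seed in (3, 4):
                cond = AcquisitionCondition("vt60", 70.0, 90.0, noise, 0.0)
                seq = st.synthesize_cine_loop(
                    lbbb_truth_small, cond, image_size=SMALL, seed=seed
                )
                sub = st.ImageSequence(frames=seq.frames[:20], frame_rate=90.0)
                fld = st.estimate_displacements(
                    sub, lbbb_truth_small.mesh, search_radius=4
                )
                scores.append(fld.scores[fld.valid].mean())
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


class TestAccumulateStrain:
    def _rect_mesh(self):
        rect = np.array([[0, 0], [310, 0], [310, 110], [0, 110]], float)
        return st.build_mesh(rect)

    def test_uniform_translation_gives_zero_strain(self):
        mesh = self._rect_mesh()
        disp = np.tile(np.array([1.3, -0.7]), (20, 11, 31, 1))
        fld = DisplacementField.from_displacements(disp, mesh)
        curve = st.accumulate_strain(fld, mesh, frame_rate=50.0)
        assert np.abs(curve.strain).max() < 1e-9

    def test_linear_contraction_reaches_minus_ten_percent(self):
        mesh = self._rect_mesh()
        n_pairs = 20
        xc = mesh.points[..., 0].mean()
        per_pair = np.zeros((n_pairs, 11, 31, 2))
        per_pair[..., 0] = -0.1 * (mesh.points[None, ..., 0] - xc) / n_pairs
        fld = DisplacementField.from_displacements(per_pair, mesh)
        curve = st.accumulate_strain(fld, mesh, frame_rate=50.0)
        assert curve.strain[-1] == pytest.approx(-10.0, abs=1e-6)
        assert curve.strain[n_pairs // 2] == pytest.approx(-5.0, abs=1e-6)

    def test_full_pipeline_strain_recovery(self, lbbb_truth_small, tracked_small):
        curve = st.accumulate_strain(
            tracked_small,
            lbbb_truth_small.mesh,
            timing=lbbb_truth_small.timing,
            frame_rate=90.0,
        )
        rmse = np.sqrt(
            ((curve.strain - lbbb_truth_small.strain_curve.strain) ** 2).mean()
        )
        assert rmse < 1.0

    def test_too_many_invalid_points_raise(self):
        mesh = self._rect_mesh()
        disp = np.zeros((5, 11, 31, 2))
        valid = np.ones((5, 11, 31), dtype=bool)
        valid[2, :, :20] = False  # 64% of points lost in one pair
        fld = DisplacementField.from_displacements(disp, mesh, valid=valid)
        with pytest.raises(StrainUndefinedError):
            st.accumulate_strain(fld, mesh, frame_rate=50.0)


class TestGradeQuality:
    def test_clean_loop_graded_good(self, lbbb_loop_small, tracked_small):
        q = st.grade_quality(lbbb_loop_small, tracked_small)
        assert q.grade == "good"
        assert not q.excluded
        assert set(q.component_scores) == {
            "contrast", "structure", "stability", "artefact",
        }

    def test_heavy_noise_poor_but_not_excluded(self, lbbb_truth_small):
        cond = AcquisitionCondition("vt90", 70.0, 90.0, 2.5, 0.0)
        seq = st.synthesize_cine_loop(lbbb_truth_small, cond, image_size=SMALL, seed=5)
        fld = st.estimate_displacements(seq, lbbb_truth_small.mesh, search_radius=5)
        q = st.grade_quality(seq, fld)
        assert q.grade == "poor"
        assert not q.excluded

    def test_dropout_triggers_exclusion(self, lbbb_truth_small):
        cond = AcquisitionCondition("vt90", 70.0, 90.0, 0.0, 0.3)
        seq = st.synthesize_cine_loop(lbbb_truth_small, cond, image_size=SMALL, seed=2)
        fld = st.estimate_displacements(seq, lbbb_truth_small.mesh, search_radius=5)
        q = st.grade_quality(seq, fld)
        assert q.excluded
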
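"""Synthetic strain curves, ground-truth kinematics and cohorts."""

import numpy as np
import pytest

import septostrain as st
from septostrain.errors import (
    InfeasiblePatternError,
    InvalidPatternError,
    OutOfFieldError,
)
from septostrain.synthetic import (
    AcquisitionCondition,
    SeptalGeometry,
    ground_truth_from_curve,
    make_ground_truth,
)

from conftest import SMALL, make_curve


def decompose(curve):
    segs = st.segment_systole(curve)
    return st.compute_srs(segs), st.compute_ss(segs), segs.pre_shortening_stretch


class TestGenerateStrainCurve:
    @pytest.mark.parametrize(
        "family,ss,srs,pre",
        [
            ("non_lbbb_type", 15.0, 0.0, 0.0),
            ("lbbb_type", 14.0, 4.0, 0.0),
            ("lbbb_type", 8.0, 6.0, 0.0),
            ("lbbb_type", 20.0, 1.0, 0.0),
            ("lbbb_type", 12.0, 3.0, 1.5),
            ("lbbb_type", 10.0, 2.0, 0.5),
        ],
    )
    @pytest.mark.parametrize("frame_rate,hr", [(90.0, 60.0), (50.0, 95.0)])
    def test_targets_recovered_by_decomposition(self, family, ss, srs, pre, frame_rate, hr):
        pat = st.StrainPattern(
            family=family, target_ss=ss, target_srs=srs, pre_stretch=pre
        )
        timing = st.resting_timing(hr)
        curve = st.generate_strain_curve(pat, timing, frame_rate, seed=5)
        srs_m, ss_m, pre_m = decompose(curve)
        assert srs_m == pytest.approx(srs, abs=0.05)
        assert ss_m == pytest.approx(ss, abs=0.05)
        assert pre_m == pytest.approx(pre, abs=0.05)
        assert curve.strain[0] == 0.0
        assert curve.n_samples == round(timing.cycle_length * frame_rate)

    def test_non_lbbb_monotone_in_systole(self):
        pat = st.StrainPattern(family="non_lbbb_type", target_ss=15.0)
        curve = st.generate_strain_curve(pat, st.resting_timing(60.0), 90.0, seed=0)
        sys = curve.systolic_strain()
        assert np.all(np.diff(sys) <= 1e-12)
        assert decompose(curve)[0] == 0.0

    def test_deterministic_under_fixed_seed(self):
        pat = st.StrainPattern(family="lbbb_type", target_ss=14.0, target_srs=4.0)
        timing = st.resting_timing(70.0)
        a = st.generate_strain_curve(pat, timing, 90.0, seed=9)
        b = st.generate_strain_curve(pat, timing, 90.0, seed=9)
        assert np.array_equal(a.strain, b.strain)
        # the seed jitters knot timing: different seeds explore shapes
        variants = {
            st.generate_strain_curve(pat, timing, 90.0, seed=s).strain.tobytes()
            for s in range(8)
        }
        assert len(variants) > 1

    def test_invalid_and_infeasible_patterns(self):
        with pytest.raises(InvalidPatternError):
            st.StrainPattern(family="non_lbbb_type", target_ss=15.0, target_srs=2.0)
        with pytest.raises(InfeasiblePatternError):
            st.StrainPattern(
                family="lbbb_type",
                target_ss=5.0,
                target_srs=1.0,
                peak_systolic_strain=-8.0,
            )
        pat = st.StrainPattern(
            family="lbbb_type",
            target_ss=10.0,
            target_srs=4.0,
            peak_systolic_strain=-2.0,  # shallower than the AVC value: unreachable
        )
        with pytest.raises(InfeasiblePatternError):
            st.generate_strain_curve(pat, st.resting_timing(60.0), 90.0, seed=0)

    def test_specified_peak_is_reached(self):
        pat = st.StrainPattern(
            family="lbbb_type",
            target_ss=14.0,
            target_srs=4.0,
            peak_systolic_strain=-11.0,
        )
        curve = st.generate_strain_curve(pat, st.resting_timing(60.0), 90.0, seed=2)
        assert curve.systolic_strain().min() == pytest.approx(-11.0, abs=0.05)
        srs_m, ss_m, _ = decompose(curve)
        assert (srs_m, ss_m) == pytest.approx((4.0, 14.0), abs=0.05)

    def test_plateau_and_recoil_both_return_to_zero(self):
        timing = st.resting_timing(70.0)
        for behaviour in ("recoil_to_zero", "plateau"):
            pat = st.StrainPattern(
                family="lbbb_type",
                target_ss=12.0,
                target_srs=3.0,
                post_systolic_behavior=behaviour,
            )
            curve = st.generate_strain_curve(pat, timing, 90.0, seed=1)
            assert curve.strain[-1] == pytest.approx(0.0, abs=1e-9)


class TestGroundTruthKinematics:
    def test_analytic_indices_match_discoordination_module(self, lbbb_truth_small):
        idx = lbbb_truth_small.analytic_indices
        again = st.analyze_curve(lbbb_truth_small.strain_curve)
        assert idx.srs_sept == pytest.approx(again.srs_sept, abs=1e-6)
        assert idx.ss == pytest.approx(again.ss, abs=1e-6)
        assert idx.sdi == pytest.approx(again.sdi, abs=1e-6)

    def test_trajectory_arc_length_reproduces_strain_curve(self, lbbb_truth_small):
        traj = lbbb_truth_small.mesh_trajectory
        seglen = np.linalg.norm(np.diff(traj, axis=2), axis=3)
        row_len = seglen.sum(axis=2)  # (n_frames, n_radial)
        strain = 100.0 * (row_len / row_len[0] - 1.0).mean(axis=1)
        assert np.abs(strain - lbbb_truth_small.strain_curve.strain).max() < 0.05

    def test_mesh_points_inside_segmentation(self, lbbb_truth_small):
        from shapely.geometry import Point, Polygon

        poly = Polygon(lbbb_truth_small.segmentation).buffer(1e-9)
        pts = lbbb_truth_small.mesh.points.reshape(-1, 2)
        assert all(poly.contains(Point(p)) for p in pts)


class TestSynthesizeCineLoop:
    def test_static_scene_gives_identical_frames(self):
        flat = make_curve(np.zeros(40), frame_rate=60.0, n_systole=20)
        truth = ground_truth_from_curve(flat, image_size=SMALL)
        cond = AcquisitionCondition("baseline", 90.0, 60.0, 0.0, 0.0)
        seq = st.synthesize_cine_loop(truth, cond, image_size=SMALL, seed=4)
        diff = np.abs(seq.frames - seq.frames[0]).max()
        assert diff < 1e-6

    def test_noise_and_dropout_reproducible_and_marked(self, lbbb_truth_small):
        cond = AcquisitionCondition("vt90", 70.0, 90.0, 0.2, 0.3)
        a = st.synthesize_cine_loop(lbbb_truth_small, cond, image_size=SMALL, seed=6)
        b = st.synthesize_cine_loop(lbbb_truth_small, cond, image_size=SMALL, seed=6)
        assert np.array_equal(a.frames, b.frames)
        # at least one frame holds an occlusion (a disc of exact zeros)
        zero_counts = (a.frames == 0.0).reshape(a.n_frames, -1).sum(axis=1)
        assert (zero_counts > 200).any()

    def test_out_of_field_trajectory_rejected(self, lbbb_truth_small):
        cond = AcquisitionCondition("baseline", 70.0, 90.0, 0.0, 0.0)
        with pytest.raises(OutOfFieldError):
            st.synthesize_cine_loop(lbbb_truth_small, cond, image_size=(120, 100), seed=0)


class TestSimulateCohort:
    def test_manifest_counts(self):
        cohort = st.simulate_cohort(
            12, conditions=list(st.synthetic.INTENSITY_LEVELS), seed=0
        )
        assert len(cohort.manifest) == 12 * 2 * 5
        assert len(cohort.truths) == 120

    def test_zero_visit_noise_gives_identical_visits(self):
        cohort = st.simulate_cohort(
            6, conditions=["baseline"], visit_noise_sd=0.0, seed=3, lbbb_fraction=1.0
        )
        piv = cohort.manifest.pivot_table(
            index="subject", columns="visit", values="truth_srs"
        )
        assert np.allclose(piv[1], piv[2])

    def test_heart_rate_monotone_with_intensity(self):
        cohort = st.simulate_cohort(
            8, conditions=["baseline", "vt90"], seed=2, visit_noise_sd=0.5
        )
        piv = cohort.manifest.pivot_table(
            index=["subject", "visit"], columns="intensity", values="heart_rate"
        )
        assert (piv["vt90"] >= piv["baseline"]).all()

    def test_determinism_under_fixed_seed(self):
        a = st.simulate_cohort(4, conditions=["baseline"], seed=11)
        b = st.simulate_cohort(4, conditions=["baseline"], seed=11)
        assert a.manifest.equals(b.manifest)

    def test_visit_noise_scales_test_retest_sd(self):
        # each visit = subject base + independent noise, so the paired
        # difference of the SRS truth has SD ~ sqrt(2) * visit_noise_sd
        diffs = []
        for seed in range(30):
            cohort = st.simulate_cohort(
                20,
                conditions=["baseline"],
                visit_noise_sd=1.0,
                seed=seed,
                lbbb_fraction=1.0,
                srs_range=(3.0, 6.0),
            )
            piv = cohort.manifest.pivot_table(
                index="subject", columns="visit", values="truth_srs"
            )
            diffs.append(piv[1] - piv[2])
        sd = np.concatenate(diffs).std(ddof=1)
        assert sd == pytest.approx(np.sqrt(2.0), rel=0.15)
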
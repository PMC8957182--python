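"""Shared fixtures.

Heavy objects (synthetic loops, tracked fields) are session-scoped so
the speckle synthesis and block matching run once and are reused by the
tracking, quality and pipeline tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import septostrain as st
from septostrain.synthetic import AcquisitionCondition, make_ground_truth

SMALL = (320, 240)


def make_curve(strain, frame_rate=90.0, n_systole=None, heart_rate=None):
    """StrainCurve from raw samples; systole covers the first n samples."""
    strain = np.asarray(strain, dtype=float)
    n = len(strain)
    if n_systole is None:
        n_systole = n
    dt = 1.0 / frame_rate
    cycle = n * dt
    if heart_rate is None:
        heart_rate = 60.0 / cycle
    timing = st.CardiacTiming(
        heart_rate=heart_rate,
        cycle_length=cycle,
        mvc_time=0.0,
        avc_time=(n_systole - 1 + 0.5) * dt,
        source="visual",
    )
    return st.StrainCurve(time=np.arange(n) * dt, strain=strain, timing=timing)


@pytest.fixture(scope="session")
def phase_model():
    return st.fit_phase_duration_splines(st.default_reference_table())


@pytest.fixture(scope="session")
def rest_timing_70():
    return st.resting_timing(70.0)


@pytest.fixture(scope="session")
def lbbb_truth_small(rest_timing_70):
    pat = st.StrainPattern(family="lbbb_type", target_ss=14.0, target_srs=4.0)
    return make_ground_truth(pat, rest_timing_70, 90.0, image_size=SMALL, seed=1)


@pytest.fixture(scope="session")
def lbbb_loop_small(lbbb_truth_small):
    cond = AcquisitionCondition(
        "baseline", 70.0, 90.0, noise_level=0.0, dropout_fraction=0.0
    )
    return st.synthesize_cine_loop(lbbb_truth_small, cond, image_size=SMALL, seed=1)


@pytest.fixture(scope="session")
def tracked_small(lbbb_truth_small, lbbb_loop_small):
    return st.estimate_displacements(
        lbbb_loop_small, lbbb_truth_small.mesh, block_size=21, search_radius=5
    )
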
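"""Shared fixtures: small synthetic scenes and the default study matrices."""

import numpy as np
import pytest

from cropclass import synth


@pytest.fixture(scope="session")
def default_study():
    """Default 12-class, 20-parcels-per-class, 7-time study (seed 1)."""
    return synth.make_study(seed=1)


@pytest.fixture(scope="session")
def small_scene_set():
    """Three-time, 2-parcels-per-class scene series for I/O tests."""
    times = ["T1", "T2", "T3"]
    profiles = synth.default_profiles(times)
    layout = synth.make_layout({p.class_label: 2 for p in profiles},
                               parcel_shape=(6, 6))
    scenes, parcels = synth.generate(profiles, layout, times, seed=3)
    return scenes, parcels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
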
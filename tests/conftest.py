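import logging
import warnings

import numpy as np
import pytest

from mdinet.synthetic_data import (
    EffectSpec,
    library_to_frame,
    make_compound_library,
    mouse_design,
    ogtt_design,
    simulate_study,
)

logging.getLogger("mdinet").setLevel(logging.WARNING)

STEROIDS = "Steroids and steroid derivatives"


@pytest.fixture(scope="session")
def small_library():
    return make_compound_library(n_per_class=20, seed=1)


@pytest.fixture(scope="session")
def small_library_frame(small_library):
    return library_to_frame(small_library)


@pytest.fixture(scope="session")
def mouse_dataset(small_library):
    """Two-group single-timepoint study with steroids up 2-fold in risk."""
    design = mouse_design(n_per_group=8, seed=3)
    effects = [EffectSpec(STEROIDS, {"t0": 1.0}, fraction=0.8)]
    peaklists, metadata, truth = simulate_study(small_library, design, effects)
    return peaklists, metadata, truth, design


@pytest.fixture(scope="session")
def ogtt_dataset(small_library):
    """Three-timepoint OGTT study: steroids transiently up at t1 in risk."""
    design = ogtt_design(n_per_group=15, seed=11)
    effects = [EffectSpec(STEROIDS, {"t1": 0.8}, fraction=0.8)]
    peaklists, metadata, truth = simulate_study(small_library, design, effects)
    return peaklists, metadata, truth, design
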
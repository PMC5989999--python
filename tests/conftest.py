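"""Shared fixtures: synthetic segments and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from eegdyn import (Segment, average_reference, default_params,
                    generate_recording)

#: Sliding-window step (samples) used throughout the test suite; keeps the
#: dynamics matrices at k = 129 for 10-s, 256-Hz segments while computing
#: the measures identically to the unit-step definition.
TEST_STEP = 16
TEST_FS = 256.0


def make_segment(phenotype: str, seed: int, fs: float = TEST_FS,
                 duration: float = 10.0, **overrides) -> Segment:
    """Average-referenced 10-s segment of a synthetic phenotype."""
    params = default_params(phenotype, fs=fs, duration=duration, seed=seed,
                            **overrides)
    rec = average_reference(generate_recording(params))
    return Segment(f"{phenotype}_{seed}", rec.data, rec.fs)


@pytest.fixture(scope="session")
def control_segment() -> Segment:
    return make_segment("stationary_control", 7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
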
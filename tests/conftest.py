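"""Shared fixtures: small synthetic inputs generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nigraquant.record_abstraction import default_dictionary
from nigraquant.synthetic_data import (
    ClinicalCorpusParams,
    HistologyFixtureParams,
    generate_clinical_corpus,
    generate_histology_fixture,
)


@pytest.fixture(scope="session")
def small_histology():
    """A 800×800 px slide with 6 pigmented + 4 non-pigmented neurons."""
    params = HistologyFixtureParams(
        image_width_px=800,
        image_height_px=800,
        n_pigmented=6,
        n_non_pigmented=4,
        pigment_clutter_density=3.0,
        seed=3,
    )
    image, roi, truth = generate_histology_fixture(params)
    return params, image, roi, truth


@pytest.fixture(scope="session")
def small_corpus():
    """A 50-patient corpus with the default mention mix."""
    params = ClinicalCorpusParams(n_patients=50, seed=5)
    return params, generate_clinical_corpus(params)


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
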
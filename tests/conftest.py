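"""Shared fixtures: the default model, one library scan, and its fingerprints.

The scan and the synthetic-fingerprint stack are session-scoped — they are
deterministic and every downstream test reads them without mutation.
"""

import numpy as np
import pytest

import strainprint as sp


@pytest.fixture(scope="session")
def config() -> sp.ModelConfig:
    return sp.ModelConfig()


@pytest.fixture(scope="session")
def waveform(config) -> sp.TensionWaveform:
    return sp.generate_external_tension(config)


@pytest.fixture(scope="session")
def grid() -> sp.ParameterGrid:
    return sp.default_grid()


@pytest.fixture(scope="session")
def library(grid, waveform, config) -> sp.StrainLibrary:
    return sp.build_library(grid, waveform, config)


@pytest.fixture(scope="session")
def window(waveform) -> sp.AnalysisWindow:
    return sp.analysis_window(waveform)


@pytest.fixture(scope="session")
def synthetic_masks(library, window) -> np.ndarray:
    return sp.build_synthetic_fingerprints(library, window)


@pytest.fixture(scope="session")
def similarity_matrix(library, window) -> np.ndarray:
    return sp.pairwise_similarity(library, window)
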
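"""Shared fixtures: deterministic phantoms reused across test modules."""

import numpy as np
import pytest

from cvrkit import PhantomSpec, extract_etco2, simulate_capnogram


@pytest.fixture(scope="session")
def standard_capnogram():
    """Deterministic-breathing 7 min capnogram with 60/60 s blocks, 40->48 mmHg."""
    spec = PhantomSpec(breath_period_sd=0.0, capno_duration_s=420.0, seed=0)
    trace, truth = simulate_capnogram(spec)
    return spec, trace, truth


@pytest.fixture(scope="session")
def standard_etco2(standard_capnogram):
    """Extracted EtCO2 curve + QC for the standard capnogram."""
    _, trace, _ = standard_capnogram
    return extract_etco2(trace)


@pytest.fixture(scope="session")
def aligned_phantom_curve():
    """EtCO2 curve long enough to cover a 150-frame TR-2 BOLD run plus large shifts.

    Extracted from a deterministic capnogram so the curve has realistic
    breath-resolved transitions (needed for sub-second shift identifiability).
    """
    spec = PhantomSpec(breath_period_sd=0.0, capno_duration_s=420.0, n_frames=150, seed=0)
    trace, truth = simulate_capnogram(spec)
    curve, _ = extract_etco2(trace)
    return curve, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
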
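"""Shared fixtures: small simulated pools and deterministic toy ensembles."""

import numpy as np
import pytest

from phasete import NMMConfig, extract_phase, simulate_batch
from phasete.benchmark import NMM_BAND, NMM_FIR_ORDER


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _phase_pool(omega, n_pairs, seed, delta_ms=20.0):
    cfg = NMMConfig(w_xy=omega, w_yx=0.0, delta_ms=delta_ms, seed=seed)
    x, y = simulate_batch(cfg, n_pairs)
    px = extract_phase(x, NMM_BAND, order=NMM_FIR_ORDER)
    py = extract_phase(y, NMM_BAND, order=NMM_FIR_ORDER)
    return px, py


@pytest.fixture(scope="session")
def coupled_phases():
    """Strongly coupled (w=70, delta=20 ms) phase pool, 60 pairs."""
    return _phase_pool(70.0, 60, seed=21)


@pytest.fixture(scope="session")
def null_phases():
    """Uncoupled (w=0) phase pool, 60 pairs."""
    return _phase_pool(0.0, 60, seed=22)


@pytest.fixture(scope="session")
def uniform_phase_pair():
    """Independent i.i.d. uniform phase ensembles (no dynamics at all)."""
    g = np.random.default_rng(7)
    from phasete import PhaseEnsemble

    a = g.uniform(-np.pi, np.pi, (30, 200))
    b = g.uniform(-np.pi, np.pi, (30, 200))
    return (PhaseEnsemble(a, (15.0, 35.0), 100.0),
            PhaseEnsemble(b, (15.0, 35.0), 100.0))
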
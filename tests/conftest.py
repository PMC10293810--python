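import numpy as np
import pytest

from dtkin.kinetics_core import RateConstants, ReactionTotals
from dtkin.synthetic_data import get_preset


@pytest.fixture
def trex1_rates() -> RateConstants:
    """TREX1 + ssDNA 5-mer self-competition kinetics (25 C plate assay)."""
    return get_preset("TREX1_ssDNA_25C").rate_constants()


@pytest.fixture
def chase_totals() -> ReactionTotals:
    """Standard chase: 100 nM protein, 5 nM labeled ligand, 10 uM competitor."""
    return ReactionTotals(E_total=100e-9, P_total=5e-9, D_total=10e-6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
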
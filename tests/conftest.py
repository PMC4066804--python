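import numpy as np
import pytest

from targetsearch.model import AssayCondition, NonspecificParams


@pytest.fixture
def params_150mM() -> NonspecificParams:
    """Microscopic parameters near physiological salt (per-site K_d 16 uM)."""
    return NonspecificParams(
        D1=2.5e6, k_off_N=920.0, K_d_N=16e-6, k_IT_N=1e7, phi=2
    )


@pytest.fixture
def params_no_transfer() -> NonspecificParams:
    """Truth with k_IT_N = 0: tau_N is concentration-independent, so the
    length-fit convention (fixed lambda across the series) is exact."""
    return NonspecificParams(
        D1=1.33e6, k_off_N=920.0, K_d_N=16e-6, k_IT_N=0.0, phi=2
    )


@pytest.fixture
def cond_probe113() -> AssayCondition:
    """113-bp probe (L = 105), 28-bp competitor (M = 20), standard mix."""
    return AssayCondition(
        probe_len_bp=113,
        competitor_len_bp=28,
        D_tot=2.5e-9,
        C_tot=2e-6,
        footprint_B=9,
        target_pos_m=2,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
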
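"""Shared fixtures: the expensive scaled-down studies run once per session."""

import pytest

BASE_SEED = 1


@pytest.fixture(scope="session")
def exponent_study():
    """Three p_flex runs at phi_tot = 0.3, c_A = 0.2, L = 20 plus the
    pooled near-threshold B configurations; feeds all exponent checks."""
    from flexibcd.protocols import run_exponent_study

    return run_exponent_study(seed=BASE_SEED)


@pytest.fixture(scope="session")
def zc_flexible():
    from flexibcd.protocols import run_zc_plateau_study

    return run_zc_plateau_study(1.0, seed=BASE_SEED + 7)


@pytest.fixture(scope="session")
def zc_rigid():
    from flexibcd.protocols import run_zc_plateau_study

    return run_zc_plateau_study(0.0, seed=BASE_SEED + 8)


@pytest.fixture(scope="session")
def growth_study():
    from flexibcd.protocols import run_growth_study

    return run_growth_study(seed=BASE_SEED + 2)
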
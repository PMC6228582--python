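import numpy as np
import pytest

from promstrength import (
    NucleotideBackground,
    PWM,
    anderson_fixture,
    build_count_matrix,
    fit_ols,
    generate_hexamer_set,
    minus10_profile,
    minus35_profile,
    to_log_odds,
)


@pytest.fixture(scope="session")
def anderson():
    return anderson_fixture()


@pytest.fixture(scope="session")
def anderson_table(anderson):
    return anderson.feature_table()


@pytest.fixture(scope="session")
def anderson_fit(anderson_table):
    return fit_ols(anderson_table)


@pytest.fixture(scope="session")
def pwm35():
    """PWM built from a synthetic -35-like hexamer set (fixed seed)."""
    hexamers = generate_hexamer_set(minus35_profile(), n=500, seed=101)
    return to_log_odds(build_count_matrix(hexamers))


@pytest.fixture(scope="session")
def pwm10():
    """PWM built from a synthetic -10-like hexamer set (fixed seed)."""
    hexamers = generate_hexamer_set(minus10_profile(), n=500, seed=202)
    return to_log_odds(build_count_matrix(hexamers))


def make_random_pwm(seed: int, scale: float = 1.5, background=None) -> PWM:
    """Arbitrary log-odds matrix for oracle tests (weights need not derive
    from counts)."""
    rng = np.random.default_rng(seed)
    return PWM(
        weights=rng.normal(0.0, scale, size=(6, 4)),
        background=background or NucleotideBackground.from_gc(),
        pseudocount_total=1.0,
    )
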
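import numpy as np
import pytest

import medlongsim as m


@pytest.fixture(scope="session")
def base_params() -> m.SEMParameters:
    return m.SEMParameters()


@pytest.fixture(scope="session")
def medium_equal_params(base_params) -> m.SEMParameters:
    """Medium standardized effect (0.5) split equally between the direct
    and mediated paths — the workhorse generating scenario."""
    return m.calibrate_effects(m.EffectTarget(0.5, "equal"), base_params)


@pytest.fixture(scope="session")
def small_dataset(medium_equal_params) -> m.TrialDataset:
    return m.simulate_dataset(medium_equal_params, 120, m.ErrorSpec(), seed=42)


def random_psd_psi(rng: np.random.Generator) -> np.ndarray:
    """Random 3x3 PSD structural covariance with zero mediator cross terms."""
    a = rng.uniform(0.2, 2.0, size=2)
    r = rng.uniform(-0.9, 0.9)
    psi = np.diag([a[0], a[1], rng.uniform(0.2, 2.0)])
    psi[0, 1] = psi[1, 0] = r * np.sqrt(a[0] * a[1])
    return psi


def random_params(rng: np.random.Generator) -> m.SEMParameters:
    return m.SEMParameters(
        b13=rng.normal(scale=0.7),
        b23=rng.normal(scale=0.3),
        gamma11=rng.normal(scale=0.5),
        gamma21=rng.normal(scale=0.3),
        gamma31=rng.normal(scale=0.5),
        gamma13=rng.normal(scale=0.5),
        gamma23=rng.normal(scale=0.3),
        gamma33=rng.normal(scale=0.5),
        alpha1=rng.normal(),
        alpha2=rng.normal(scale=0.5),
        alpha3=rng.normal(),
        psi=random_psd_psi(rng),
        sigma2=rng.uniform(0.2, 2.0),
    )
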
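import numpy as np
import pytest

from palaeocoast import synthetic


@pytest.fixture(scope="session")
def identity_curve():
    """mu(theta) = theta, sigma_c = 0, spanning 3000-9000 cal BP."""
    return synthetic.identity_curve((9000.0, 3000.0), sigma=0.0, knot_step=50.0)


@pytest.fixture(scope="session")
def identity_curve_sig20():
    """Identity curve with constant 20 yr curve error."""
    return synthetic.identity_curve((9000.0, 3000.0), sigma=20.0, knot_step=50.0)


@pytest.fixture(scope="session")
def wiggly_curve():
    """Monotone synthetic curve with wiggles, noise and 15 yr curve error."""
    return synthetic.make_calcurve(span=(9000.0, 3000.0), wiggle_amp=30.0,
                                   wiggle_period=800.0, sigma=15.0, seed=11)


@pytest.fixture(scope="session")
def std_training():
    """The standard Gaussian-niche training set (150 x 40, gradient 0-30)."""
    return synthetic.make_training_set(seed=42)


@pytest.fixture(scope="session")
def three_site_fluxes():
    """Flux series for three synthetic cores sharing both pulse windows."""
    from palaeocoast import strat
    out = []
    for i in range(3):
        rec, ctl, _ = synthetic.make_core(site=f"SITE{i + 1}", seed=100 + i)
        out.append(strat.compute_flux(rec, strat.build_age_model(ctl),
                                      "pigments"))
    return out


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
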
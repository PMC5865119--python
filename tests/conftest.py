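import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from triselect.habitat_model import Coefficients, Posterior, UseRecord, sample_posterior
from triselect.simplex_core import make_composition
from triselect.synthetic_data import Scenario, simulate_dataset


def make_point_posterior(
    a: np.ndarray,
    form: str = "pooled",
    sites: tuple[str, ...] = (),
    animals: tuple[tuple[str, str], ...] = (),
    sigma: float = 0.0,
    eps: np.ndarray | None = None,
    chains: int = 2,
    draws: int = 60,
) -> Posterior:
    """A degenerate posterior whose draws are all identical — handy for
    constructing exact expectations."""
    a = np.asarray(a, dtype=float)
    S = len(sites) if form == "site_specific" else 1
    assert a.shape == (S, 2, 3)
    K = len(animals)
    if eps is None:
        eps = np.zeros((K, 2))
    return Posterior(
        form=form,
        sites=sites,
        animals=animals,
        a=np.broadcast_to(a, (chains, draws, S, 2, 3)).copy(),
        sigma=np.full((chains, draws), sigma),
        eps=np.broadcast_to(eps, (chains, draws, K, 2)).copy(),
        chain_meta={"synthetic": True},
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A small pooled-truth scenario for fast unit-level fits."""
    return Scenario(
        name="unit_small",
        sites={"A": (4.0, 5.0, 6.0), "B": (6.0, 4.0, 5.0)},
        coeffs=Coefficients(form="pooled", a=np.array([[[-0.4, 1.2, 0.0], [-0.2, 0.0, 0.8]]])),
        sigma=0.25,
        animals_per_site=6,
        fixes_per_animal=250,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    records, _ = small_dataset
    post = sample_posterior(
        records, form="pooled", chains=3, iterations=2500, burn_in=500, thin=5, seed=7
    )
    return post, records


@pytest.fixture(scope="session")
def contrast_fit():
    """Small site-specific fit over 3 sites for prediction/map tests."""
    sc = Scenario(
        name="unit_contrast",
        sites={"A": (4.0, 5.0, 6.0), "B": (6.0, 4.0, 5.0), "C": (5.0, 6.0, 4.0)},
        coeffs=Coefficients(
            form="site_specific",
            sites=("A", "B", "C"),
            a=np.array(
                [
                    [[-1.5, 4.0, 0.0], [-0.4, 0.0, 1.0]],
                    [[0.5, 0.5, 0.0], [0.1, 0.3, 1.2]],
                    [[1.0, -1.5, 0.3], [-0.8, 0.0, 1.5]],
                ]
            ),
        ),
        sigma=0.25,
        animals_per_site=6,
        fixes_per_animal=250,
        seed=43,
    )
    records, truth = simulate_dataset(sc)
    post = sample_posterior(
        records, form="site_specific", chains=3, iterations=2500, burn_in=500, thin=5, seed=8
    )
    return post, records, truth


@pytest.fixture
def simple_record():
    return UseRecord(
        site="A", animal_id="x", n=np.array([3, 2, 5]),
        d=make_composition([0.3, 0.3, 0.4]),
    )
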
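import numpy as np
import pandas as pd
import pytest

from emadsem.dsem import PosteriorDraws, param_names
from emadsem.synthetic import RE_NAMES, DesignConfig, TrueModel, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-person, 7-day study from the reference truth."""
    cfg = DesignConfig(n_persons=40, n_days=7, seed=99)
    return simulate_dataset(cfg)


def null_truth() -> TrueModel:
    """A truth with every structural coefficient at zero."""
    return TrueModel(
        re_means=np.array([9.5, 14.0, 0.2, 0.2, 0.0, 0.0]),
        gamma=np.zeros((6, 1)),
        re_resid_sd=np.array([1.5, 1.5, 0.08, 0.08, 0.05, 0.05]),
        sigma_w=np.array([[3.0, 0.0], [0.0, 6.0]]),
        beta_int=np.zeros(7),
        int_resid_sd=1.0,
    )


def make_draws(values: dict, n_draws: int = 400, n_chains: int = 2,
               seed: int = 0, random_effects=None, jitter: float = 0.0,
               pred_names=("adhd",)) -> PosteriorDraws:
    """Synthetic PosteriorDraws with given per-parameter values.

    ``values`` maps parameter name -> scalar (point mass) or array of
    shape (n_chains, n_draws).  Unnamed parameters default to benign
    constants (variances 1, loadings 1, everything else 0).
    """
    names = param_names(pred_names)
    rng = np.random.default_rng(seed)
    arr = np.zeros((n_chains, n_draws, len(names)))
    for i, n in enumerate(names):
        if n.startswith(("tau2", "psi", "theta")) or n in (
            "sigma_w[s,s]", "sigma_w[a,a]",
        ) or n.startswith("lambda"):
            arr[:, :, i] = 1.0
    if jitter:
        arr += jitter * rng.standard_normal(arr.shape)
    idx = {n: i for i, n in enumerate(names)}
    for name, val in values.items():
        arr[:, :, idx[name]] = val
    return PosteriorDraws(
        params=arr, names=names, psr=np.ones(len(names)), converged=True,
        n_iterations=n_draws * 10, thinning=10, seeds=[[0], [1]],
        random_effects=random_effects, meta={"predictors": list(pred_names)},
    )


def baseline_re_draws(n_chains=2, n_draws=400, n_persons=30, seed=0,
                      mu=(9.5, 14.0), phi=(0.25, 0.2, 0.03, 0.12),
                      spread=0.0) -> np.ndarray:
    """(C, D, N, 6) random-effect draws with optional person spread."""
    rng = np.random.default_rng(seed)
    re = np.zeros((n_chains, n_draws, n_persons, 6))
    base = np.array(list(mu) + list(phi))  # order: mu_s, mu_a, ss, aa, as, sa
    re[:] = base[None, None, None, :]
    if spread:
        person_dev = spread * rng.standard_normal((n_persons, 6))
        re += person_dev[None, None]
    return re


@pytest.fixture
def persons_table(rng):
    n = 50
    df = pd.DataFrame({"person_id": np.arange(n)})
    for j in range(9):
        df[f"adhd{j+1}"] = rng.integers(1, 6, n)
    for j in range(14):
        df[f"int{j+1}"] = rng.integers(1, 6, n)
    df["sex"] = rng.integers(0, 2, n)
    df["origin"] = rng.integers(0, 2, n)
    df["ses"] = rng.normal(49, 17, n)
    return df
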
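import warnings

import numpy as np
import pytest

from pdestride.dictionary import DesignSystem


warnings.filterwarnings(
    "ignore", message="sample size below 2p", category=UserWarning
)


def make_orthonormal_system(n=40, p=6, k=2, seed=0, noise=0.0):
    """Random design with orthonormalized columns and a k-sparse truth.

    Columns are orthonormal (unit l2 norm), response centered; the system
    is flagged standardized so solvers accept it.  Returns (system, xi_true).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    Q = Q[:, :p]
    xi = np.zeros(p)
    support = rng.choice(p, size=k, replace=False)
    xi[support] = rng.uniform(1.0, 3.0, size=k) * rng.choice([-1.0, 1.0], size=k)
    y = Q @ xi + noise * rng.normal(size=n)
    sys_ = DesignSystem(
        theta=Q, ut=y, labels=tuple(f"c{j}" for j in range(p)), standardized=True
    )
    return sys_, xi


def make_gaussian_system(n=60, p=8, k=2, seed=0, noise=0.0, corr=0.0):
    """Standardized random-Gaussian design with a k-sparse truth."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if corr:
        common = rng.normal(size=(n, 1))
        X = (1 - corr) * X + corr * common
    X -= X.mean(axis=0)
    X /= np.sqrt(np.mean(X**2, axis=0))
    xi = np.zeros(p)
    support = rng.choice(p, size=k, replace=False)
    xi[support] = rng.uniform(1.0, 3.0, size=k) * rng.choice([-1.0, 1.0], size=k)
    y = X @ xi + noise * rng.normal(size=n)
    y = y - y.mean()
    sys_ = DesignSystem(
        theta=X, ut=y, labels=tuple(f"c{j}" for j in range(p)), standardized=True
    )
    return sys_, xi


@pytest.fixture(scope="session")
def burgers_field():
    from pdestride.simulators import simulate_burgers

    return simulate_burgers()


@pytest.fixture(scope="session")
def burgers_system():
    from pdestride.experiments import get_problem, trial_system

    return trial_system(get_problem("burgers"), 250, 0.0, sample_seed=1)
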
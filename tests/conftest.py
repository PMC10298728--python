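import numpy as np
import pytest

from tetrablup.simulate import (
    GameteModel,
    StudyDesignConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A small but structurally complete study: 4 founders, 9 blocks,
    4 S1 families and 2 half-sib F1 families sharing founder P1."""
    cfg = StudyDesignConfig(
        n_loci=200,
        s1_family_sizes=18,
        f1_family_sizes=18,
        test_plots_per_block=15,
        seed=11,
    )
    dm, trial, pedigree = simulate_study(cfg)
    return cfg, dm, trial, pedigree


@pytest.fixture(scope="session")
def marker_population():
    """Unrelated tetraploid genotypes with a kernel and an additive trait.

    Returns (X, K, g, rng) where g is a noiseless additive genetic value
    built from the same markers as K, standardised to unit variance.
    """
    rng = np.random.default_rng(2024)
    n, m = 150, 400
    p = rng.uniform(0.05, 0.95, m)
    X = rng.binomial(4, np.broadcast_to(p, (n, m))).astype(float)
    ps = X.mean(axis=0) / 4.0
    W = X - 4.0 * ps
    K = W @ W.T / float((4.0 * ps * (1.0 - ps)).sum())
    beta = rng.normal(0.0, 1.0, m)
    g = W @ beta
    g = g / g.std()
    return X, K, g, rng
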
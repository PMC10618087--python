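import numpy as np
import pytest

from mrpipe import HarmonisedData, harmonise_pair, scenario_preset, simulate_pair


def make_h(gamma, alpha, se_alpha=None, se_gamma=None, n_exp=None, n_out=None):
    """Build HarmonisedData directly from arrays (tiny-fixture helper)."""
    gamma = np.asarray(gamma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    j = gamma.size
    se_alpha = np.full(j, 0.01) if se_alpha is None else np.asarray(se_alpha, float)
    se_gamma = np.full(j, 1e-8) if se_gamma is None else np.asarray(se_gamma, float)
    return HarmonisedData(
        snp=[f"rs{i}" for i in range(j)],
        gamma=gamma, se_gamma=se_gamma, alpha=alpha, se_alpha=se_alpha,
        n_exp=np.full(j, n_exp, float) if n_exp else None,
        n_out=np.full(j, n_out, float) if n_out else None,
    )


def sim_h(preset: str, seed: int, **overrides) -> tuple[HarmonisedData, object]:
    """Simulate a preset pair, harmonise it, return (data, truth)."""
    ex, out, truth = simulate_pair(scenario_preset(preset, seed=seed, **overrides))
    return harmonise_pair(ex, out), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_h(rng):
    """Moderately heterogeneous 30-SNP harmonised dataset."""
    j = 30
    gamma = rng.normal(0, 0.05, j)
    gamma[np.abs(gamma) < 0.01] = 0.02
    se_g = np.full(j, 0.004)
    se_a = rng.uniform(0.005, 0.02, j)
    alpha = 0.2 * gamma + rng.normal(0, se_a)
    return make_h(gamma, alpha, se_a, se_g, n_exp=100_000, n_out=100_000)
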
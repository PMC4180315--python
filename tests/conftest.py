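import numpy as np
import pytest

from methicc import MixtureFit, SimulationConfig, simulate_methylation_study

# fitted truncated-model parameters as published for the HM450 reliability
# analysis: zero cluster 36,017 of 473,788 sites, low component N(0.04, 0.28)
# truncated at 0 with weight 0.67, high component N(0.72, 0.11)
PUBLISHED_P0 = 36_017 / 473_788
PUBLISHED_TRUNCATED = dict(p=0.67, mu1=0.04, sigma1=0.28, mu2=0.72, sigma2=0.11)
PUBLISHED_CENSORED = dict(p=0.55, mu1=0.15, sigma1=0.14, mu2=0.67, sigma2=0.14)


@pytest.fixture(scope="session")
def published_truncated_fit() -> MixtureFit:
    return MixtureFit(
        model_kind="truncated",
        loglik=float("nan"),
        n_iter=0,
        converged=True,
        p0=PUBLISHED_P0,
        n_obs=473_788,
        **PUBLISHED_TRUNCATED,
    )


@pytest.fixture(scope="session")
def published_censored_fit() -> MixtureFit:
    return MixtureFit(
        model_kind="censored",
        loglik=float("nan"),
        n_iter=0,
        converged=True,
        n_obs=473_788,
        **PUBLISHED_CENSORED,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by fast tests."""
    cfg = SimulationConfig(
        seed=11,
        n_probes=300,
        n_subjects=200,
        n_replicate_pairs=60,
        n_replicate_triples=3,
        effect_probes=5,
    )
    beta, detp, sheet, annotation, truth = simulate_methylation_study(cfg)
    return dict(config=cfg, beta=beta, detp=detp, sheet=sheet, annotation=annotation, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
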
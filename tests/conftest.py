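import numpy as np
import pytest

from explainstab import GeneratorConfig, ResamplingPlan, generate_cohort, small_model_config


def tiny_model_config(seed: int = 0, **overrides):
    """1 x 8 net sized for 60-subject cohorts: generalises instead of
    memorising the 30-odd training rows of a fold."""
    base = dict(
        n_hidden_layers=1,
        units_per_layer=8,
        max_epochs=300,
        early_stop_patience=60,
        validation_fraction=0.2,
        seed=seed,
    )
    base.update(overrides)
    return small_model_config(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 sites x 20 subjects, 8 features (3 planted) — seconds to train on."""
    cfg = GeneratorConfig(
        n_sites=3,
        site_sizes=(20, 20, 20),
        site_age_ranges=((6.0, 18.0), (8.0, 25.0), (10.0, 40.0)),
        n_features=8,
        n_age_features=3,
        age_effect_sizes=(1.0, -1.0, 0.8),
        snr_site_means=(20.0, 12.0, 16.0),
        seed=42,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_loso_run(tiny_cohort):
    """Resampled LOSO on the tiny cohort: N = 2 rounds, small nets."""
    from explainstab import run_resampled_loso

    cohort, _ = tiny_cohort
    plan = ResamplingPlan(n_rounds=2, subsample_fraction=0.8, base_seed=11)
    report, registry = run_resampled_loso(cohort, tiny_model_config(seed=0), plan)
    return cohort, plan, report, registry


def random_predictor(P: int, seed: int):
    """A random small feed-forward net as a black-box predictor."""
    from explainstab.nnet import FeedForwardNet

    rng = np.random.default_rng(seed)
    net = FeedForwardNet.init(P, [8, 8], "tanh", rng)
    # non-degenerate random weights on a scale that keeps tanh active
    net.weights = [rng.normal(0, 0.8, W.shape) for W in net.weights]
    net.biases = [rng.normal(0, 0.3, b.shape) for b in net.biases]
    return net.forward
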
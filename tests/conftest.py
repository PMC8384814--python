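import numpy as np
import pytest

from neoms import synthetic as syn
from neoms.clustering import TemplateSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_zero_mean_maps(n, c, rng):
    maps = rng.standard_normal((n, c))
    return maps - maps.mean(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def planted_templates():
    """Five well-separated zero-mean unit-GFP 19-channel maps."""
    return syn.make_templates(5, 19, geometry="10-20",
                              min_pairwise_dissimilarity=0.8, seed=42)


def make_truth(templates, *, seed=0, snr=10.0, mean_ms=120.0,
               n_subjects=3, epoch_length_s=20.0, markov=None, **kwargs):
    k = templates.shape[0]
    channels = syn.montage_channels("10-20", templates.shape[1])
    return syn.SyntheticGroundTruth(
        templates=templates,
        markov=syn.uniform_markov(k) if markov is None else markov,
        channels=channels,
        duration_law=kwargs.pop("duration_law", {
            "name": "lognormal", "mean_ms": mean_ms, "sigma": 0.4,
            "min_ms": 30.0}),
        noise={"alpha": 1.0, "snr": snr, "spatial_decay": 0.3},
        n_subjects=n_subjects, epoch_length_s=epoch_length_s,
        seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_cohort(planted_templates):
    """3 subjects x 2 states x 20 s at SNR 10 with shared templates."""
    t_as = make_truth(planted_templates, seed=1, mean_ms=110.0)
    t_qs = make_truth(planted_templates, seed=2, mean_ms=150.0)
    return syn.simulate_cohort(t_as, t_qs)


@pytest.fixture(scope="session")
def planted_template_set(planted_templates):
    channels = syn.montage_channels("10-20", planted_templates.shape[1])
    return TemplateSet(maps=planted_templates.copy(), channels=channels)
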
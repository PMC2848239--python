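import numpy as np
import pytest

import pwmblend as pb


@pytest.fixture(scope="session")
def small_bench():
    """Small motif benchmark: 60 sites (L=8) + 3 kb background in chunks."""
    spec = pb.GeneratorSpec(n_fg=60, bg_total_bp=3000, L=8, chunk_len=100, seed=7)
    return pb.make_benchmark(spec)


@pytest.fixture(scope="session")
def small_data(small_bench):
    return small_bench.data


@pytest.fixture(scope="session")
def hyper8():
    return pb.hyperparams_from_ess(4.0, 1024.0, L=8)


@pytest.fixture(scope="session")
def tiny_data():
    """40 sequences of length 4, two overlapping classes (for exact checks)."""
    rng = np.random.default_rng(11)
    fg = pb.sample_pwm_dataset(pb.motif_pwm(4, strength=0.55, seed=1), 20, seed=rng)
    bg = pb.sample_pwm_dataset(np.full((4, 4), 0.25), 20, seed=rng, prefix="bg")
    return pb.LabeledData.from_classes(bg, fg)


@pytest.fixture(scope="session")
def hyper4():
    return pb.hyperparams_from_ess(4.0, 1024.0, L=4)


@pytest.fixture
def random_params():
    """Factory for random parameter vectors of a given shape."""

    def make(L, K=4, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        return pb.ClassifierParams(
            class_z=rng.normal(scale=scale, size=2),
            pwm_z=rng.normal(scale=scale, size=(2, L, K)),
        )

    return make
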
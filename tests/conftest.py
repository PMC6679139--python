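import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_genome(rng):
    """A 1-kb single-chromosome synthetic genome."""
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    return {"chr1": seq}


@pytest.fixture
def small_config():
    """A small float64 configuration for numerically exact unit tests."""
    from dannseq.network import DannConfig

    return DannConfig(n_kernels_1=3, n_kernels_2=4, fc_width=8, dtype="float64", seed=7)


def random_dataset(rng, n_pos, n_neg, domain="target"):
    """Random labeled 101-mers (no planted structure)."""
    from dannseq.sequences import LabeledSequence

    out = []
    for label, n in (("positive", n_pos), ("negative", n_neg)):
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=101))
            out.append(LabeledSequence(seq, label, domain))
    return out


@pytest.fixture
def tiny_separable_task(rng):
    """A small, cleanly separable synthetic task: positives always carry the
    consensus motif, negatives never do."""
    from dannseq.simulate import DomainSpec, MotifModel, generate_domain

    motif = MotifModel.from_consensus(strength=1.0)
    target = generate_domain(DomainSpec("t", _bg(), 150, 150, seed=1), motif, "target")
    source = generate_domain(DomainSpec("s", _bg(), 150, 150, seed=2), motif, "source")
    return target, source


def _bg():
    from dannseq.simulate import BG_AT_RICH

    return BG_AT_RICH
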
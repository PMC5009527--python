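import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pnpalign.seqio import Family, Sequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def global_hmm():
    from pnpalign.hmm import global_model

    return global_model()


@pytest.fixture(scope="session")
def local_hmm():
    from pnpalign.hmm import local_model

    return local_model()


@pytest.fixture
def toy_family():
    return Family(
        (
            Sequence("s1", "MKTAYIAK"),
            Sequence("s2", "MKTAYIVK"),
            Sequence("s3", "MKSAYIAK"),
        )
    )


@pytest.fixture
def toy_posteriors(toy_family, global_hmm):
    from pnpalign.posterior import compute_posteriors

    return compute_posteriors(toy_family, [global_hmm], cutoff=0.0)


def random_posterior_set(family, rng, density=0.4):
    """A synthetic (not model-derived) posterior set for graph tests."""
    from itertools import combinations

    from pnpalign.posterior import PosteriorSet

    mats = {}
    for i, j in combinations(range(len(family)), 2):
        shape = (len(family[i]), len(family[j]))
        mat = rng.random(shape) * (rng.random(shape) < density)
        mats[(i, j)] = mat
    return PosteriorSet(len(family), mats)


def random_family(rng, n=3, min_len=4, max_len=8, alphabet="ACDEFGHIKL"):
    seqs = []
    for s in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seqs.append(
            Sequence(f"s{s + 1}", "".join(rng.choice(list(alphabet), length)))
        )
    return Family(tuple(seqs))
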
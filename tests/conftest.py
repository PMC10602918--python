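import numpy as np
import pytest

from amirnakit import GuideRNA


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


@pytest.fixture
def random_guide(rng):
    def make(name: str = "amiR-test", seed: int | None = None) -> GuideRNA:
        r = rng if seed is None else np.random.default_rng(seed)
        return GuideRNA("".join(r.choice(list("ACGU"), size=21)), name)

    return make


@pytest.fixture
def nbsu_like_reference(rng):
    """Synthetic stand-in for a target mRNA long enough for coordinate tests."""
    return "".join(rng.choice(list("ACGT"), size=1200))
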
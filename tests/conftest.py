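import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mddpalm.sequence_io import (
    NEGATIVE,
    POSITIVE,
    Fragment,
    FragmentDataset,
    ProteinRecord,
    SiteAnnotation,
)

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_fragment(residues: str, label: str = POSITIVE, pid: str = "p", pos: int = 100):
    return Fragment(pid, pos, residues, label)


def random_fragment(rng: np.random.Generator, n: int = 10, label: str = POSITIVE,
                    pid: str = "p", pos: int = 100) -> Fragment:
    res = rng.choice(list(AA20), size=2 * n + 1)
    res[n] = "C"
    return Fragment(pid, pos, "".join(res), label)


def random_dataset(seed: int = 0, n_pos: int = 20, n_neg: int = 40, n: int = 10):
    rng = np.random.default_rng(seed)
    frags = [random_fragment(rng, n, POSITIVE, f"pp{i}", 50) for i in range(n_pos)]
    frags += [random_fragment(rng, n, NEGATIVE, f"nn{i}", 50) for i in range(n_neg)]
    return FragmentDataset(frags, n=n)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_protein():
    return ProteinRecord("prot1", "MKCLLVACCAWYKCDE")


@pytest.fixture
def proteins():
    return [
        ProteinRecord("prot1", "MKCLLVACCAWYKCDE"),
        ProteinRecord("prot2", "CCCAAAC"),
    ]


@pytest.fixture
def annotations():
    return [
        SiteAnnotation("prot1", 3, POSITIVE),
        SiteAnnotation("prot1", 9, POSITIVE),
        SiteAnnotation("prot2", 1, POSITIVE),
    ]


@pytest.fixture
def fragment21():
    return make_fragment("AAAAAAAAAACAAAAAAAAAA")
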
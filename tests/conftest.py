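import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mtphylogeo.mtdna_io import (
    Haplotype,
    HaplogroupDef,
    Mutation,
    load_reference,
    parse_haplotype_tokens,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def toy_defs():
    """Small U3-style haplogroup forest keyed by HVSI diagnostic motifs."""
    return [
        HaplogroupDef("U", None, ()),
        HaplogroupDef("U3", "U", parse_haplotype_tokens("16343")),
        HaplogroupDef("U3a", "U3", parse_haplotype_tokens("16390")),
        HaplogroupDef("U3a1", "U3a", parse_haplotype_tokens("16148")),
        HaplogroupDef("U3b", "U3", parse_haplotype_tokens("16111")),
        HaplogroupDef("U3b1a", "U3b", parse_haplotype_tokens("16086 16119")),
    ]


def haps_from_vectors(vecs, nsites, base_position=100):
    """Binary vectors -> haplotypes over transition characters."""
    return [
        Haplotype(
            tuple(Mutation(base_position + i) for i in range(nsites) if (v >> i) & 1),
            sample_id=f"s{r}",
        )
        for r, v in enumerate(vecs)
    ]


@pytest.fixture
def make_binary_haps():
    return haps_from_vectors


@pytest.fixture
def rng():
    return np.random.default_rng(20170523)
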
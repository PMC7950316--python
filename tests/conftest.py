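import numpy as np
import pytest

from ligandscape import synth


@pytest.fixture(scope="session")
def a29_spec():
    return synth.hla_a29_like()


@pytest.fixture(scope="session")
def a29_ligands(a29_spec):
    return synth.sample_ligands(a29_spec, 2000, seed=1234)


@pytest.fixture(scope="session")
def disjoint_anchor_families():
    """Two motif families with disjoint anchors at P2 and PΩ."""
    fam_a = synth.make_allele(
        "famA", 9, anchors={2: {"L": 0.5, "V": 0.5}, 9: {"Y": 0.5, "F": 0.5}}
    )
    fam_b = synth.make_allele(
        "famB", 9, anchors={2: {"S": 0.5, "T": 0.5}, 9: {"K": 0.5, "R": 0.5}}
    )
    return fam_a, fam_b


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
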
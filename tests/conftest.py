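import numpy as np
import pytest

from matesim import LocusSpec, MatingConfig, MatingSystem, MutationModel
from matesim.genetics import LocusClass


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def four_class_specs():
    """Two autosomal loci plus one locus of each sex-linked class, mutation off."""
    zero = MutationModel(0.0)
    return [
        LocusSpec(LocusClass.AUTOSOMAL, 2, 100, zero),
        LocusSpec(LocusClass.X, 1, 100, zero),
        LocusSpec(LocusClass.Y, 1, 100, zero),
        LocusSpec(LocusClass.MT, 1, 100, zero),
    ]


@pytest.fixture
def random_mating():
    return MatingConfig(MatingSystem.POLYGAMY)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
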
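import numpy as np
import pytest

from stowaway_kit.synthetic import (FamilySpec, generate_background,
                                    generate_family, plant_insertions)


@pytest.fixture(scope="session")
def clean_family():
    """A divergence-free family: 5 identical copies of a 274 bp consensus."""
    spec = FamilySpec("fam0", divergence=0.0, indel_rate=0.0, at_fraction=0.65)
    consensus, copies = generate_family(spec, 5, seed=11)
    return spec, consensus, copies


@pytest.fixture(scope="session")
def planted_genome(clean_family):
    """A 60 kb background carrying 8 planted copies, with truth."""
    _, _, copies = clean_family
    background = generate_background(60_000, 0.65, seed=21)
    genome, truth = plant_insertions(background, copies, 8, seed=22)
    return background, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
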
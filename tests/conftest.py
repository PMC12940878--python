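import numpy as np
import pytest

from pplscan.pedio import Individual, Pedigree
from pplscan.grids import TraitModel
from pplscan.phenotypes import derive_traits, trait_coding_map
from pplscan.synthcohort import (StratumPlan, SyntheticCohortConfig,
                                 generate_cohort)


@pytest.fixture
def trio():
    return Pedigree("f1", [
        Individual("f1", "1", None, None, "male"),
        Individual("f1", "2", None, None, "female"),
        Individual("f1", "3", "1", "2", "male"),
    ])


@pytest.fixture
def nuclear5():
    return Pedigree("f1", [
        Individual("f1", "1", None, None, "male"),
        Individual("f1", "2", None, None, "female"),
        Individual("f1", "3", "1", "2", "male"),
        Individual("f1", "4", "1", "2", "female"),
        Individual("f1", "5", "1", "2", "male"),
    ])


@pytest.fixture
def four_generation_12():
    """Hand-built 12-member, 4-generation family: 4 founders, no loops."""
    return Pedigree("big", [
        Individual("big", "gg1", None, None, "male"),
        Individual("big", "gg2", None, None, "female"),
        Individual("big", "g1", "gg1", "gg2", "male"),
        Individual("big", "g2", None, None, "female"),
        Individual("big", "p1", "g1", "g2", "male"),
        Individual("big", "p2", None, None, "female"),
        Individual("big", "p3", "g1", "g2", "female"),
        Individual("big", "c1", "p1", "p2", "male"),
        Individual("big", "c2", "p1", "p2", "female"),
        Individual("big", "c3", "p1", "p2", "male"),
        Individual("big", "g3", "gg1", "gg2", "female"),
        Individual("big", "c4", "p1", "p2", "female"),
    ])


def random_pedigree(rng, n, family_id="rf"):
    """Random loopless pedigree with n members (3..6)."""
    members = [
        Individual(family_id, "1", None, None, "male"),
        Individual(family_id, "2", None, None, "female"),
    ]
    next_id = 3
    # first child
    members.append(Individual(family_id, "3", "1", "2",
                              "male" if rng.random() < 0.5 else "female"))
    next_id = 4
    while len(members) < n:
        if len(members) <= n - 2 and rng.random() < 0.35:
            # extend: give an existing child a founder mate and a grandchild
            child = members[2]
            mate_sex = "female" if child.sex == "male" else "male"
            mate = Individual(family_id, str(next_id), None, None, mate_sex)
            next_id += 1
            fa, mo = ((child, mate) if child.sex == "male" else (mate, child))
            gc = Individual(family_id, str(next_id), fa.individual_id,
                            mo.individual_id,
                            "male" if rng.random() < 0.5 else "female")
            next_id += 1
            members += [mate, gc]
        else:
            members.append(Individual(family_id, str(next_id), "1", "2",
                                      "male" if rng.random() < 0.5 else "female"))
            next_id += 1
    return Pedigree(family_id, members[:n] if len(members) == n else members)


@pytest.fixture(scope="session")
def small_cohort():
    """12 wave-1 families with a planted dominant locus on marker M2."""
    cfg = SyntheticCohortConfig(
        seed=42,
        strata=(StratumPlan(1, 1, 12, "wave1"),),
        trait_model=TraitModel("dichotomous", 0.001, (0.0, 0.7, 0.9),
                               alpha=0.9),
        n_markers=4, n_chromosomes=2, trait_locus_marker=1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_coding(small_cohort):
    traits = derive_traits(small_cohort.phenotypes)
    return trait_coding_map(traits, "LI_star")
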
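import numpy as np
import pandas as pd
import pytest

from pplscan.grids import TraitModel, power_grid
from pplscan.linkage import scan
from pplscan.phenotypes import derive_traits, trait_coding_map
from pplscan.synthcohort import (GenePlan, StratumPlan,
                                 SyntheticCohortConfig, ascertain,
                                 generate_cohort,
                                 heterogeneity_scenario_config,
                                 plant_rare_variants)


def test_determinism_byte_identical():
    cfg = SyntheticCohortConfig(
        seed=7, strata=(StratumPlan(1, 1, 5, "wave1"),),
        n_markers=4, n_chromosomes=2, trait_locus_marker=1)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert np.array_equal(a.genotypes.alleles, b.genotypes.alleles)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    assert a.linked_families == b.linked_families


def test_mendelian_consistency(small_cohort):
    g = small_cohort.genotypes
    for ped in small_cohort.pedigrees:
        rows = g.rows_for_family(ped)
        for m in ped.nonfounders:
            child = g.alleles[rows[m.individual_id]]
            fa = g.alleles[rows[m.father_id]]
            mo = g.alleles[rows[m.mother_id]]
            for j in range(child.shape[0]):
                ok = any(
                    sorted((a, b)) == sorted(child[j])
                    for a in fa[j] for b in mo[j]
                )
                assert ok, (ped.family_id, m.individual_id, j)


def test_trait_locus_never_in_genotype_output(small_cohort):
    assert set(small_cohort.genotypes.marker_names) == \
        set(small_cohort.marker_map.names)


def test_stratum_sizes_conserved():
    cfg = SyntheticCohortConfig(
        seed=3,
        strata=(StratumPlan(1, 1, 4, "wave1"), StratumPlan(1, 2, 3, "wave1"),
                StratumPlan(2, 1, 2, "wave2"), StratumPlan(2, 2, 2, "wave2")),
        n_markers=2, n_chromosomes=1, trait_locus_marker=0)
    coh = generate_cohort(cfg)
    sizes = {k: len(v) for k, v in coh.strata.items()}
    assert sizes == {(1, 1): 4, (1, 2): 3, (2, 1): 2, (2, 2): 2}
    assert sum(sizes.values()) == len(coh.pedigrees) == 11


def test_cohort_size_matches_study_waves():
    # wave-1-sized configuration: 79 families of mean size ~5.6
    cfg = SyntheticCohortConfig(
        seed=1,
        strata=(StratumPlan(1, 1, 40, "wave1"), StratumPlan(1, 2, 39, "wave1")),
        n_markers=2, n_chromosomes=1, trait_locus_marker=0)
    coh = generate_cohort(cfg)
    assert 440 * 0.85 <= coh.n_individuals() <= 440 * 1.15


# ---------------------------------------------------------------------------
# Ascertainment rules

def _rows(members):
    """members: list of (asd, celf) pairs."""
    return [{"asd": a, "celf_core": celf, "piq": 95.0,
             "oral_subtest_z": None, "intervention_history": False}
            for a, celf in members]


def test_ascertain_asd_plus_li_sib():
    rows = _rows([("yes", 102.0), ("no", 78.0)])
    assert ascertain(rows, "wave1") and ascertain(rows, "wave2")


def test_ascertain_two_asd_no_li_rejected():
    rows = _rows([("yes", 102.0), ("yes", 102.0), ("no", 102.0)])
    assert not ascertain(rows, "wave1") and not ascertain(rows, "wave2")


def test_ascertain_multiplex_asd_both_li_wave2_only():
    rows = _rows([("yes", 78.0), ("yes", 78.0), ("no", 102.0)])
    assert not ascertain(rows, "wave1")
    assert ascertain(rows, "wave2")


# ---------------------------------------------------------------------------
# Power behaviour of the generator

def test_planted_locus_detectable_at_full_penetrance():
    grid = power_grid()
    hits = 0
    for seed in range(5):
        cfg = heterogeneity_scenario_config(
            seed, n_linked=20, n_unlinked=0,
            trait_model=TraitModel("dichotomous", 0.001, (0.0, 1.0, 1.0),
                                   alpha=1.0))
        cfg.strata = (cfg.strata[0],)
        coh = generate_cohort(cfg)
        coding = trait_coding_map(derive_traits(coh.phenotypes), "LI_star")
        df = scan(coh.pedigrees, coh.genotypes, coh.marker_map, coding,
                  grid, mode="pooled")
        hits += df.loc[0, "PPL"] > 0.9
    assert hits >= 3  # majority of seeds


def test_small_alpha_stays_near_prior():
    grid = power_grid()
    ppls = []
    for seed in range(3):
        cfg = heterogeneity_scenario_config(
            100 + seed, n_linked=20, n_unlinked=0,
            trait_model=TraitModel("dichotomous", 0.001, (0.0, 1.0, 1.0),
                                   alpha=0.1))
        cfg.strata = (cfg.strata[0],)
        coh = generate_cohort(cfg)
        coding = trait_coding_map(derive_traits(coh.phenotypes), "LI_star")
        df = scan(coh.pedigrees, coh.genotypes, coh.marker_map, coding,
                  grid, mode="pooled")
        ppls.append(df.loc[0, "PPL"])
    assert max(ppls) < 0.15 and np.median(ppls) < 0.05


# ---------------------------------------------------------------------------
# Rare-variant planting

def test_plant_unknown_family_errors(small_cohort, small_cohort_coding):
    plan = GenePlan("G", "1", 1_000_000, 1_050_000,
                    carrier_families=("nope",))
    with pytest.raises(ValueError, match="nope"):
        plant_rare_variants(small_cohort, [plan], seed=0,
                            coding=small_cohort_coding)


def test_plant_carriers_mendelian(small_cohort, small_cohort_coding):
    fams = [p.family_id for p in small_cohort.pedigrees][:3]
    plan = GenePlan("G", "1", 1_000_000, 1_050_000,
                    carrier_families=tuple(fams))
    variants, anns = plant_rare_variants(small_cohort, [plan], seed=2,
                                         coding=small_cohort_coding)
    v = variants[0]
    by_fam = {p.family_id: p for p in small_cohort.pedigrees}
    for (fam, iid), n in v.carriers.items():
        if n > 0:
            ped = by_fam[fam]
            m = ped.get(iid)
            if not m.is_founder:
                # a carrier child has a carrier parent
                assert (v.carriers.get((fam, m.father_id), 0)
                        + v.carriers.get((fam, m.mother_id), 0)) > 0
    assert anns["G"].symbol == "G"


def test_decoy_tpm_fails_gate(small_cohort, small_cohort_coding):
    from pplscan.prioritize import expression_gate
    plan = GenePlan("DIM", "1", 1_000_000, 1_050_000,
                    carrier_families=(),
                    tpm_by_db=(4.9, 4.9, 4.9))
    _, anns = plant_rare_variants(small_cohort, [plan], seed=0,
                                  coding=small_cohort_coding)
    assert expression_gate(list(anns.values())) == []
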
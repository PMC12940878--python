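import numpy as np
import pytest

from pplscan.linkage import CriticalRegion
from pplscan.pedio import Individual, Pedigree
from pplscan.prioritize import (CandidateGene, GeneAnnotation, VariantRecord,
                                bonferroni_threshold, cnv_filters,
                                expression_gate, filter_rare,
                                gene_score_permutation, read_variants_vcf,
                                region_filter, segregation_lod,
                                select_subpedigree, select_top_candidates,
                                sfari_overlap, unique_family_count)
from pplscan.synthcohort import GenePlan, plant_rare_variants, write_vcf


def snv(pos, maf=0.01, chrom="1", carriers=None, gene=None, end=None,
        vclass="SNV", **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref="C", alt="T",
                         vclass=vclass, population_maf=maf,
                         carriers=carriers or {}, gene=gene, end=end, **kw)


REGION = CriticalRegion("1", 50.0, 5_000_000, 40.0, 60.0,
                        4_000_000, 6_000_000, 0.4)


# ---------------------------------------------------------------------------
# Variant filters

def test_filter_rare_boundaries():
    vs = [snv(1, 0.04), snv(2, 0.06), snv(3, 0.05), snv(4, None)]
    kept = filter_rare(vs)
    assert [v.pos for v in kept] == [1, 4]  # 0.05 exact is dropped (strict)


def test_region_filter_half_open():
    vs = [snv(4_000_000), snv(6_000_000), snv(5_999_999),
          snv(3_900_000, end=4_100_000, vclass="SV"),
          snv(6_000_000, end=6_100_000, vclass="SV")]
    kept = region_filter(vs, [REGION])
    assert [v.pos for v in kept] == [4_000_000, 5_999_999, 3_900_000]


def test_region_filter_counts(small_cohort):
    inside = [snv(4_000_000 + i * 1000) for i in range(10)]
    outside = [snv(7_000_000 + i * 1000) for i in range(10)]
    assert len(region_filter(inside + outside, [REGION])) == 10


def test_cnv_filters():
    mk = lambda length, probes: snv(1, vclass="CNV", length_bp=length,
                                    probe_count=probes, end=1 + length)
    cnvs = [mk(9_999, 10), mk(8_000_000, 10), mk(100_000, 4),
            mk(100_000, 5), mk(10_000, 5), mk(7_500_000, 5)]
    kept = cnv_filters(cnvs)
    assert [(c.length_bp, c.probe_count) for c in kept] == \
        [(100_000, 5), (10_000, 5), (7_500_000, 5)]


def test_sv_filter():
    from pplscan.prioritize import sv_filter
    svs = [snv(1, vclass="SV", end=2, benign_flag=True),
           snv(2, vclass="SV", end=3),
           snv(3, vclass="SV", end=4)]
    assert len(sv_filter(svs)) == 2


def test_filters_monotone_and_idempotent():
    vs = [snv(i, maf=m) for i, m in enumerate([0.01, 0.2, 0.04, 0.06])]
    once = filter_rare(vs)
    assert set(v.pos for v in once) <= set(v.pos for v in vs)
    assert filter_rare(once) == once


# ---------------------------------------------------------------------------
# Bonferroni

@pytest.mark.parametrize("n, expected", [
    (308, 1.62e-4), (103, 4.85e-4), (1, 0.05),
])
def test_bonferroni(n, expected):
    assert bonferroni_threshold(0.05, n) == pytest.approx(expected, rel=5e-3)


def test_bonferroni_zero_genes():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


# ---------------------------------------------------------------------------
# Segregation

def _fam(n_children, affected_children, carrier_children):
    members = [Individual("f", "1", None, None, "male"),
               Individual("f", "2", None, None, "female")]
    for k in range(n_children):
        members.append(Individual("f", str(3 + k), "1", "2", "male"))
    ped = Pedigree("f", members)
    carriers = {("f", "1"): 1, ("f", "2"): 0}
    coding = {("f", "1"): "affected", ("f", "2"): "unaffected"}
    for k in range(n_children):
        iid = str(3 + k)
        carriers[("f", iid)] = 1 if k in carrier_children else 0
        coding[("f", iid)] = ("affected" if k in affected_children
                              else "unaffected")
    v = snv(100, carriers=carriers)
    return ped, v, coding


def test_segregation_lod_single_meiosis():
    ped, v, coding = _fam(1, {0}, {0})
    lod = segregation_lod(v, ped, coding, "dominant")
    assert lod == pytest.approx(np.log10(2), abs=1e-12)
    assert lod > 0.3  # a single perfect meiosis clears the strict filter


def test_segregation_lod_two_meioses_passes_filter():
    ped, v, coding = _fam(2, {0, 1}, {0, 1})
    lod = segregation_lod(v, ped, coding, "dominant")
    assert lod == pytest.approx(2 * np.log10(2), abs=1e-12)
    assert lod > 0.3


def test_segregation_lod_countersegregation_not_positive():
    # variant carried only by unaffected members
    ped, v, coding = _fam(2, {0}, {1})
    carriers = dict(v.carriers)
    carriers[("f", "1")] = 0
    carriers[("f", "2")] = 1
    v2 = snv(100, carriers=carriers)
    assert segregation_lod(v2, ped, coding, "dominant") <= 0.0


def test_segregation_lod_uninformative_family():
    v = snv(100, carriers={("f", "1"): 1})
    ped, _, coding = _fam(1, {0}, {0})
    assert segregation_lod(v, ped, coding, "dominant") == 0.0


def test_subpedigree_selection_prefers_affected_sequenced():
    ped, v, coding = _fam(3, {0, 1}, {0, 1})
    sequenced = {"1", "2", "3", "4", "5"}
    affected = {"1", "3", "4"}
    ids = select_subpedigree(ped, sequenced, affected, "dominant")
    assert set(ids) == {"1", "2", "3", "4", "5"}
    ids_rec = select_subpedigree(ped, sequenced, affected, "recessive")
    assert set(ids_rec) == {"1", "2", "3", "4", "5"}


# ---------------------------------------------------------------------------
# Permutation score

def test_permutation_requires_enough_permutations(small_cohort,
                                                  small_cohort_coding):
    with pytest.raises(ValueError, match="n_perm"):
        gene_score_permutation([snv(1)], small_cohort.pedigrees,
                               small_cohort_coding, n_perm=10)


def test_permutation_no_carriers_p_near_one(small_cohort,
                                            small_cohort_coding):
    p, obs = gene_score_permutation([snv(1, maf=0.01)],
                                    small_cohort.pedigrees,
                                    small_cohort_coding,
                                    n_perm=200, seed=0)
    assert p == pytest.approx(1.0)


def test_permutation_p_bounds(small_cohort, small_cohort_coding):
    fams = [p.family_id for p in small_cohort.pedigrees][:3]
    plan = GenePlan("G", "1", 1_000_000, 1_050_000,
                    carrier_families=tuple(fams))
    variants, _ = plant_rare_variants(small_cohort, [plan], seed=0,
                                      coding=small_cohort_coding)
    p, _ = gene_score_permutation(variants, small_cohort.pedigrees,
                                  small_cohort_coding, n_perm=200, seed=1)
    assert 1 / 201 <= p <= 1.0


# ---------------------------------------------------------------------------
# Gene-level gates and ranking

def _ann(symbol, tpm, ndd=False, sfari=False):
    return GeneAnnotation(symbol, "1", 4_000_000, 4_100_000, tpm,
                          ndd_flag=ndd, sfari_flag=sfari)


def test_expression_gate():
    genes = [_ann("LOW", (4.9, 4.9, 4.9)), _ann("ONE", (0, 0, 6)),
             _ann("ALL", (6, 7, 8))]
    kept = expression_gate(genes)
    assert [g.symbol for g in kept] == ["ONE", "ALL"]


def test_select_top_candidates_ranking_and_flags():
    genes = {
        "MULTI": CandidateGene("MULTI", [], {}, unique_family_count=2),
        "SOLO": CandidateGene("SOLO", [], {}, unique_family_count=1),
        "DIM": CandidateGene("DIM", [], {}, unique_family_count=3),
    }
    anns = {"MULTI": _ann("MULTI", (6, 7, 8), ndd=True),
            "SOLO": _ann("SOLO", (9, 9, 9)),
            "DIM": _ann("DIM", (1, 1, 1))}
    ranked = select_top_candidates(genes, anns)
    assert [g.symbol for g in ranked] == ["MULTI", "SOLO", "DIM"]
    flags = {g.symbol: g.top_flag for g in ranked}
    assert flags == {"MULTI": True, "SOLO": False, "DIM": False}
    # deterministic ordering on reruns
    again = select_top_candidates(genes, anns)
    assert [g.symbol for g in again] == [g.symbol for g in ranked]


def test_unique_families_union_across_variant_types():
    # one SNV in one family plus one CNV in another family -> 2 families
    v1 = snv(4_010_000, carriers={("famA", "1"): 1}, gene="G")
    v2 = snv(4_020_000, vclass="CNV", length_bp=50_000, probe_count=9,
             end=4_070_000, carriers={("famB", "1"): 1}, gene="G")
    assert unique_family_count([v1, v2]) == 2


def test_sfari_overlap_counts():
    table = sfari_overlap(
        {"chr15_LI": ["A", "B", "C", "D", "E"], "chr16_RI": ["X"]},
        ["B", "D", "Q"])
    row = table.set_index("region").loc["chr15_LI"]
    assert row["n_overlap"] == 2 and row["symbols"] == "B,D"
    assert table.set_index("region").loc["chr16_RI", "n_overlap"] == 0
    assert (table["n_overlap"] <= table["n_genes"]).all()


def test_sfari_overlap_empty_list():
    t = sfari_overlap({"r": ["A", "B"]}, [])
    assert t["n_overlap"].sum() == 0


# ---------------------------------------------------------------------------
# VCF round trip

def test_vcf_round_trip(tmp_path, small_cohort, small_cohort_coding):
    fams = [p.family_id for p in small_cohort.pedigrees][:2]
    plan = GenePlan("G1", "1", 1_000_000, 1_050_000,
                    carrier_families=tuple(fams))
    variants, _ = plant_rare_variants(small_cohort, [plan], seed=4,
                                      coding=small_cohort_coding)
    path = tmp_path / "vars.vcf"
    write_vcf(variants, small_cohort.genotypes.sample_ids, path)
    back = read_variants_vcf(path)
    assert len(back) == len(variants)
    v0, b0 = variants[0], back[0]
    assert (b0.chrom, b0.pos, b0.gene) == (v0.chrom, v0.pos, "G1")
    for key, n in v0.carriers.items():
        assert b0.carriers.get(key, 0) == n
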
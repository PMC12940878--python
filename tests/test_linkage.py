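import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pplscan.grids import PRIOR_LINKAGE, TraitModel, coarse_grid, power_grid
from pplscan.linkage import (bayes_ratio_curve, critical_region, family_lod,
                             family_lr_matrix, mod_score, ppl_from_br, ppld,
                             scan, sequential_update, _marker_geno_dict)
from pplscan.phenotypes import derive_traits, trait_coding_map


# ---------------------------------------------------------------------------
# Posterior update

def test_ppl_prior_identity():
    assert ppl_from_br(1.0, 0.02) == pytest.approx(0.02)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=1e-4, max_value=1 - 1e-4))
def test_ppl_prior_identity_any_prior(prior):
    assert ppl_from_br(1.0, prior) == pytest.approx(prior, rel=1e-12)


def test_ppl_known_value_and_limits():
    assert ppl_from_br(49.0, 0.02) == pytest.approx(0.5)
    assert ppl_from_br(1e12, 0.02) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        ppl_from_br(0.0)
    with pytest.raises(ValueError):
        ppl_from_br(1.0, prior=1.5)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(min_value=0.01, max_value=100),
       st.floats(min_value=0.01, max_value=100))
def test_ppl_monotone_in_br(b1, b2):
    lo, hi = sorted((b1, b2))
    assert ppl_from_br(lo) <= ppl_from_br(hi)


# ---------------------------------------------------------------------------
# Bayes ratios

def _lr_matrices(cohort, coding, grid, marker="M2"):
    maf = float(cohort.marker_map.table.loc[
        cohort.marker_map.index_of(marker), "maf"])
    return {
        p.family_id: family_lr_matrix(
            p, _marker_geno_dict(p, cohort.genotypes, marker),
            coding, grid, maf)
        for p in cohort.pedigrees
    }


def test_uninformative_family_br_is_one(small_cohort):
    grid = coarse_grid()
    ped = small_cohort.pedigrees[0]
    coding = {}
    lr = family_lr_matrix(ped, {}, coding, grid,
                          0.4)
    assert np.allclose(lr, 1.0)
    curve, br = bayes_ratio_curve([lr], grid)
    assert np.allclose(curve, 1.0) and br == pytest.approx(1.0)


def test_br_invariant_under_family_order(small_cohort, small_cohort_coding):
    grid = power_grid()
    lrs = list(_lr_matrices(small_cohort, small_cohort_coding,
                            grid).values())
    _, a = bayes_ratio_curve(lrs, grid)
    _, b = bayes_ratio_curve(lrs[::-1], grid)
    assert a == pytest.approx(b, rel=1e-12)


def test_br_two_family_toy_matches_direct_summation():
    # brute-force oracle: direct sums over the grid on fabricated LR matrices
    rng = np.random.default_rng(0)
    grid = coarse_grid()
    lrs = [np.exp(rng.normal(0, 0.3, (grid.n_models, len(grid.thetas))))
           for _ in range(2)]
    lrs = [np.concatenate([l[:, :-1], np.ones((grid.n_models, 1))], axis=1)
           for l in lrs]
    curve, integrated = bayes_ratio_curve(lrs, grid)
    expect = np.zeros(len(grid.thetas))
    for t in range(len(grid.thetas)):
        acc = 0.0
        for m in range(grid.n_models):
            for a, wa in zip(grid.alphas, grid.alpha_weights):
                prod = 1.0
                for l in lrs:
                    prod *= a * l[m, t] + (1 - a)
                acc += grid.model_weights[m] * wa * prod
        expect[t] = acc
    assert np.allclose(curve, expect, rtol=1e-10)
    assert integrated == pytest.approx(
        float(np.dot(grid.theta_weights, expect)), rel=1e-10)


def test_sequential_neutral_stratum_is_identity():
    grid = coarse_grid()
    rng = np.random.default_rng(1)
    curve = np.exp(rng.normal(0, 0.5, len(grid.thetas)))
    ones = np.ones(len(grid.thetas))
    br1, ppl1 = sequential_update([curve], grid)
    br2, ppl2 = sequential_update([curve, ones], grid)
    assert br1 == pytest.approx(br2) and ppl1 == pytest.approx(ppl2)


def test_sequential_all_neutral_gives_prior():
    grid = coarse_grid()
    ones = np.ones(len(grid.thetas))
    _, ppl = sequential_update([ones, ones, ones], grid)
    assert ppl == pytest.approx(grid.prior_linkage)


def test_sequential_single_stratum_equals_pooled(small_cohort,
                                                 small_cohort_coding):
    grid = power_grid()
    lrs = list(_lr_matrices(small_cohort, small_cohort_coding,
                            grid).values())
    curve, pooled_br = bayes_ratio_curve(lrs, grid)
    seq_br, _ = sequential_update([curve], grid)
    assert seq_br == pytest.approx(pooled_br, rel=1e-12)


def test_sequential_mismatched_grids_error():
    grid = coarse_grid()
    with pytest.raises(ValueError, match="theta grid"):
        sequential_update([np.ones(3)], grid)


def test_mod_null_is_zero():
    grid = coarse_grid()
    lrs = [np.ones((grid.n_models, len(grid.thetas)))]
    mod, model, theta = mod_score(lrs, grid)
    assert mod == pytest.approx(0.0)


def test_mod_bounds_integrated_br(small_cohort, small_cohort_coding):
    grid = power_grid()
    lrs = list(_lr_matrices(small_cohort, small_cohort_coding,
                            grid).values())
    mod, _, _ = mod_score(lrs, grid)
    _, br = bayes_ratio_curve(lrs, grid)
    assert mod >= np.log10(br) - 1e-9  # max over grid >= weighted mean


def test_family_lod_degenerate_cases(trio):
    geno = {"1": (1, 2), "2": (1, 1), "3": (1, 2)}
    coding = {("f1", "1"): "affected", ("f1", "2"): "unaffected",
              ("f1", "3"): "affected"}
    m_null = TraitModel("dichotomous", 0.01, (0.0, 1.0, 1.0), alpha=1.0)
    assert family_lod(trio, geno, coding, m_null, 0.5, 0.3) == 0.0
    m_tiny = TraitModel("dichotomous", 0.01, (0.0, 1.0, 1.0), alpha=1e-12)
    assert family_lod(trio, geno, coding, m_tiny, 0.1, 0.3) == \
        pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Scans and critical regions

def test_scan_single_marker_equals_direct(small_cohort, small_cohort_coding):
    grid = power_grid()
    sub_map = type(small_cohort.marker_map)(
        small_cohort.marker_map.table.iloc[[1]].reset_index(drop=True))
    df = scan(small_cohort.pedigrees, small_cohort.genotypes, sub_map,
              small_cohort_coding, grid, mode="pooled")
    lrs = list(_lr_matrices(small_cohort, small_cohort_coding, grid,
                            "M2").values())
    _, br = bayes_ratio_curve(lrs, grid)
    assert df.loc[0, "BR"] == pytest.approx(br, rel=1e-12)
    assert df.loc[0, "PPL"] == pytest.approx(ppl_from_br(br), rel=1e-12)


def test_scan_requires_information(small_cohort):
    with pytest.raises(ValueError, match="no information"):
        scan(small_cohort.pedigrees, small_cohort.genotypes,
             small_cohort.marker_map, {}, power_grid(), mode="pooled")


def test_scan_per_stratum_covers_cohort(small_cohort, small_cohort_coding):
    grid = power_grid()
    strata = {"w1t1": [p.family_id for p in small_cohort.pedigrees]}
    df = scan(small_cohort.pedigrees, small_cohort.genotypes,
              small_cohort.marker_map, small_cohort_coding, grid,
              mode="per_stratum", strata=strata)
    assert "PPL_w1t1" in df.columns and len(df) == 4


def _ppl_df(ppls, chrom="1"):
    n = len(ppls)
    return pd.DataFrame({
        "chrom": [chrom] * n, "cM": np.arange(n) * 10.0,
        "bp": (np.arange(n) + 1) * 1_000_000, "PPL": ppls,
    })


def test_critical_region_hand_trace():
    r = critical_region(_ppl_df([0.01, 0.06, 0.30, 0.57, 0.20, 0.04]))
    assert (r.lo_cM, r.hi_cM) == (10.0, 40.0)
    assert r.peak_cM == 30.0 and r.peak_ppl == 0.57
    assert r.width_Mb == pytest.approx(3.0)


def test_critical_region_none_below_threshold():
    assert critical_region(_ppl_df([0.01, 0.02, 0.04])) is None


def test_critical_region_clamps_to_chromosome_end():
    r = critical_region(_ppl_df([0.01, 0.10, 0.30, 0.60]))
    assert r.hi_cM == 30.0 and r.peak_cM == 30.0


def test_critical_region_tie_takes_smallest_cM():
    r = critical_region(_ppl_df([0.01, 0.40, 0.40, 0.01]))
    assert r.peak_cM == 10.0


# ---------------------------------------------------------------------------
# PPLD

def _snp_genotypes(cohort, dprime, rng):
    snp = {}
    for ped in cohort.pedigrees:
        snp[ped.family_id] = {}
        for m in ped:
            dose = cohort.trait_doses[(ped.family_id, m.individual_id)]
            if rng.random() < dprime and dose > 0:
                gt = (2, 2) if dose >= 2 else (1, 2)
            else:
                gt = (1, 2) if rng.random() < 0.3 else (1, 1)
            snp[ped.family_id][m.individual_id] = gt
    return snp


def test_ppld_collapsed_grid_returns_prior(small_cohort,
                                           small_cohort_coding):
    snp = _snp_genotypes(small_cohort, 0.0, np.random.default_rng(0))
    val = ppld(small_cohort.pedigrees, snp, small_cohort_coding,
               power_grid(), snp_maf=0.2, prior_ld=0.02, dprime_grid=())
    assert val == pytest.approx(0.02)


def test_ppld_monotone_in_association(small_cohort, small_cohort_coding):
    vals = []
    for dp in (0.0, 0.5, 0.95):
        snp = _snp_genotypes(small_cohort, dp, np.random.default_rng(3))
        vals.append(ppld(small_cohort.pedigrees, snp, small_cohort_coding,
                         power_grid(), snp_maf=0.2))
    assert vals[0] < vals[2]
    assert 0 < min(vals) and max(vals) < 1


def test_ppld_monomorphic_snp_rejected(small_cohort, small_cohort_coding):
    with pytest.raises(ValueError, match="monomorphic"):
        ppld(small_cohort.pedigrees, {}, small_cohort_coding, power_grid(),
             snp_maf=0.0)


def test_ppld_reporting_rule():
    # posteriors at or below 5% are flagged "not pursued" downstream
    assert ppl_from_br(1.0, 0.02) <= 0.05
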
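"""Posterior probability of linkage (PPL) machinery.

For each family f and marker, the engine computes the likelihood-ratio
matrix LR_f[m, t] = L_f(θ_t, model_m) / L_f(0.5, model_m) by Elston–Stewart
peeling.  Everything downstream is arithmetic on those matrices:

* Bayes ratio curve   BR(θ) = Σ_m w_m Σ_α w_α Π_f [α·LR_f + (1−α)]
* integrated BR       BR = Σ_θ w_θ BR(θ)
* PPL                 π·BR / (π·BR + 1 − π), prior π = 2%
* sequential updating Π over strata of the per-stratum BR(θ), θ shared
* MOD score           max over (model, α, θ) of Σ_f log10 admixture-LR

Products over families run in log space so cohorts of a hundred families
with extreme penetrances stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import peeling
from .grids import TraitModel, TraitModelGrid, PRIOR_LINKAGE
from .pedio import GenotypeMatrix, MarkerMap, Pedigree

AFFECTION_STATES = ("affected", "unaffected", "unknown")


# ---------------------------------------------------------------------------
# Per-family likelihoods

def _evidence_for(coding_value, kind, effects):
    """(M, 16) trait evidence for one individual under all grid models."""
    if kind == "dichotomous":
        v = coding_value if coding_value in AFFECTION_STATES else "unknown"
        return peeling.dichotomous_evidence(v, effects)
    z = coding_value
    if z is None or isinstance(z, str):
        z = np.nan
    return peeling.quantitative_evidence(float(z), effects)


def _founder_prior_batch(p_disease: np.ndarray, maf: float) -> np.ndarray:
    pt = np.stack([1.0 - p_disease, p_disease], axis=1)       # (M, 2)
    pm = np.array([1.0 - maf, maf])
    h = pt[:, :, None] * pm[None, None, :]                    # (M, 2, 2)
    return (h[:, peeling.PAT_TRAIT, peeling.PAT_MARK]
            * h[:, peeling.MAT_TRAIT, peeling.MAT_MARK])      # (M, 16)


def _family_factors(pedigree, marker_genotypes, coding, grid, maf):
    """Unary factor list (individual -> (M,16)) with priors folded in."""
    prior = _founder_prior_batch(grid.p_disease, maf)
    factors = []
    for m in pedigree:
        iid = m.individual_id
        ev = _evidence_for(coding.get((pedigree.family_id, iid)),
                           grid.kind, grid.effects)
        ev = ev * peeling.marker_indicator(marker_genotypes.get(iid, (0, 0)))
        if m.is_founder:
            ev = ev * prior
        factors.append(((iid,), ev))
    return factors


def family_likelihoods_by_theta(pedigree, marker_genotypes, coding,
                                grid: TraitModelGrid, maf,
                                thetas=None) -> np.ndarray:
    """(M, T) likelihoods for every grid model × recombination fraction."""
    if pedigree.loops_flag:
        raise peeling.PedigreeError(
            f"family {pedigree.family_id}: looped pedigree unsupported"
        )
    if thetas is None:
        thetas = grid.thetas
    unaries = _family_factors(pedigree, marker_genotypes, coding, grid, maf)
    names = [m.individual_id for m in pedigree]
    out = np.empty((grid.n_models, len(thetas)))
    for t, theta in enumerate(thetas):
        trans = peeling.transmission_tensor(theta)
        factors = list(unaries)
        for m in pedigree.nonfounders:
            factors.append(((m.individual_id, m.father_id, m.mother_id), trans))
        out[:, t] = peeling.eliminate(factors, names)
    return out


def family_lr_matrix(pedigree, marker_genotypes, coding,
                     grid: TraitModelGrid, maf) -> np.ndarray:
    """(M, T) likelihood ratios against θ = 0.5.

    Models under which the family data are impossible (zero likelihood at
    every θ) carry no linkage information and get LR ≡ 1.
    """
    thetas = list(grid.thetas)
    if 0.5 not in thetas:
        thetas = thetas + [0.5]
    lik = family_likelihoods_by_theta(
        pedigree, marker_genotypes, coding, grid, maf, thetas
    )
    null = lik[:, thetas.index(0.5)]
    lr = np.ones((grid.n_models, len(grid.thetas)))
    ok = null > 0
    lr[ok] = lik[ok, : len(grid.thetas)] / null[ok, None]
    return lr


def pedigree_likelihood(pedigree, marker_genotypes, coding,
                        model: TraitModel, theta: float,
                        maf: float = 0.25) -> float:
    """Single-model two-locus pedigree likelihood (spec-level operation)."""
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta outside [0, 0.5]: {theta}")
    effects = np.asarray(model.effects)[None, :]
    evidence = {}
    for m in pedigree:
        ev = _evidence_for(coding.get((pedigree.family_id, m.individual_id)),
                           model.kind, effects)[0]
        evidence[m.individual_id] = ev
    res = peeling.family_likelihood(
        pedigree, marker_genotypes, evidence, theta,
        model.p_disease, maf,
    )
    return float(res)


def family_lod(pedigree, marker_genotypes, coding, model: TraitModel,
               theta: float, maf: float = 0.25) -> float:
    """log10 admixture likelihood ratio of one family versus θ = 0.5."""
    l_theta = pedigree_likelihood(pedigree, marker_genotypes, coding,
                                  model, theta, maf)
    l_null = pedigree_likelihood(pedigree, marker_genotypes, coding,
                                 model, 0.5, maf)
    if l_null <= 0:
        return 0.0
    lr = l_theta / l_null
    with np.errstate(divide="ignore"):
        return float(np.log10(model.alpha * lr + (1.0 - model.alpha)))


# ---------------------------------------------------------------------------
# Bayes ratios and PPL

def _coding_informative(pedigrees, coding) -> bool:
    for ped in pedigrees:
        for m in ped:
            v = coding.get((ped.family_id, m.individual_id))
            if isinstance(v, str) and v in ("affected", "unaffected"):
                return True
            if isinstance(v, (int, float)) and np.isfinite(v):
                return True
    return False


def bayes_ratio_curve(lr_matrices, grid: TraitModelGrid):
    """Integrate per-family LR matrices into BR(θ) and the integrated BR.

    Returns (br_theta (T,), integrated_br).  Computation is in log space:
    log Π_f (α·LR + 1−α) summed over families, then a weighted logsumexp
    over models and α.
    """
    lrs = np.stack(lr_matrices)                       # (F, M, T)
    alphas = grid.alphas[None, None, :, None]
    with np.errstate(divide="ignore"):
        log_terms = np.log(lrs[:, :, None, :] * alphas + (1 - alphas))
    s = log_terms.sum(axis=0)                         # (M, A, T)
    logw = (np.log(grid.model_weights)[:, None, None]
            + np.log(grid.alpha_weights)[None, :, None])
    log_br_theta = logsumexp(s + logw, axis=(0, 1))   # (T,)
    br_theta = np.exp(log_br_theta)
    integrated = float(np.exp(logsumexp(log_br_theta,
                                        b=grid.theta_weights)))
    return br_theta, integrated


def ppl_from_br(br: float, prior: float = PRIOR_LINKAGE) -> float:
    """Posterior probability of linkage from an integrated Bayes ratio."""
    if br <= 0:
        raise ValueError(f"Bayes ratio must be positive: {br}")
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior outside (0,1): {prior}")
    return prior * br / (prior * br + 1.0 - prior)


def sequential_update(stratum_br_curves, grid: TraitModelGrid,
                      prior: float | None = None):
    """Combine per-stratum BR(θ) curves by multiplication at shared θ.

    Trait-model parameters (and α) were already integrated within each
    stratum; only θ is shared.  Returns (combined BR, PPL).
    """
    curves = [np.asarray(c, dtype=float) for c in stratum_br_curves]
    if not curves:
        raise ValueError("no strata to combine")
    n = len(grid.thetas)
    for c in curves:
        if c.shape != (n,):
            raise ValueError("stratum BR curve not on the shared theta grid")
    log_prod = np.sum([np.log(c) for c in curves], axis=0)
    br = float(np.exp(logsumexp(log_prod, b=grid.theta_weights)))
    ppl = ppl_from_br(br, prior if prior is not None else grid.prior_linkage)
    return br, ppl


def mod_score(lr_matrices, grid: TraitModelGrid):
    """Fully maximized LOD over (model, α, θ) with its maximizing model."""
    if grid.n_models == 0 or len(grid.thetas) == 0:
        raise ValueError("empty search grid")
    lrs = np.stack(lr_matrices)                       # (F, M, T)
    alphas = grid.alphas[None, None, :, None]
    with np.errstate(divide="ignore"):
        log10_terms = np.log10(lrs[:, :, None, :] * alphas + (1 - alphas))
    s = log10_terms.sum(axis=0)                       # (M, A, T)
    m, a, t = np.unravel_index(np.argmax(s), s.shape)
    model = TraitModel(
        kind=grid.kind,
        p_disease=float(grid.p_disease[m]),
        effects=tuple(grid.effects[m]),
        alpha=float(grid.alphas[a]),
    )
    return float(s[m, a, t]), model, float(grid.thetas[t])


# ---------------------------------------------------------------------------
# Scans

@dataclass
class ScanConfig:
    mode: str = "sequential"      # sequential | pooled | per_stratum
    prior: float = PRIOR_LINKAGE


def _marker_geno_dict(pedigree, genotypes: GenotypeMatrix, marker):
    col_rows = genotypes.rows_for_family(pedigree)
    col = genotypes.column(marker)
    return {iid: tuple(col[row]) for iid, row in col_rows.items()}


def scan(pedigrees, genotypes: GenotypeMatrix, marker_map: MarkerMap,
         coding, grid: TraitModelGrid, mode: str = "sequential",
         strata: dict | None = None,
         prior: float = PRIOR_LINKAGE) -> pd.DataFrame:
    """Two-point scan along the marker panel.

    ``coding`` maps (family_id, individual_id) to trait values; ``strata``
    maps a stratum label to its family-id roster (required for sequential
    and per-stratum modes).  Returns one row per marker with BR, PPL, MOD
    and the maximizing model; per-stratum PPL columns in stratified modes.
    """
    if mode not in ("sequential", "pooled", "per_stratum"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if mode != "pooled" and strata is None:
        strata = {"all": [p.family_id for p in pedigrees]}
    if not _coding_informative(pedigrees, coding):
        raise ValueError("no information: trait coding is unknown everywhere")
    by_fam = {p.family_id: p for p in pedigrees}

    rows = []
    for _, mrow in marker_map.table.iterrows():
        marker, maf = mrow["name"], float(mrow["maf"])
        lr_by_fam = {}
        for ped in pedigrees:
            mg = _marker_geno_dict(ped, genotypes, marker)
            lr_by_fam[ped.family_id] = family_lr_matrix(
                ped, mg, coding, grid, maf
            )
        all_lrs = [lr_by_fam[p.family_id] for p in pedigrees]
        mod, mx_model, mx_theta = mod_score(all_lrs, grid)

        rec = {
            "chrom": mrow["chrom"], "marker": marker,
            "cM": float(mrow["cM"]), "bp": int(mrow["bp"]),
            "MOD": mod, "theta_hat": mx_theta,
            "p_D": mx_model.p_disease, "alpha": mx_model.alpha,
        }
        eff_names = (("f0", "f1", "f2") if grid.kind == "dichotomous"
                     else ("mu0", "mu1", "mu2"))
        for name, val in zip(eff_names, mx_model.effects):
            rec[name] = val

        if mode == "pooled":
            _, br = bayes_ratio_curve(all_lrs, grid)
            rec["BR"], rec["PPL"] = br, ppl_from_br(br, prior)
        else:
            curves = []
            for label, fams in strata.items():
                lrs = [lr_by_fam[f] for f in fams if f in lr_by_fam]
                if not lrs:
                    curve = np.ones(len(grid.thetas))
                    stratum_br = 1.0
                else:
                    curve, stratum_br = bayes_ratio_curve(lrs, grid)
                curves.append(curve)
                rec[f"PPL_{label}"] = ppl_from_br(stratum_br, prior)
            br, ppl = sequential_update(curves, grid, prior)
            rec["BR"], rec["PPL"] = br, ppl
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Critical regions

@dataclass
class CriticalRegion:
    chrom: str
    peak_cM: float
    peak_bp: int
    lo_cM: float
    hi_cM: float
    lo_bp: int
    hi_bp: int
    peak_ppl: float

    @property
    def width_Mb(self) -> float:
        return (self.hi_bp - self.lo_bp) / 1e6

    def contains_bp(self, chrom, pos) -> bool:
        # half-open [lo_bp, hi_bp)
        return str(chrom) == str(self.chrom) and self.lo_bp <= pos < self.hi_bp

    def overlaps_bp(self, chrom, start, end) -> bool:
        return (str(chrom) == str(self.chrom)
                and start < self.hi_bp and end > self.lo_bp)


def critical_region(scan_df: pd.DataFrame,
                    threshold: float = 0.05) -> CriticalRegion | None:
    """Extract the critical region around a chromosome's PPL peak.

    Walks outward from the maximum-PPL position (ties → smallest cM) until
    the PPL drops below ``threshold`` or the chromosome ends.  Returns None
    when no position reaches the threshold.
    """
    if scan_df["chrom"].nunique() != 1:
        raise ValueError("critical_region expects a single chromosome")
    df = scan_df.sort_values("cM").reset_index(drop=True)
    ppl = df["PPL"].to_numpy()
    if (ppl < threshold).all():
        return None
    peak = int(np.argmax(ppl))  # argmax returns the first (smallest cM) tie
    lo = peak
    while lo - 1 >= 0 and ppl[lo - 1] >= threshold:
        lo -= 1
    hi = peak
    while hi + 1 < len(ppl) and ppl[hi + 1] >= threshold:
        hi += 1
    return CriticalRegion(
        chrom=str(df.loc[peak, "chrom"]),
        peak_cM=float(df.loc[peak, "cM"]), peak_bp=int(df.loc[peak, "bp"]),
        lo_cM=float(df.loc[lo, "cM"]), hi_cM=float(df.loc[hi, "cM"]),
        lo_bp=int(df.loc[lo, "bp"]), hi_bp=int(df.loc[hi, "bp"]),
        peak_ppl=float(ppl[peak]),
    )


# ---------------------------------------------------------------------------
# PPLD (posterior probability of linkage disequilibrium), simplified

DPRIME_GRID_DEFAULT = (0.2, 0.4, 0.6, 0.8, 1.0)


def _haplotype_freqs(p_disease: float, maf: float, dprime: float) -> np.ndarray:
    """2×2 trait×marker haplotype frequencies at standardized LD D′ ≥ 0
    (positive association between disease allele and minor allele)."""
    d_max = min(p_disease * (1 - maf), (1 - p_disease) * maf)
    d = dprime * d_max
    h = np.array([
        [(1 - p_disease) * (1 - maf) + d, (1 - p_disease) * maf - d],
        [p_disease * (1 - maf) - d, p_disease * maf + d],
    ])
    return np.clip(h, 0.0, 1.0)


def ppld(pedigrees, snp_genotypes_by_family: dict, coding,
         grid: TraitModelGrid, snp_maf: float,
         prior_ld: float = 0.02,
         dprime_grid=DPRIME_GRID_DEFAULT) -> float:
    """Posterior probability of trait–SNP linkage disequilibrium.

    The trait locus is placed at the SNP (θ = 0); the Bayes ratio compares
    the likelihood integrated over trait models and a D′ grid of founder
    haplotype frequencies against the same models at D′ = 0 (linkage
    equilibrium).  α is fixed at 1 (association is within-locus).
    """
    if not 0 < snp_maf <= 0.5:
        raise ValueError(f"monomorphic or invalid SNP (maf={snp_maf})")
    dprime_grid = tuple(dprime_grid)

    def integrated_lik(dprime):
        total_log = 0.0
        for ped in pedigrees:
            mg = snp_genotypes_by_family[ped.family_id]
            liks = np.empty(grid.n_models)
            for m in range(grid.n_models):
                h = _haplotype_freqs(float(grid.p_disease[m]), snp_maf, dprime)
                evidence = {}
                eff = grid.effects[m][None, :]
                for mem in ped:
                    evidence[mem.individual_id] = _evidence_for(
                        coding.get((ped.family_id, mem.individual_id)),
                        grid.kind, eff,
                    )[0]
                liks[m] = peeling.family_likelihood(
                    ped, mg, evidence, 0.0, 0.5, snp_maf,
                    haplotype_freqs=h,
                )
            total_log += logsumexp(np.log(np.maximum(liks, 1e-300)),
                                   b=grid.model_weights)
        return total_log

    log_null = integrated_lik(0.0)
    if not dprime_grid or all(d == 0 for d in dprime_grid):
        br = 1.0
    else:
        logs = np.array([integrated_lik(d) for d in dprime_grid])
        br = float(np.exp(logsumexp(logs - log_null)
                          - np.log(len(dprime_grid))))
    return ppl_from_br(br, prior_ld)
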
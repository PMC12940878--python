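"""Synthetic multiplex-family cohort generator.

Emulates the study design the analysis modules expect: two recruitment
waves (defaults 79 and 36 families, mean family size ≈ 5.6) each split
into two tiers, a diallelic trait locus with a penetrance vector / gene
frequency / admixture proportion α, SNP panels with MAF > 30%, rejection-
sampled ascertainment (a family enters only if it satisfies its wave's
proband rules), and plantable rare variants / expression tables for the
prioritization pipeline.

The trait-locus genotype is simulated explicitly — on the marker
chromosome for linked families, on an independent phantom chromosome for
unlinked ones — and then hidden: it never appears in genotype output.
A disease allele is seeded into one founder per family so multiplex
ascertainment is feasible at rare gene frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import chromosome_layout, drop_family_haplotypes
from .grids import TraitModel
from .pedio import (GenotypeMatrix, Individual, MarkerMap, Pedigree,
                    empty_phenotype_table)
from .phenotypes import code_LI

ATTEMPT_CAP = 10_000


@dataclass
class StratumPlan:
    wave: int
    tier: int
    n_families: int
    ascertainment: str = "wave1"   # "wave1" | "wave2"
    #: stratum-specific linked-family proportion (None → the trait model's α;
    #: 0.0 makes the stratum entirely unlinked, for heterogeneity scenarios)
    alpha_override: float | None = None


@dataclass
class SyntheticCohortConfig:
    """Generator contract; defaults mirror the study conditions."""

    seed: int = 0
    strata: tuple = (
        StratumPlan(1, 1, 40, "wave1"),
        StratumPlan(1, 2, 39, "wave1"),
        StratumPlan(2, 1, 18, "wave2"),
        StratumPlan(2, 2, 18, "wave2"),
    )
    trait_model: TraitModel = field(
        default_factory=lambda: TraitModel(
            "dichotomous", 0.001, (0.0, 0.7, 0.9), alpha=0.9
        )
    )
    target_trait: str = "LI_star"
    # family shape
    p_three_generations: float = 0.3
    sibship_range: tuple = (2, 3)
    # marker panel: evenly spaced, MAF > 30%
    n_markers: int = 10
    n_chromosomes: int = 2
    spacing_cM: float = 10.0
    maf_range: tuple = (0.3, 0.5)
    trait_locus_marker: int = 2    # panel index the trait locus sits on
    # raw-field synthesis
    p_asd_given_affected: float = 0.5
    p_li_given_affected: float = 0.8

    def __post_init__(self):
        if not 0 < self.trait_model.alpha <= 1:
            raise ValueError("alpha outside (0,1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("MAF range outside (0, 0.5]")
        if not 0 <= self.trait_locus_marker < self.n_markers:
            raise ValueError("trait locus outside the map")


@dataclass
class Cohort:
    pedigrees: list
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    marker_map: MarkerMap
    linked_families: set
    trait_doses: dict              # (family_id, individual_id) -> 0/1/2
    config: SyntheticCohortConfig = None

    @property
    def strata(self) -> dict:
        out = {}
        sub = self.phenotypes.drop_duplicates("family_id")
        for r in sub.itertuples():
            out.setdefault((int(r.wave), int(r.tier)), []).append(r.family_id)
        return out

    def n_individuals(self) -> int:
        return sum(len(p) for p in self.pedigrees)


def make_marker_map(config: SyntheticCohortConfig,
                    rng: np.random.Generator) -> MarkerMap:
    per_chrom = int(np.ceil(config.n_markers / config.n_chromosomes))
    rows = []
    i = 0
    for c in range(1, config.n_chromosomes + 1):
        for j in range(per_chrom):
            if i >= config.n_markers:
                break
            rows.append({
                "chrom": str(c),
                "name": f"M{i + 1}",
                "cM": 5.0 + j * config.spacing_cM,
                "bp": int(1_000_000 + j * 1_000_000),
                "allele1": "A", "allele2": "B",
                "maf": float(np.round(rng.uniform(*config.maf_range), 3)),
            })
            i += 1
    return MarkerMap(pd.DataFrame(rows))


def _sample_structure(fam_id: str, rng: np.random.Generator,
                      config: SyntheticCohortConfig) -> Pedigree:
    """Two- or three-generation family around one founder couple."""
    lo, hi = config.sibship_range
    members = [
        Individual(fam_id, "1", None, None, "male"),
        Individual(fam_id, "2", None, None, "female"),
    ]
    n_kids = int(rng.integers(lo, hi + 1))
    kids = []
    for k in range(n_kids):
        sex = "male" if rng.random() < 0.5 else "female"
        kids.append(Individual(fam_id, str(3 + k), "1", "2", sex))
    members += kids
    if rng.random() < config.p_three_generations and kids:
        parent = kids[int(rng.integers(0, len(kids)))]
        spouse_sex = "female" if parent.sex == "male" else "male"
        spouse = Individual(fam_id, "90", None, None, spouse_sex)
        members.append(spouse)
        father, mother = ((parent, spouse) if parent.sex == "male"
                          else (spouse, parent))
        for k in range(int(rng.integers(lo, hi + 1))):
            sex = "male" if rng.random() < 0.5 else "female"
            members.append(Individual(fam_id, str(91 + k),
                                      father.individual_id,
                                      mother.individual_id, sex))
    return Pedigree(fam_id, members)


def _trait_locus_layout(marker_map: MarkerMap, config, linked: bool):
    """Insert the hidden trait locus into the recombination layout.

    Returns (chrom_slices, thetas, freqs, trait_index) over the extended
    locus vector (markers plus one trait slot)."""
    t = marker_map.table
    mafs = t["maf"].to_numpy(dtype=float)
    if linked:
        ext = t.copy()
        target = t.iloc[config.trait_locus_marker]
        row = target.copy()
        row["name"] = "__trait__"
        row["cM"] = target["cM"] + 1e-9  # coincident with its marker
        row["bp"] = target["bp"] + 1
        ext = pd.concat(
            [ext.iloc[: config.trait_locus_marker + 1],
             row.to_frame().T,
             ext.iloc[config.trait_locus_marker + 1:]],
            ignore_index=True,
        )
        trait_index = config.trait_locus_marker + 1
    else:
        ext = pd.concat(
            [t, pd.DataFrame([{
                "chrom": "__phantom__", "name": "__trait__",
                "cM": 0.0, "bp": 1, "allele1": "d", "allele2": "D",
                "maf": 0.0,
            }])],
            ignore_index=True,
        )
        trait_index = len(ext) - 1
    chrom_slices, thetas = chromosome_layout(ext)
    freqs = np.empty(len(ext))
    k = 0
    for i in range(len(ext)):
        if i == trait_index:
            freqs[i] = 0.0
        else:
            freqs[i] = mafs[k]
            k += 1
    return chrom_slices, thetas, freqs, trait_index


def _synthesize_phenotypes(ped: Pedigree, doses: dict, config,
                           rng: np.random.Generator, wave: int) -> list:
    """Raw phenotype rows realizing the target trait from trait doses."""
    f = np.asarray(config.trait_model.effects)
    quantitative = config.trait_model.kind == "quantitative"
    rows = []
    for m in ped:
        g = doses[m.individual_id]
        if quantitative:
            z = rng.normal(f[g], 1.0)
            affected = z >= 1.0
        else:
            z = rng.normal(1.5 if rng.random() < f[g] else -0.2, 0.5)
            affected = rng.random() < f[g]
        asd = affected and rng.random() < config.p_asd_given_affected
        # non-ASD affecteds express the target impairment itself; ASD
        # members have a concomitant language impairment with p_li
        li = affected and not asd
        asd_li = asd and rng.random() < config.p_li_given_affected
        has_li_fields = li or asd_li
        reading_impaired = affected and config.target_trait == "RI_star"
        rows.append({
            "family_id": ped.family_id,
            "individual_id": m.individual_id,
            "asd": "yes" if asd else "no",
            "li": None,
            "ri": None,
            "piq": 95.0,
            "celf_core": 78.0 if has_li_fields else 102.0,
            "oral_subtest_z": None,
            "intervention_history": bool(has_li_fields),
            "reading_subtest_z": (
                [-1.5, -1.2, -1.1, 0.1, -1.3] if reading_impaired
                else [0.2, 0.4, -0.1, 0.5, 0.3]
            ),
            "srs_t": float(np.clip(50 + 10 * z, 30, 95)),
            "srs_rirb_t": float(np.clip(50 + 10 * (0.8 * z + rng.normal(0, 0.6)),
                                        30, 95)),
            "wave": wave,
            "tier": None,   # filled by the caller
        })
    return rows


def ascertain(pheno_rows, rule: str) -> bool:
    """Wave-specific family ascertainment.

    wave1: ≥1 ASD member and ≥1 non-ASD member meeting LI criteria.
    wave2: the wave-1 pattern, or a multiplex ASD family (≥2 ASD) in which
    at least one ASD proband has LI — and, with no non-ASD LI member in
    the family, both ASD probands must be language impaired.
    """
    wave = 1 if rule == "wave1" else 2
    asd, li = [], []
    for r in pheno_rows:
        asd.append(r.get("asd") == "yes")
        li.append(code_LI(r, wave) == "yes")
    n_asd = sum(asd)
    nonasd_li = sum(l and not a for a, l in zip(asd, li))
    asd_li = sum(l and a for a, l in zip(asd, li))
    base = n_asd >= 1 and nonasd_li >= 1
    if rule == "wave1":
        return base
    if rule == "wave2":
        return base or (n_asd >= 2 and asd_li >= 2)
    raise ValueError(f"unknown ascertainment rule {rule!r}")


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate the full cohort (pedigrees, genotypes, phenotypes, map)."""
    rng = np.random.default_rng(config.seed)
    marker_map = make_marker_map(config, rng)
    n_markers = len(marker_map)

    pedigrees, sample_ids, geno_rows = [], [], []
    pheno_rows_all = []
    linked_families = set()
    trait_doses = {}
    fam_counter = 0

    for plan in config.strata:
        alpha = (config.trait_model.alpha if plan.alpha_override is None
                 else plan.alpha_override)
        for _ in range(plan.n_families):
            fam_counter += 1
            fam_id = f"F{fam_counter:04d}"
            accepted = None
            for attempt in range(ATTEMPT_CAP):
                ped = _sample_structure(fam_id, rng, config)
                linked = rng.random() < alpha
                layout = _trait_locus_layout(marker_map, config, linked)
                chrom_slices, thetas, freqs, trait_index = layout
                # seed one disease allele in a random founder so multiplex
                # ascertainment is reachable at rare gene frequencies
                founders = ped.founders
                seeded = founders[int(rng.integers(0, len(founders)))]
                fh = {}
                n_loci = len(freqs)
                hap0 = (rng.random(n_loci) < freqs).astype(np.int8)
                hap1 = (rng.random(n_loci) < freqs).astype(np.int8)
                hap0[trait_index] = 1
                fh[seeded.individual_id] = (hap0, hap1)
                # remaining founders may carry at the population frequency
                pop_freqs = freqs.copy()
                pop_freqs[trait_index] = config.trait_model.p_disease
                haps = drop_family_haplotypes(
                    ped, pop_freqs, chrom_slices, thetas, rng,
                    founder_haps=fh,
                )
                doses = {
                    iid: int(h[0][trait_index] + h[1][trait_index])
                    for iid, h in haps.items()
                }
                rows = _synthesize_phenotypes(ped, doses, config, rng,
                                              plan.wave)
                if ascertain(rows, plan.ascertainment):
                    accepted = (ped, haps, doses, rows, linked, trait_index)
                    break
            if accepted is None:
                raise RuntimeError(
                    f"family {fam_id}: ascertainment infeasible after "
                    f"{ATTEMPT_CAP} attempts (rule {plan.ascertainment}; "
                    "acceptance rate ~0)"
                )
            ped, haps, doses, rows, linked, trait_index = accepted
            pedigrees.append(ped)
            if linked:
                linked_families.add(fam_id)
            marker_idx = [i for i in range(len(haps[ped.members[0].individual_id][0]))
                          if i != trait_index]
            for m in ped:
                h = haps[m.individual_id]
                sample_ids.append((fam_id, m.individual_id))
                geno_rows.append(np.stack(
                    [h[0][marker_idx] + 1, h[1][marker_idx] + 1], axis=1
                ))
                trait_doses[(fam_id, m.individual_id)] = doses[m.individual_id]
            for r in rows:
                r["tier"] = plan.tier
            pheno_rows_all += rows

    genotypes = GenotypeMatrix(
        sample_ids, marker_map.names,
        np.stack(geno_rows).astype(np.int8),
    )
    pheno = pd.DataFrame(pheno_rows_all)
    return Cohort(
        pedigrees=pedigrees, genotypes=genotypes, phenotypes=pheno,
        marker_map=marker_map, linked_families=linked_families,
        trait_doses=trait_doses, config=config,
    )


def heterogeneity_scenario_config(seed: int, n_linked: int = 30,
                                  n_unlinked: int = 15,
                                  trait_model: TraitModel | None = None,
                                  ) -> SyntheticCohortConfig:
    """Two-stratum heterogeneity scenario: stratum A linked under a
    dominant-style model (default f=(0, 0.7, 0.9), p_D=0.001, α=0.9),
    stratum B entirely unlinked.

    Power settings (extended informative pedigrees: sibships of 3–4,
    half the families three-generation, high-MAF panel, trait locus on
    the first marker) are fixed here so the scenario's qualitative
    signature — sequential PPL above pooled PPL at the planted locus and
    near-null stratum-B PPL — is reproducible at desk scale.
    """
    if trait_model is None:
        trait_model = TraitModel("dichotomous", 0.001, (0.0, 0.7, 0.9),
                                 alpha=0.9)
    return SyntheticCohortConfig(
        seed=seed,
        strata=(StratumPlan(1, 1, n_linked, "wave1"),
                StratumPlan(2, 1, n_unlinked, "wave2", alpha_override=0.0)),
        trait_model=trait_model,
        n_markers=2, n_chromosomes=1, trait_locus_marker=0, spacing_cM=20.0,
        sibship_range=(3, 4), p_three_generations=0.5, maf_range=(0.4, 0.5),
    )


# ---------------------------------------------------------------------------
# Rare-variant / expression fixtures

@dataclass
class GenePlan:
    symbol: str
    chrom: str
    start: int
    end: int
    carrier_families: tuple = ()
    inheritance: str = "dominant"
    penetrance: float = 0.9        # P(carrier | affected descendant)
    leak: float = 0.1              # P(carrier | unaffected descendant)
    population_maf: float = 0.002
    n_variants: int = 1
    tpm_by_db: tuple = (8.0, 6.0, 7.0)
    ndd_flag: bool = False
    sfari_flag: bool = False
    carriers_only_unaffected: bool = False


def _plant_in_family(ped: Pedigree, affected: set, plan: GenePlan,
                     rng: np.random.Generator) -> dict:
    """Carrier map for one family: a founder carrier whose descendants
    inherit with affection-enriched (or, for decoys, unaffected-only)
    transmission; Mendelian in the sense that every carrier's parent
    chain back to the founder carries."""
    founders = ped.founders
    if plan.carriers_only_unaffected:
        pool = [f for f in founders if f.individual_id not in affected]
        founder = pool[0] if pool else founders[0]
    else:
        # an affected founder (when one exists) anchors co-segregation:
        # the trait allele then travels with the variant haplotype
        founder = max(
            founders,
            key=lambda f: (
                f.individual_id in affected,
                sum(1 for iid in affected
                    if f.individual_id in ped.ancestors(iid)),
            ),
        )
    carriers = {(ped.family_id, founder.individual_id): 1}

    def descend(iid):
        for child in ped.children_of(iid):
            cid = child.individual_id
            if plan.carriers_only_unaffected:
                p = 0.0 if cid in affected else 0.7
            else:
                p = plan.penetrance if cid in affected else plan.leak
            if rng.random() < p:
                carriers[(ped.family_id, cid)] = 1
                descend(cid)
    descend(founder.individual_id)
    # everyone else in the family is sequenced non-carrier
    for m in ped:
        carriers.setdefault((ped.family_id, m.individual_id), 0)
    return carriers


def plant_rare_variants(cohort: Cohort, plans, seed: int = 0,
                        coding: dict | None = None):
    """Materialize planned rare variants and gene annotations.

    ``coding`` supplies affection (defaults to trait-dose > 0 carriers of
    the cohort's trait locus being affected is unknowable here, so pass
    the derived trait coding for realistic co-segregation).  Returns
    (variants, annotations dict).
    """
    from .prioritize import GeneAnnotation, VariantRecord

    rng = np.random.default_rng(seed)
    by_fam = {p.family_id: p for p in cohort.pedigrees}
    variants, annotations = [], {}
    for plan in plans:
        annotations[plan.symbol] = GeneAnnotation(
            symbol=plan.symbol, chrom=plan.chrom,
            start=plan.start, end=plan.end,
            tpm_by_db=tuple(plan.tpm_by_db),
            ndd_flag=plan.ndd_flag, sfari_flag=plan.sfari_flag,
        )
        unknown = [f for f in plan.carrier_families if f not in by_fam]
        if unknown:
            raise ValueError(
                f"gene {plan.symbol}: plan references unknown families "
                f"{unknown}"
            )
        span = plan.end - plan.start
        for v in range(plan.n_variants):
            carriers = {}
            fams = plan.carrier_families[v::plan.n_variants] \
                if plan.n_variants > 1 else plan.carrier_families
            for fam in (fams or plan.carrier_families):
                ped = by_fam[fam]
                if coding is not None:
                    affected = {
                        m.individual_id for m in ped
                        if coding.get((fam, m.individual_id)) == "affected"
                    }
                else:
                    affected = {
                        m.individual_id for m in ped
                        if cohort.trait_doses.get((fam, m.individual_id), 0) > 0
                    }
                carriers.update(_plant_in_family(ped, affected, plan, rng))
            pos = plan.start + int((v + 1) * span / (plan.n_variants + 1))
            variants.append(VariantRecord(
                chrom=plan.chrom, pos=pos, ref="C", alt="T",
                vclass="SNV", consequence="non_synonymous",
                population_maf=plan.population_maf,
                carriers=carriers, gene=plan.symbol,
            ))
    return variants, annotations


def write_vcf(variants, sample_ids, path) -> None:
    """Write a minimal VCF (GT only) for the planted variant set."""
    cols = [f"{fam}_{iid}" for fam, iid in sample_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,'
                 'Description="Assigned gene symbol">\n')
        chroms = sorted({v.chrom for v in variants}, key=str)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cols) + "\n")
        for v in sorted(variants, key=lambda v: (str(v.chrom), v.pos)):
            gts = []
            for fam, iid in sample_ids:
                n = v.carriers.get((fam, iid))
                gts.append("./." if n is None
                           else "1/1" if n >= 2 else "0/1" if n == 1 else "0/0")
            fh.write("\t".join([
                str(v.chrom), str(v.pos), v.variant_id, v.ref, v.alt,
                ".", "PASS", f"GENE={v.gene or '.'}", "GT",
            ] + gts) + "\n")
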
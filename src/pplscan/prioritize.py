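"""Candidate-variant filtration and gene prioritization in linkage regions.

Pipeline: rare-variant MAF filter → critical-region intersection →
variant-class filters (CNV size/probe, SV benign flag) → per-family
co-segregation LOD under a fully penetrant dominant or recessive model →
permutation gene score (segregation + rarity) → brain-expression and
constraint gating → deterministic top-candidate selection → SFARI overlap.

Every filter is monotone (output ⊆ input) and idempotent, and drop counts
partition the input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedio import Pedigree

log = logging.getLogger(__name__)

VARIANT_CLASSES = ("SNV", "indel", "SV", "CNV", "MEI")


@dataclass
class VariantRecord:
    chrom: str
    pos: int                      # 1-based start
    ref: str
    alt: str
    vclass: str                   # SNV | indel | SV | CNV | MEI
    consequence: str = "other"    # non_synonymous | CDS | intronic | other
    population_maf: float | None = None
    carriers: dict = field(default_factory=dict)  # (fam, iid) -> 0/1/2 copies
    end: int | None = None        # half-open end for CNV/SV spans
    gene: str | None = None
    length_bp: int | None = None
    probe_count: int | None = None
    copy_number: int | None = None
    benign_flag: bool = False

    def __post_init__(self):
        if self.vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if self.vclass == "CNV" and (self.length_bp or 0) <= 0:
            raise ValueError("CNV needs positive length_bp")
        if self.population_maf is not None and not 0 <= self.population_maf <= 1:
            raise ValueError("population MAF outside [0,1]")

    @property
    def variant_id(self) -> str:
        if self.vclass in ("SNV", "indel"):
            return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"
        return f"{self.chrom}_{self.pos}_{self.end or self.pos}_{self.alt}"

    @property
    def families(self) -> set:
        return {fam for (fam, _), n in self.carriers.items() if n > 0}


@dataclass
class GeneAnnotation:
    symbol: str
    chrom: str
    start: int                    # half-open [start, end)
    end: int
    tpm_by_db: tuple = (0.0, 0.0, 0.0)   # (GTEx, BrainSpan, HDBR)
    pli: float | None = None
    loeuf: float | None = None
    oe_lof: float | None = None
    missense_z: float | None = None
    ndd_flag: bool = False
    sfari_flag: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.symbol}: malformed interval")
        if any(t < 0 for t in self.tpm_by_db):
            raise ValueError(f"{self.symbol}: negative TPM")


@dataclass
class CandidateGene:
    symbol: str
    variants: list
    family_lods: dict             # (variant_id, family) -> LOD
    unique_family_count: int
    gene_p: float | None = None
    annotation: GeneAnnotation | None = None
    top_flag: bool = False
    rank_notes: str = ""


# ---------------------------------------------------------------------------
# Variant-level filters

def filter_rare(variants, maf_max: float = 0.05):
    """Keep variants with population MAF strictly below ``maf_max``.

    Missing MAF counts as rare (absent from the reference panel) and is
    logged."""
    kept = []
    for v in variants:
        if v.population_maf is None:
            log.warning("variant %s has no population MAF; treated as rare",
                        v.variant_id)
            kept.append(v)
        elif v.population_maf < maf_max:
            kept.append(v)
    return kept


def region_filter(variants, regions):
    """Keep variants intersecting any critical region (half-open bp)."""
    if not regions:
        raise ValueError("no critical regions supplied")
    kept = []
    for v in variants:
        if v.end is not None:
            hit = any(r.overlaps_bp(v.chrom, v.pos, v.end) for r in regions)
        else:
            hit = any(r.contains_bp(v.chrom, v.pos) for r in regions)
        if hit:
            kept.append(v)
    return kept


def cnv_filters(cnvs, min_bp: int = 10_000, max_bp: int = 7_500_000,
                min_probes: int = 5):
    """Drop CNVs that are too small, too large, or thinly supported."""
    return [
        c for c in cnvs
        if min_bp <= (c.length_bp or 0) <= max_bp
        and (c.probe_count or 0) >= min_probes
    ]


def sv_filter(svs):
    """Drop structural variants flagged benign by annotation."""
    return [s for s in svs if not s.benign_flag]


# ---------------------------------------------------------------------------
# Segregation

def select_subpedigree(pedigree: Pedigree, sequenced: set, affected: set,
                       inheritance: str) -> list:
    """Sub-pedigree selection for segregation analysis.

    Dominant: all members descending from one founder couple (with their
    mating partners); recessive: parents and siblings of each affected
    member (nuclear units).  Among candidates, pick the one with the most
    affected members sequenced; ties → most members sequenced.
    """
    candidates = []
    if inheritance == "dominant":
        couples = {(m.father_id, m.mother_id) for m in pedigree.nonfounders}
        for fa, mo in couples:
            if not (pedigree.get(fa).is_founder and pedigree.get(mo).is_founder):
                continue
            ids = {fa, mo}
            frontier = [fa, mo]
            while frontier:
                cur = frontier.pop()
                for child in pedigree.children_of(cur):
                    if child.individual_id not in ids:
                        ids.add(child.individual_id)
                        ids.add(child.father_id)
                        ids.add(child.mother_id)
                        frontier.append(child.individual_id)
            candidates.append(sorted(ids))
    elif inheritance == "recessive":
        for m in pedigree:
            if m.individual_id not in affected or m.is_founder:
                continue
            sibs = [
                s.individual_id for s in pedigree
                if (s.father_id, s.mother_id) == (m.father_id, m.mother_id)
            ]
            candidates.append(sorted({m.father_id, m.mother_id, *sibs}))
    else:
        raise ValueError(f"unknown inheritance {inheritance!r}")
    if not candidates:
        candidates = [sorted(m.individual_id for m in pedigree)]
    return max(
        candidates,
        key=lambda ids: (len(set(ids) & affected & sequenced),
                         len(set(ids) & sequenced)),
    )


def _subpedigree(pedigree: Pedigree, keep_ids) -> Pedigree:
    keep = set(keep_ids)
    members = []
    for m in pedigree:
        if m.individual_id not in keep:
            continue
        if m.father_id in keep and m.mother_id in keep:
            members.append(m)
        else:
            from .pedio import Individual
            members.append(Individual(m.family_id, m.individual_id,
                                      None, None, m.sex))
    return Pedigree(pedigree.family_id, members)


def _coupled_haplotypes(carrier_freq: float) -> np.ndarray:
    """Founder haplotype frequencies with the variant identical to the
    trait allele (complete coupling): carriers carry the risk allele."""
    return np.array([[1.0 - carrier_freq, 0.0], [0.0, carrier_freq]])


def _variant_genotypes(variant: VariantRecord, fam: str, members) -> dict:
    geno = {}
    for m in members:
        n = variant.carriers.get((fam, m.individual_id))
        if n is None:
            geno[m.individual_id] = (0, 0)
        else:
            geno[m.individual_id] = (
                (2, 2) if n >= 2 else (1, 2) if n == 1 else (1, 1)
            )
    return geno


#: softened penetrance vectors for permutation scoring: a small phenocopy
#: rate and incomplete penetrance keep the score finite and graded on
#: labelings the strict model calls impossible
SOFT_PENETRANCE = {
    "dominant": (0.02, 0.95, 0.95),
    "recessive": (0.02, 0.02, 0.95),
}


def segregation_lod(variant: VariantRecord, pedigree: Pedigree,
                    trait_coding: dict, inheritance: str = "dominant",
                    carrier_freq: float = 0.01,
                    penetrances=None) -> float:
    """Per-family LOD that the variant co-segregates with the trait.

    The variant is modeled as the trait allele itself (complete coupling
    of the variant and risk haplotypes), fully penetrant with no
    phenocopies under the declared inheritance (dominant f=(0,1,1);
    recessive f=(0,0,1)); LOD = log10 L(θ=0)/L(θ=0.5).  One fully
    informative non-recombinant meiosis contributes log10 2.
    Uninformative or internally impossible families return 0.
    """
    from . import peeling

    fam = pedigree.family_id
    sequenced = {iid for (f, iid) in variant.carriers if f == fam}
    if len(sequenced) < 2:
        return 0.0
    affected = {
        m.individual_id for m in pedigree
        if trait_coding.get((fam, m.individual_id)) == "affected"
    }
    sub_ids = select_subpedigree(pedigree, sequenced, affected, inheritance)
    sub = _subpedigree(pedigree, sub_ids)
    geno = _variant_genotypes(variant, fam, sub)
    if penetrances is None:
        penetrances = ((0.0, 1.0, 1.0) if inheritance == "dominant"
                       else (0.0, 0.0, 1.0))
    f = np.array(penetrances)
    evidence = {
        m.individual_id: peeling.dichotomous_evidence(
            trait_coding.get((fam, m.individual_id), "unknown"), f)
        for m in sub
    }
    h = _coupled_haplotypes(carrier_freq)
    l0 = float(peeling.family_likelihood(sub, geno, evidence, 0.0,
                                         carrier_freq, carrier_freq,
                                         haplotype_freqs=h))
    l5 = float(peeling.family_likelihood(sub, geno, evidence, 0.5,
                                         carrier_freq, carrier_freq,
                                         haplotype_freqs=h))
    if l5 <= 0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(np.log10(l0 / l5))


def _seg_lod_batch(sub: Pedigree, geno: dict, status_batch: dict,
                   inheritance: str, carrier_freq: float) -> np.ndarray:
    """(B,) segregation LODs for a batch of affection-label vectors.

    ``status_batch`` maps individual_id -> length-B list of affection
    states; the variant genotype and sub-pedigree are shared across the
    batch, so one peeling pass per θ covers every permutation.
    """
    from . import peeling

    f = np.array(SOFT_PENETRANCE[inheritance])
    rows = {
        st: peeling.dichotomous_evidence(st, f)
        for st in ("affected", "unaffected", "unknown")
    }
    evidence = {
        iid: np.stack([rows.get(st, rows["unknown"]) for st in states])
        for iid, states in status_batch.items()
    }
    b = len(next(iter(evidence.values())))
    h = _coupled_haplotypes(carrier_freq)
    l0 = peeling.family_likelihood(sub, geno, evidence, 0.0,
                                   carrier_freq, carrier_freq,
                                   haplotype_freqs=h)
    l5 = peeling.family_likelihood(sub, geno, evidence, 0.5,
                                   carrier_freq, carrier_freq,
                                   haplotype_freqs=h)
    l0, l5 = np.atleast_1d(l0), np.atleast_1d(l5)
    out = np.zeros(b)
    ok = l5 > 0
    with np.errstate(divide="ignore"):
        out[ok] = np.log10(l0[ok] / l5[ok])
    return out


def gene_score_permutation(gene_variants, pedigrees, trait_coding,
                           n_perm: int = 1000, seed: int = 0,
                           inheritance: str = "dominant") -> tuple:
    """Permutation p-value for a gene's segregation + rarity score.

    Observed score = Σ over carrier families of max(0, segregation LOD)
    plus Σ over variants of −log10(population MAF).  The null permutes
    affection labels within each family (preserving the affected count);
    sub-pedigrees are fixed at their observed selection.  All permutations
    run through one batched peeling pass per variant × family.
    p = (1 + #{null ≥ observed}) / (n_perm + 1).  Returns (p, observed).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} too small (need ≥100)")
    rng = np.random.default_rng(seed)
    by_fam = {p.family_id: p for p in pedigrees}

    rarity = 0.0
    for v in gene_variants:
        maf = v.population_maf if v.population_maf else 1e-4
        rarity += -math.log10(max(maf, 1e-6))

    fams = sorted({f for v in gene_variants for f in v.families
                   if f in by_fam})
    members = {f: [m.individual_id for m in by_fam[f]] for f in fams}
    # B = observed + n_perm label vectors per family, shared by the gene's
    # variants within each replicate
    labels = {}
    for f in fams:
        obs = [trait_coding.get((f, i), "unknown") for i in members[f]]
        cols = [obs]
        for _ in range(n_perm):
            sh = list(obs)
            rng.shuffle(sh)
            cols.append(sh)
        labels[f] = {iid: [cols[b][k] for b in range(n_perm + 1)]
                     for k, iid in enumerate(members[f])}

    scores = np.zeros(n_perm + 1)
    for v in gene_variants:
        for fam in sorted(v.families):
            ped = by_fam.get(fam)
            if ped is None:
                continue
            sequenced = {iid for (fm, iid) in v.carriers if fm == fam}
            if len(sequenced) < 2:
                continue
            affected = {
                m.individual_id for m in ped
                if trait_coding.get((fam, m.individual_id)) == "affected"
            }
            sub_ids = select_subpedigree(ped, sequenced, affected, inheritance)
            sub = _subpedigree(ped, sub_ids)
            geno = _variant_genotypes(v, fam, sub)
            status_batch = {iid: labels[fam][iid] for iid in sub_ids}
            lods = _seg_lod_batch(sub, geno, status_batch, inheritance, 0.01)
            scores += np.maximum(0.0, lods)
    observed = scores[0] + rarity
    exceed = int(np.sum(scores[1:] + rarity >= observed))
    return (1 + exceed) / (n_perm + 1), float(observed)


def bonferroni_threshold(alpha: float = 0.05, n_genes: int = 1) -> float:
    """Multiple-comparison p threshold: alpha divided by the region's
    gene count."""
    if n_genes < 1:
        raise ValueError("need at least one gene in the region")
    return alpha / n_genes


# ---------------------------------------------------------------------------
# Gene-level gating and ranking

def expression_gate(genes, tpm_min: float = 5.0, tpm_strict: bool = False):
    """Keep genes whose max TPM reaches ``tpm_min`` in ≥1 of the three
    brain-expression databases (strict > when ``tpm_strict``)."""
    kept = []
    for g in genes:
        best = max(g.tpm_by_db) if g.tpm_by_db else 0.0
        ok = best > tpm_min if tpm_strict else best >= tpm_min
        if ok:
            kept.append(g)
    return kept


def _multi_db_count(ann: GeneAnnotation, tpm_min: float = 5.0) -> int:
    return sum(1 for t in ann.tpm_by_db if t >= tpm_min)


def select_top_candidates(genes: dict, annotations: dict,
                          tpm_min: float = 5.0) -> list:
    """Flag and rank top candidate genes.

    ``genes`` maps symbol -> CandidateGene (with unique_family_count and
    gene_p populated); ``annotations`` maps symbol -> GeneAnnotation.
    top_flag iff variants segregate in ≥2 unique families and the
    brain-expression gate passes.  Ordering is deterministic: NDD flag,
    multi-database TPM count, unique family count, gene p, symbol.
    """
    out = []
    for symbol in sorted(genes):
        g = genes[symbol]
        ann = annotations.get(symbol)
        expr_ok = ann is not None and max(ann.tpm_by_db) >= tpm_min
        g.annotation = ann
        g.top_flag = bool(g.unique_family_count >= 2 and expr_ok)
        notes = []
        if ann is not None and ann.ndd_flag:
            notes.append("known NDD gene")
        if ann is not None:
            notes.append(f"TPM≥{tpm_min:g} in {_multi_db_count(ann, tpm_min)}/3 databases")
        g.rank_notes = "; ".join(notes)
        out.append(g)

    def key(g: CandidateGene):
        ann = g.annotation
        return (
            0 if (ann and ann.ndd_flag) else 1,
            -(_multi_db_count(ann, tpm_min) if ann else 0),
            -g.unique_family_count,
            g.gene_p if g.gene_p is not None else 1.1,
            g.symbol,
        )

    return sorted(out, key=key)


def unique_family_count(variants) -> int:
    """Unique families carrying any of the gene's variants, over all
    variant types."""
    fams = set()
    for v in variants:
        fams |= v.families
    return len(fams)


def sfari_overlap(region_genes: dict, sfari_list) -> pd.DataFrame:
    """Per-region intersection with the SFARI autism gene list.

    ``region_genes`` maps a region label to gene symbols; returns a table
    (region, n_genes, n_overlap, symbols)."""
    sfari = {s.strip() for s in sfari_list if s and s.strip()}
    rows = []
    for region, symbols in region_genes.items():
        hit = sorted(set(symbols) & sfari)
        rows.append({
            "region": region,
            "n_genes": len(set(symbols)),
            "n_overlap": len(hit),
            "symbols": ",".join(hit),
        })
    return pd.DataFrame(rows)


def read_sfari_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_variants_vcf(path, vclass: str = "SNV") -> list:
    """Read SNV/indel records with carrier status from VCF genotypes.

    Sample names are ``<family>_<individual>``; the GENE info key, when
    present, assigns the variant to a gene symbol."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = []
    for s in vcf.samples:
        fam, _, iid = s.partition("_")
        samples.append((fam, iid))
    out = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        cls = vclass
        if len(rec.REF) != len(alt) and vclass == "SNV":
            cls = "indel"
        carriers = {}
        for key, gt in zip(samples, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            if gt == 0:
                carriers[key] = 0
            elif gt == 1:
                carriers[key] = 1
            elif gt == 3:
                carriers[key] = 2
        out.append(VariantRecord(
            chrom=str(rec.CHROM), pos=int(rec.POS), ref=rec.REF, alt=alt,
            vclass=cls, consequence="non_synonymous",
            population_maf=None,
            carriers=carriers,
            gene=rec.INFO.get("GENE"),
        ))
    return out
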
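"""Empirical null calibration of the genome-wide maximum PPL.

Gene dropping simulates marker genotypes down the fixed pedigrees from
founder allele frequencies — without regard to phenotypes — so repeated
scans of dropped genomes give the null distribution of the maximum PPL
over the map and the declared trait set.  Thresholds for a genome-wide
error rate p are order statistics of the replicate maxima.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .linkage import scan
from .pedio import GenotypeMatrix, MarkerMap, kosambi_theta


def _drop_gamete(hap_pat, hap_mat, chrom_slices, thetas, rng):
    """One meiosis: recombine a parent's two haplotypes along the map."""
    n = hap_pat.shape[0]
    gamete = np.empty(n, dtype=np.int8)
    for lo, hi in chrom_slices:
        src = rng.integers(0, 2)
        for j in range(lo, hi):
            if j > lo and rng.random() < thetas[j]:
                src = 1 - src
            gamete[j] = hap_pat[j] if src == 0 else hap_mat[j]
    return gamete


def chromosome_layout(map_table):
    """(chrom slices, inter-locus θ array) from an ordered map table."""
    n = len(map_table)
    chrom_slices = []
    thetas = np.zeros(n)
    pos = 0
    for _, sub in map_table.groupby("chrom", sort=False):
        k = len(sub)
        chrom_slices.append((pos, pos + k))
        cm = sub["cM"].to_numpy(dtype=float)
        for j in range(1, k):
            thetas[pos + j] = kosambi_theta(cm[j] - cm[j - 1])
        pos += k
    return chrom_slices, thetas


def drop_family_haplotypes(pedigree, freqs, chrom_slices, thetas, rng,
                           founder_haps: dict | None = None) -> dict:
    """Mendelian haplotype drop for one family.

    Founders draw each locus independently at ``freqs`` (Hardy–Weinberg);
    ``founder_haps`` can pre-assign particular founder haplotypes.
    Returns individual_id -> (paternal, maternal) 0/1 haplotype arrays.
    """
    n = len(freqs)
    haps = dict(founder_haps or {})
    pending = [m for m in pedigree if m.individual_id not in haps]
    while pending:
        progressed = False
        for m in list(pending):
            if m.is_founder:
                haps[m.individual_id] = (
                    (rng.random(n) < freqs).astype(np.int8),
                    (rng.random(n) < freqs).astype(np.int8),
                )
            elif m.father_id in haps and m.mother_id in haps:
                fa, mo = haps[m.father_id], haps[m.mother_id]
                haps[m.individual_id] = (
                    _drop_gamete(fa[0], fa[1], chrom_slices, thetas, rng),
                    _drop_gamete(mo[0], mo[1], chrom_slices, thetas, rng),
                )
            else:
                continue
            pending.remove(m)
            progressed = True
        if not progressed:  # pragma: no cover - guarded by Pedigree
            raise RuntimeError("unresolvable parentage order")
    return haps


def gene_drop(pedigrees, marker_map: MarkerMap, seed=None,
              rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate genotypes for all families under the null of no linkage.

    Founders draw haplotypes from Hardy–Weinberg at each marker's MAF;
    transmissions are Mendelian with inter-marker recombination fractions
    from the Kosambi map distances.  Phenotypes are untouched.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t = marker_map.table
    mafs = t["maf"].to_numpy(dtype=float)
    chrom_slices, thetas = chromosome_layout(t)

    sample_ids, rows = [], []
    for ped in pedigrees:
        haps = drop_family_haplotypes(ped, mafs, chrom_slices, thetas, rng)
        for m in ped:
            h = haps[m.individual_id]
            sample_ids.append((ped.family_id, m.individual_id))
            rows.append(np.stack([h[0] + 1, h[1] + 1], axis=1))
    alleles = np.stack(rows)  # (n_ind, n_mark, 2); codes 1/2, no missingness
    return GenotypeMatrix(sample_ids, list(t["name"]), alleles)


@dataclass
class NullCalibration:
    """Replicate maxima of the genome-wide max PPL plus derived cutoffs."""

    R: int
    seed: int
    maxima: np.ndarray
    traits: tuple = ()

    def threshold(self, p: float) -> float:
        """PPL cutoff for genome-wide error rate p: the ceil((1−p)·R)-th
        order statistic of the replicate maxima."""
        if not 0.0 < p < 1.0:
            raise ValueError(f"p outside (0,1): {p}")
        k = math.ceil((1.0 - p) * self.R)
        k = min(max(k, 1), self.R)
        return float(np.sort(self.maxima)[k - 1])

    def thresholds(self, levels=(0.001, 0.01, 0.05)) -> dict:
        return {p: self.threshold(p) for p in levels}

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "R": self.R,
                "seed": self.seed,
                "traits": list(self.traits),
                "thresholds": {str(p): v
                               for p, v in self.thresholds().items()},
                "maxima": [float(x) for x in self.maxima],
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def calibrate(pedigrees, marker_map: MarkerMap, trait_codings: dict,
              grids: dict, R: int, seed: int,
              strata: dict | None = None,
              mode: str = "sequential",
              joint_over_traits: bool = True) -> NullCalibration:
    """Empirical null of the genome-wide maximum PPL.

    ``trait_codings`` maps trait name -> coding dict; ``grids`` maps trait
    name -> TraitModelGrid.  Each replicate gene-drops a fresh genome,
    scans it for every trait, and records the maximum PPL over all map
    positions and (by default) over the whole trait set jointly.
    Per-replicate seeds derive from ``seed`` via a counter.  With
    ``joint_over_traits`` (the default) the maximum is taken over the whole
    trait set and one NullCalibration is returned; otherwise a dict of
    per-trait calibrations.
    """
    if R < 20:
        raise ValueError(f"R={R}: too few replicates for quantiles (need ≥20)")
    names = list(trait_codings)
    maxima = np.empty((R, len(names)))
    for r in range(R):
        rng = np.random.default_rng((int(seed), r))
        geno = gene_drop(pedigrees, marker_map, rng=rng)
        for j, trait in enumerate(names):
            df = scan(pedigrees, geno, marker_map, trait_codings[trait],
                      grids[trait], mode=mode, strata=strata)
            maxima[r, j] = float(df["PPL"].max())
    if joint_over_traits:
        return NullCalibration(R=R, seed=int(seed),
                               maxima=maxima.max(axis=1),
                               traits=tuple(names))
    return {
        trait: NullCalibration(R=R, seed=int(seed), maxima=maxima[:, j],
                               traits=(trait,))
        for j, trait in enumerate(names)
    }


def empirical_p(observed_ppl: float, calibration: NullCalibration) -> float:
    """Add-one permutation-style p estimate for an observed PPL."""
    exceed = int(np.sum(calibration.maxima >= observed_ppl))
    return (1 + exceed) / (calibration.R + 1)
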
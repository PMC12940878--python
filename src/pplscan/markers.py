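"""Linkage panel construction and tabular SNP QC.

The linkage panel keeps markers shared across the declared array types
with minor allele frequency above 30%, greedily pruned for pairwise LD;
array-specific markers can be appended afterwards (``augment``) provided
no family mixes arrays.  Post-imputation SNP tables are filtered on MAF,
imputation quality and Hardy–Weinberg equilibrium with drop counts
attributed to the first failing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SnpQcRule:
    maf_min: float = 0.05
    imputation_quality_min: float = 0.4
    hwe_p_min: float = 1e-5

    def __post_init__(self):
        for v in (self.maf_min, self.imputation_quality_min, self.hwe_p_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold outside [0,1]: {v}")


@dataclass
class MarkerPanel:
    """Selected markers with their provenance (shared vs augment)."""

    table: pd.DataFrame  # columns: name, chrom, cM, bp?, maf, source
    arrays: tuple = ()

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def counts_by_source(self) -> dict:
        return self.table["source"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.table)


def composite_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD estimate from unphased dosages: squared Pearson
    correlation of 0/1/2 allele counts (Rogers & Huff style)."""
    ok = ~(np.isnan(dosage_a) | np.isnan(dosage_b))
    a, b = dosage_a[ok], dosage_b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _ld_prune(table: pd.DataFrame, dosages: np.ndarray | None,
              ld_r2_max: float, window_cM: float) -> pd.DataFrame:
    """Greedy pruning in map order: drop the later marker of any pair with
    r² > ld_r2_max within the cM window; at equal position keep higher MAF.

    ``dosages`` is (n_founders, n_markers) aligned with ``table`` rows;
    None skips pruning (no genotype evidence of LD).
    """
    if dosages is None:
        return table
    order = table.sort_values(
        ["chrom", "cM", "maf"], ascending=[True, True, False]
    ).index
    kept: list[int] = []
    pos = {i: (table.loc[i, "chrom"], float(table.loc[i, "cM"]))
           for i in table.index}
    col = {idx: j for j, idx in enumerate(table.index)}
    for i in order:
        drop = False
        for k in kept:
            if pos[k][0] != pos[i][0]:
                continue
            if abs(pos[i][1] - pos[k][1]) > window_cM:
                continue
            if composite_r2(dosages[:, col[k]], dosages[:, col[i]]) > ld_r2_max:
                drop = True
                break
        if not drop:
            kept.append(i)
    return table.loc[sorted(kept, key=lambda i: list(table.index).index(i))]


def validate_single_array_per_family(panel_table: pd.DataFrame,
                                     family_arrays: dict,
                                     array_membership: dict) -> None:
    """Each family is genotyped on one array; every panel marker must be
    present on that array or it induces within-family missingness."""
    for fam, arr in family_arrays.items():
        for name in panel_table["name"]:
            if arr not in array_membership.get(name, ()):  # pragma: no branch
                raise ValueError(
                    f"family {fam} (array {arr}): marker {name} missing from "
                    "its array — within-family missing-data pattern"
                )


def build_linkage_panel(markers: pd.DataFrame, array_membership: dict,
                        maf_min: float = 0.30, ld_r2_max: float = 0.10,
                        window_cM: float = 5.0,
                        founder_dosages: np.ndarray | None = None,
                        arrays: tuple | None = None) -> MarkerPanel:
    """Markers shared by all arrays, MAF > maf_min, LD-pruned, order kept.

    ``markers`` needs columns name/chrom/cM/maf; ``array_membership`` maps
    marker name -> set of array labels; ``founder_dosages`` aligns with the
    rows of ``markers`` for the composite-r² pruning.
    """
    if len(markers) == 0:
        raise ValueError("empty marker table")
    if arrays is None:
        arrays = tuple(sorted({a for s in array_membership.values() for a in s}))
    shared_mask = markers["name"].map(
        lambda n: set(arrays) <= set(array_membership.get(n, ()))
    )
    shared = markers[shared_mask]
    if len(arrays) > 1 and shared.empty:
        raise ValueError(
            "no markers shared across all declared arrays; "
            "consider augment mode for array-specific markers"
        )
    sel = shared[shared["maf"] > maf_min]
    dos = None
    if founder_dosages is not None:
        cols = [markers.index.get_loc(i) for i in sel.index]
        dos = founder_dosages[:, cols]
        sel = sel.reset_index(drop=True)
    sel = _ld_prune(sel.reset_index(drop=True), dos, ld_r2_max, window_cM)
    out = sel.copy()
    out["source"] = "shared"
    return MarkerPanel(table=out.reset_index(drop=True), arrays=arrays)


def augment_panel(panel: MarkerPanel, extra_markers: pd.DataFrame,
                  array_membership: dict,
                  family_arrays: dict | None = None) -> MarkerPanel:
    """Append array-specific markers (source="augment").

    When ``family_arrays`` (family -> array label) is given, re-validate
    that no family would see missing data at an augment marker absent from
    its own array.
    """
    extra = extra_markers.copy()
    untyped = [n for n in extra["name"]
               if not array_membership.get(n)]
    if untyped:
        raise ValueError(f"augment markers typed on no declared array: {untyped}")
    if family_arrays is not None:
        for fam, arr in family_arrays.items():
            bad = [n for n in extra["name"]
                   if arr not in array_membership[n]]
            if bad:
                raise ValueError(
                    f"family {fam} (array {arr}): augment markers {bad} "
                    "would induce within-family missing data"
                )
    extra["source"] = "augment"
    table = pd.concat([panel.table, extra], ignore_index=True)
    return MarkerPanel(table=table, arrays=panel.arrays)


QC_RULE_ORDER = ("maf", "quality", "hwe")


def apply_snp_qc(variant_table: pd.DataFrame, rule: SnpQcRule):
    """Filter a post-imputation SNP table on MAF, quality and HWE.

    Retains rows with maf > maf_min, quality > imputation_quality_min and
    hwe_p > hwe_p_min (all strict).  Returns (filtered table, drop counts
    attributed to the first failing rule in fixed order maf → quality →
    hwe).
    """
    for col in ("maf", "quality", "hwe_p"):
        if col not in variant_table.columns:
            raise KeyError(f"SNP QC table missing column {col!r}")
    fails = {
        "maf": ~(variant_table["maf"] > rule.maf_min),
        "quality": ~(variant_table["quality"] > rule.imputation_quality_min),
        "hwe": ~(variant_table["hwe_p"] > rule.hwe_p_min),
    }
    attributed = pd.Series("pass", index=variant_table.index, dtype=object)
    for name in QC_RULE_ORDER:
        attributed[(attributed == "pass") & fails[name]] = name
    kept = variant_table[attributed == "pass"]
    drops = {name: int((attributed == name).sum()) for name in QC_RULE_ORDER}
    return kept, drops
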
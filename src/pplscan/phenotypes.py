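"""Trait derivation and cohort stratification.

Five analysis traits are derived from the raw phenotype table:

* ``LI_star``  — language impairment and/or ASD (etiological equivalence)
* ``RI_star``  — reading impairment and/or ASD
* ``SRS_TS``   — Social Responsiveness Scale total T-score (quantitative)
* ``SRS_TS_DT``— SRS total dichotomized at a mild-range T cutoff
* ``SRS_RIRB`` — SRS Restricted Interests / Repetitive Behaviors subscale

Missing raw data always degrade a coding to "unknown", never to an error.
Families carry (wave, tier) labels; analyses stratify on their cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import math

import numpy as np
import pandas as pd

YES, NO, UNKNOWN = "yes", "no", "unknown"
AFFECTED, UNAFFECTED = "affected", "unaffected"

CATEGORICAL_TRAITS = ("LI_star", "RI_star", "SRS_TS_DT")
QUANTITATIVE_TRAITS = ("SRS_TS", "SRS_RIRB")
TRAITS = CATEGORICAL_TRAITS + QUANTITATIVE_TRAITS

#: fraction of subtests that must fall ≥1 SD below the mean
SUBTEST_FRACTION = Fraction(3, 5)

#: default mild-range SRS T-score cutoff for dichotomous affection
SRS_CUTOFF_T = 60.0


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


def _frac_low(zscores) -> Fraction:
    """Exact fraction of z-scores at or below −1 (no float rounding)."""
    n_low = sum(1 for z in zscores if z <= -1.0)
    return Fraction(n_low, len(zscores))


def code_LI(row, wave: int) -> str:
    """Language-impairment coding.

    Affected iff CELF core standard score ≤ 85, or ≥60% of administered oral
    language subtests fall ≥1 SD below peers together with a documented
    history of language intervention.  Wave-1 families additionally require
    performance IQ ≥ 80 (PIQ missing leaves the coding unknown); wave 2
    drops the PIQ requirement.
    """
    celf = row.get("celf_core")
    oral = row.get("oral_subtest_z")
    has_celf = not _is_missing(celf)
    has_oral = not (oral is None or (isinstance(oral, float) and math.isnan(oral))
                    or len(oral) == 0)
    if not has_celf and not has_oral:
        return UNKNOWN

    meets = False
    if has_celf and celf <= 85:
        meets = True
    if not meets and has_oral:
        # intervention history must be explicitly true for this branch
        if row.get("intervention_history") is True and \
                _frac_low(oral) >= SUBTEST_FRACTION:
            meets = True

    if not meets:
        return NO
    if int(wave) == 1:
        piq = row.get("piq")
        if _is_missing(piq):
            return UNKNOWN
        if piq < 80:
            return NO
    return YES


def code_RI(row) -> str:
    """Reading impairment: ≥60% of reading tests/subtests ≥1 SD below mean."""
    z = row.get("reading_subtest_z")
    if z is None or (isinstance(z, float) and math.isnan(z)) or len(z) == 0:
        return UNKNOWN
    return YES if _frac_low(z) >= SUBTEST_FRACTION else NO


def code_star_trait(base: str, row) -> str:
    """Etiological-equivalence coding: ASD and/or the base impairment.

    ``base`` is "LI" or "RI"; the row must carry ``asd`` plus the base
    coding under the lower-cased key ("li"/"ri").
    """
    if base not in ("LI", "RI"):
        raise ValueError(f"unknown base trait {base!r}")
    asd = row.get("asd")
    base_val = row.get(base.lower())
    asd = UNKNOWN if _is_missing(asd) else asd
    base_val = UNKNOWN if _is_missing(base_val) else base_val
    if asd == YES or base_val == YES:
        return AFFECTED
    if asd == NO and base_val == NO:
        return UNAFFECTED
    return UNKNOWN


def code_srs_dichotomous(srs_t, cutoff_t: float = SRS_CUTOFF_T) -> str:
    """Dichotomize an SRS T-score at the mild-range boundary (default 60)."""
    if _is_missing(srs_t):
        return UNKNOWN
    return AFFECTED if srs_t >= cutoff_t else UNAFFECTED


def derive_traits(pheno: pd.DataFrame, srs_cutoff_t: float = SRS_CUTOFF_T,
                  standardize_srs: bool = True) -> pd.DataFrame:
    """Derive all analysis traits for a cohort phenotype table.

    Returns a long table (family_id, individual_id, trait, value):
    categorical traits get affected/unaffected/unknown, quantitative traits
    a z-score (SRS T standardized against the unaffected-founder mean/SD of
    the cohort when ``standardize_srs``; NaN when missing).
    """
    recs = []
    df = pheno.copy()
    li = []
    ri = []
    for _, row in df.iterrows():
        r = row.to_dict()
        li.append(code_LI(r, int(r.get("wave") or 1)))
        ri.append(code_RI(r))
    # raw li/ri columns, when supplied, take precedence over derivation
    df["li"] = [o if isinstance(o, str) and o in (YES, NO) else v
                for v, o in zip(li, pheno.get("li", [None] * len(df)))]
    df["ri"] = [o if isinstance(o, str) and o in (YES, NO) else v
                for v, o in zip(ri, pheno.get("ri", [None] * len(df)))]

    for quant in ("srs_t", "srs_rirb_t"):
        if quant in df:
            df[quant] = pd.to_numeric(df[quant], errors="coerce")
        else:
            df[quant] = pd.Series(np.nan, index=df.index)

    # z-standardization anchor: unaffected (non-ASD) founders if available
    def _standardize(col: pd.Series) -> pd.Series:
        if not standardize_srs:
            return col
        mask = (df.get("asd") == NO) & col.notna()
        anchor = col[mask]
        if len(anchor) >= 2 and anchor.std(ddof=1) > 0:
            return (col - anchor.mean()) / anchor.std(ddof=1)
        return (col - 50.0) / 10.0  # T-score scale fallback

    srs_z = _standardize(df["srs_t"])
    rirb_z = _standardize(df["srs_rirb_t"])

    for i, (_, row) in enumerate(df.iterrows()):
        r = row.to_dict()
        key = (r["family_id"], r["individual_id"])
        recs.append((*key, "LI_star", code_star_trait("LI", r)))
        recs.append((*key, "RI_star", code_star_trait("RI", r)))
        recs.append((*key, "SRS_TS_DT",
                     code_srs_dichotomous(r.get("srs_t"), srs_cutoff_t)))
        recs.append((*key, "SRS_TS",
                     float(srs_z.iloc[i]) if not _is_missing(srs_z.iloc[i]) else np.nan))
        recs.append((*key, "SRS_RIRB",
                     float(rirb_z.iloc[i]) if not _is_missing(rirb_z.iloc[i]) else np.nan))
    return pd.DataFrame(
        recs, columns=["family_id", "individual_id", "trait", "value"]
    )


@dataclass
class Stratification:
    """Partition of the family set over the (wave, tier) cross."""

    strata: dict  # (wave, tier) -> list of family_id
    empty: list   # labels of declared-but-empty strata

    def __len__(self) -> int:
        return len(self.strata)

    def roster(self, label) -> list:
        return self.strata[label]

    @property
    def families(self) -> list:
        return [f for fams in self.strata.values() for f in fams]


def stratify(pheno: pd.DataFrame, waves=(1, 2), tiers=(1, 2)) -> Stratification:
    """Partition families into the wave × tier cross.

    Wave/tier must be constant within a family; unlabeled families raise.
    Empty strata are retained and flagged.
    """
    fam_labels = {}
    for fam, sub in pheno.groupby("family_id", sort=False):
        w = set(pd.to_numeric(sub["wave"], errors="coerce").dropna().astype(int))
        t = set(pd.to_numeric(sub["tier"], errors="coerce").dropna().astype(int))
        if len(w) != 1 or len(t) != 1:
            raise ValueError(
                f"family {fam}: wave/tier missing or not constant "
                f"(waves={sorted(w)}, tiers={sorted(t)})"
            )
        fam_labels[fam] = (w.pop(), t.pop())
    strata = {(w, t): [] for w in waves for t in tiers}
    for fam, label in fam_labels.items():
        if label not in strata:
            raise ValueError(f"family {fam}: label {label} outside declared "
                             f"waves {waves} × tiers {tiers}")
        strata[label].append(fam)
    empty = [label for label, fams in strata.items() if not fams]
    return Stratification(strata=strata, empty=empty)


def trait_coding_map(trait_table: pd.DataFrame, trait: str) -> dict:
    """(family_id, individual_id) -> coded value for one trait."""
    sub = trait_table[trait_table["trait"] == trait]
    return {
        (r.family_id, r.individual_id): r.value
        for r in sub.itertuples()
    }
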
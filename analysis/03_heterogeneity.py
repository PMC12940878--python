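#!/usr/bin/env python
"""Heterogeneity analysis: sequential versus pooled updating.

Generates the two-stratum scenario (30 linked families, 15 unlinked),
computes the sequentially updated PPL, the pooled PPL, and the
per-stratum PPLs at the planted locus, flags each stratum against the 2%
prior, and writes a breakdown table under results/.
"""

from pathlib import Path

import pandas as pd

from pplscan.cli import evidence_flag
from pplscan.grids import power_grid
from pplscan.linkage import (bayes_ratio_curve, family_lr_matrix,
                             ppl_from_br, sequential_update,
                             _marker_geno_dict)
from pplscan.phenotypes import derive_traits, trait_coding_map
from pplscan.synthcohort import generate_cohort, heterogeneity_scenario_config

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    grid = power_grid()
    rows = []
    for seed in range(10):
        cohort = generate_cohort(heterogeneity_scenario_config(seed))
        coding = trait_coding_map(derive_traits(cohort.phenotypes),
                                  "LI_star")
        maf = float(cohort.marker_map.table.loc[0, "maf"])
        lr = {p.family_id: family_lr_matrix(
            p, _marker_geno_dict(p, cohort.genotypes, "M1"), coding, grid,
            maf) for p in cohort.pedigrees}
        curves, ppls = [], {}
        for (w, t), fams in cohort.strata.items():
            curve, br = bayes_ratio_curve([lr[f] for f in fams], grid)
            curves.append(curve)
            ppls[f"w{w}t{t}"] = ppl_from_br(br)
        _, seq_ppl = sequential_update(curves, grid)
        _, pooled_br = bayes_ratio_curve(list(lr.values()), grid)
        row = {"seed": seed, "PPL_sequential": seq_ppl,
               "PPL_pooled": ppl_from_br(pooled_br)}
        for label, v in ppls.items():
            row[f"PPL_{label}"] = v
            row[f"flag_{label}"] = evidence_flag(v)
        rows.append(row)
    df = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    df.to_csv(ROOT / "heterogeneity_breakdown.tsv", sep="\t", index=False)
    n_sig = (df["PPL_sequential"] > df["PPL_pooled"]).sum()
    n_null = (df["PPL_w2t1"] <= 0.02).sum()
    print(df.round(4).to_string(index=False))
    print(f"\nsequential > pooled at the planted locus in {n_sig}/10 seeds; "
          f"unlinked stratum at or below the 2% prior in {n_null}/10")


if __name__ == "__main__":
    main()
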
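#!/usr/bin/env python
"""Generate the study-sized synthetic cohort.

Two recruitment waves (79 and 36 families, each split into two tiers),
multiplex ascertainment, a planted dominant language-impairment locus
(f = (0, 0.7, 0.9), gene frequency 0.001, 90% of families linked), and a
high-MAF SNP panel.  Writes PED/MAP/phenotype files plus a manifest under
results/data/.
"""

import json
from pathlib import Path

from pplscan.grids import TraitModel
from pplscan.pedio import write_ped_map
from pplscan.synthcohort import (StratumPlan, SyntheticCohortConfig,
                                 generate_cohort)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260919


def main():
    cfg = SyntheticCohortConfig(
        seed=SEED,
        strata=(
            StratumPlan(1, 1, 40, "wave1"),
            StratumPlan(1, 2, 39, "wave1"),
            StratumPlan(2, 1, 18, "wave2"),
            StratumPlan(2, 2, 18, "wave2"),
        ),
        trait_model=TraitModel("dichotomous", 0.001, (0.0, 0.7, 0.9),
                               alpha=0.9),
        n_markers=10, n_chromosomes=2, trait_locus_marker=2,
    )
    cohort = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_ped_map(cohort.pedigrees, cohort.genotypes, cohort.marker_map,
                  cohort.phenotypes, str(OUT / "cohort"))
    manifest = {
        "seed": SEED,
        "n_families": len(cohort.pedigrees),
        "n_individuals": cohort.n_individuals(),
        "strata": {f"w{w}t{t}": len(v)
                   for (w, t), v in cohort.strata.items()},
        "n_linked_families": len(cohort.linked_families),
        "trait_locus_marker": cohort.marker_map.names[
            cfg.trait_locus_marker],
    }
    with open(OUT / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    print(f"cohort: {manifest['n_families']} families, "
          f"{manifest['n_individuals']} individuals "
          f"({manifest['n_linked_families']} linked); "
          f"trait locus at {manifest['trait_locus_marker']}")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
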
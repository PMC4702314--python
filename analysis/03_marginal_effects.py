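"""Marginal design-factor effects for the Landrace approach.

Runs a reduced factorial over heritability, genotyping platform, and the
number of phenotyped synthetic seeds - the three factors with lasting effects
on final merit - at the desk-scale conditions with high founder diversity and
diverse accessions (F = 0.3), then reports level means with 95% quantile
ranges and significance letters for merit at the end of discovery (S) and of
improvement (C4). Writes results/landrace_subset_records.csv and
results/marginal_effects.csv.
"""

from __future__ import annotations

import sys
from pathlib import Path

from prebreedsim.config import write_records
from prebreedsim.decision import marginal_effects
from prebreedsim.desk import DESK_NE_HIGH, DESK_SETTINGS
from prebreedsim.program import Scenario, run_grid

OUT = Path(__file__).resolve().parents[1] / "results"

FACTORS = ["h2", "platform", "n_synthetic_phenotypes"]


def landrace_subset() -> list[Scenario]:
    return [
        Scenario(
            approach="Landrace",
            Ne=DESK_NE_HIGH,
            F=0.3,
            h2=h2,
            platform=platform,
            seeds_per_landrace=1,
            n_selected_landraces=40,
            tested_seeds_per_landrace=10,
            n_synthetic_phenotypes=n_syn,
        )
        for h2 in (0.25, 0.50)
        for platform in ("GBS10x@10K", "GBS1x@100K")
        for n_syn in (0, 60)
    ]


def main(seed: int = 1, replicates: int = 5) -> None:
    OUT.mkdir(exist_ok=True)
    records = run_grid(landrace_subset(), replicates, seed, DESK_SETTINGS, progress=True)
    write_records(records, OUT / "landrace_subset_records.csv", master_seed=seed)
    tables = []
    for stage in ("S", "C4"):
        sub = records[records.stage == stage].reset_index(drop=True)
        factors = [f for f in FACTORS if stage == "C4" or f != "n_synthetic_phenotypes"]
        tab = marginal_effects(sub, "merit", factors, alpha=0.01)
        tab.insert(0, "stage", stage)
        tables.append(tab)
        print(f"\n=== merit at stage {stage} ===")
        print(tab.to_string(index=False))
    import pandas as pd

    pd.concat(tables).to_csv(OUT / "marginal_effects.csv", index=False)
    print(f"\nwrote {OUT/'marginal_effects.csv'}")


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    reps = int(sys.argv[2]) if len(sys.argv) > 2 else 5
    main(seed, reps)
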
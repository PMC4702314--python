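"""Decision trees for merit at the end of discovery and of improvement.

Recursive partitioning with a permutation F-test gate (alpha = 0.01,
Bonferroni over factors per node) over the Landrace-approach subset produced by
03_marginal_effects.py. Writes results/tree_discovery.{txt,json} and
results/tree_improvement.{txt,json}.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

from prebreedsim.decision import build_tree, render_tree

OUT = Path(__file__).resolve().parents[1] / "results"

FACTORS = ["h2", "platform", "n_synthetic_phenotypes"]


def main(seed: int = 1) -> None:
    records_path = OUT / "landrace_subset_records.csv"
    if not records_path.exists():
        sys.exit("run analysis/03_marginal_effects.py first (records not found)")
    records = pd.read_csv(records_path)
    for stage, name in (("S", "discovery"), ("C4", "improvement")):
        sub = records[records.stage == stage].reset_index(drop=True)
        factors = [f for f in FACTORS if sub[f].nunique() > 1]
        tree = build_tree(
            sub, "merit", factors, alpha=0.01, min_leaf=10, seed=seed
        )
        text, payload = render_tree(tree)
        (OUT / f"tree_{name}.txt").write_text(text + "\n")
        (OUT / f"tree_{name}.json").write_text(payload)
        print(f"=== merit at end of {name} (stage {stage}) ===")
        print(text, "\n")
    print(f"wrote trees under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
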
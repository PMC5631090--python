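"""Idealized scenario: OTUs assigned to the error-free known tags.

Reproduces the shape of the known-tag experiment: closed-reference richness
for the tags alone should sit near the strain count (less lumping, plus
splitting), while adding every single-substitution variant — a model of a
0.2-0.4% base-call error rate — inflates closed-reference richness because
variants scatter across near-neighbor reference entries.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from otubench.pipeline import BenchmarkConfig, run_known_tags_experiment


def main(seed: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = {}
    for region in ("V35", "V4"):
        config = BenchmarkConfig(seed=seed, tag_region=region)
        report = run_known_tags_experiment(config)
        rows[region] = {
            "true_groups": report["true_group_count"],
            "tags_closed": report["tags"]["closed_richness"],
            "tags_open_extra": report["tags"]["open_extra"],
            "tags_1sub_closed": report["tags+1sub"]["closed_richness"],
            "tags_1sub_open_extra": report["tags+1sub"]["open_extra"],
            "n_split_strains": len(report["split_strains"]),
            "n_failed_strains": len(report["failed_strains"]),
            "n_lumped_otus": len(report["lumped_groups"]),
        }
        with open(outdir / f"known_tags_{region}.json", "w") as fh:
            json.dump(report, fh, indent=2)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.to_csv(outdir / "known_tags_richness.tsv", sep="\t")
    print(table)
    print("\nIdealized input, yet closed-reference richness moves away from")
    print("the true group count once 1-sub variants (a 0.2-0.4% error model)")
    print("are included — the error-free case is the only clean one.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/known_tags"))
    args = ap.parse_args()
    main(args.seed, args.out)
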
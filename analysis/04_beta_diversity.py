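"""Beta diversity contrast: weighted Jaccard vs weighted UniFrac.

Compares replicate samples of one community under two regimes: error-free
reads (correct OTUs; distances reflect subsampling noise only) and a noisy
run whose reads scatter across near-neighbor reference entries (induced OTU
splitting).  Jaccard inflates sharply under splitting while the tree-aware
UniFrac stays small, because the spurious OTUs sit next to the correct OTU
in the tree — the central tolerance/sensitivity trade-off between the two
metrics.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from otubench import clustering, metrics, simulate
from otubench.clustering import OTU, OTUSet
from otubench.pipeline import build_reference
from otubench.simulate import ErrorModel

DEPTH = 5000


def _closed_set(queries, ref97):
    res = clustering.closed_reference_assign(queries, ref97)
    hit = {a.otu_id for a in res if a.otu_id}
    return OTUSet(otus=[OTU(e.ref_id, e.sequence, "reference")
                        for e in ref97.entries if e.ref_id in hit],
                  assignments=res,
                  query_abundance={q: ab for q, _s, ab in queries})


def main(seed: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pair = simulate.default_primer_pairs()[1]
    j_clean, u_clean, j_split, u_split = [], [], [], []
    for rep in range(4):
        s = seed + rep
        com = simulate.make_mock_community(n_strains=6,
                                           paralogs_per_strain=(1, 2),
                                           seed=s, profile_kinds=("even",))
        tg = simulate.community_tags(com, [pair])
        _f, _c, ref97 = build_reference(com, pair, seed=s + 100,
                                        neighbors_per_otu=6)
        samples = [
            simulate.simulate_reads(com, tg, "clean1", 5500, ErrorModel(0.0),
                                    seed=s * 10 + 1, profile="even"),
            simulate.simulate_reads(com, tg, "clean2", 5500, ErrorModel(0.0),
                                    seed=s * 10 + 2, profile="even"),
            simulate.simulate_reads(com, tg, "noisy", 7000, ErrorModel(0.02),
                                    seed=s * 10 + 3, profile="even"),
        ]
        sets = {}
        for sample in samples:
            queries, _ = clustering.dereplicate_reads(sample)
            sets[sample.sample_id] = _closed_set(queries, ref97)
        table = metrics.build_otu_table(sets)
        freqs = {}
        for i, sid in enumerate(table.sample_ids):
            sub = metrics.subsample_counts(table.sample_counts(sid), DEPTH,
                                           seed=s * 7 + i)
            freqs[sid] = sub / sub.sum()
        tree = metrics.upgma_tree_from_sequences(
            [(e.ref_id, e.sequence) for e in ref97.entries])
        j_clean.append(metrics.weighted_jaccard(freqs["clean1"], freqs["clean2"]))
        u_clean.append(metrics.weighted_unifrac(freqs["clean1"],
                                                freqs["clean2"], tree))
        j_split.append(metrics.weighted_jaccard(freqs["clean1"], freqs["noisy"]))
        u_split.append(metrics.weighted_unifrac(freqs["clean1"],
                                                freqs["noisy"], tree))

    out = {
        "subsample_depth": DEPTH,
        "jaccard_clean_mean": float(np.mean(j_clean)),
        "unifrac_clean_mean": float(np.mean(u_clean)),
        "jaccard_split_mean": float(np.mean(j_split)),
        "unifrac_split_mean": float(np.mean(u_split)),
        "jaccard_histogram_split": metrics.distance_histogram(j_split).to_dict(),
        "unifrac_histogram_split": metrics.distance_histogram(u_split).to_dict(),
    }
    with open(outdir / "beta_contrast.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"replicates, correct OTUs : Jaccard {out['jaccard_clean_mean']:.3f}"
          f"  UniFrac {out['unifrac_clean_mean']:.3f}")
    print(f"replicates, split OTUs   : Jaccard {out['jaccard_split_mean']:.3f}"
          f"  UniFrac {out['unifrac_split_mean']:.3f}")
    print("\nJaccard inflates under splitting; UniFrac barely moves because")
    print("the spurious OTUs are adjacent to the correct OTU in the tree.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/beta_diversity"))
    args = ap.parse_args()
    main(args.seed, args.out)
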
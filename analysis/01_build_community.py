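"""Build the default mock community and its reference database.

Writes the ground-truth artifacts every later step consumes: the community
manifest, known-tag FASTA (two copies per sequence, the convention that
protects correct sequences from singleton discarding), the tag-level
reference database with its taxonomy, and the full-span reference id list.
"""

import argparse
import json
from pathlib import Path

from otubench import simulate, tags
from otubench.pipeline import BenchmarkConfig, build_reference


def main(seed: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config = BenchmarkConfig(seed=seed)
    pairs = simulate.default_primer_pairs()
    pair = next(p for p in pairs if p.tag_name == config.tag_region)

    community = simulate.make_mock_community(
        n_strains=config.n_strains,
        paralogs_per_strain=config.paralogs_per_strain,
        paralog_divergence=config.paralog_divergence,
        profile_kinds=config.profile_kinds,
        seed=seed, core_length=config.core_length)

    known = tags.build_known_tags(
        {s.strain_id: [g for _p, g, _c in s.paralogs] for s in community.strains},
        pairs)
    tags.write_known_tags_fasta(outdir / "known_tags.fasta", known)

    full_refs, ref97_clean, ref97 = build_reference(
        community, pair, seed=seed + 1,
        neighbors_per_otu=config.db_neighbors_per_otu,
        neighbor_divergence=config.db_neighbor_divergence)
    tags.write_fasta(outdir / "ref97.fasta",
                     [(e.ref_id, e.sequence) for e in ref97.entries])
    with open(outdir / "ref97_taxonomy.tsv", "w") as fh:
        for e in ref97.entries:
            fh.write(f"{e.ref_id}\t{e.lineage}\n")

    full_span = tags.filter_full_span(
        [(f"{s.strain_id}|{pid}", gene)
         for s in community.strains for pid, gene, _c in s.paralogs], pairs)

    community.to_yaml(outdir / "community.yaml")
    summary = {
        "n_strains": len(community.strains),
        "n_genera": len({s.genus for s in community.strains}),
        "n_paralogs": sum(len(s.paralogs) for s in community.strains),
        "n_known_tags": len(known),
        "n_ref97_centroids": len(ref97_clean),
        "n_ref97_entries_with_neighbors": len(ref97),
        "n_full_span_sources": len(full_span),
        "profiles": {k: {s: round(a, 6) for s, a in v.items()}
                     for k, v in community.profiles.items()},
    }
    with open(outdir / "community_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"community: {summary['n_strains']} strains, "
          f"{summary['n_genera']} genera, {summary['n_paralogs']} paralogs")
    print(f"known tags: {summary['n_known_tags']} "
          f"(regions {[p.tag_name for p in pairs]})")
    print(f"reference: {summary['n_ref97_centroids']} centroids, "
          f"{summary['n_ref97_entries_with_neighbors']} entries including "
          f"near-neighbors; {summary['n_full_span_sources']} full-span sources")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/community"))
    args = ap.parse_args()
    main(args.seed, args.out)
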
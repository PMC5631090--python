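"""OTU tables and alpha/beta diversity computations.

Frequencies are x_i = n_i / N, the fraction of a sample's reads assigned to
OTU i.  The weighted Jaccard distance between samples X and Y is
J = 1 - sum_i min(x_i, y_i) / sum_i max(x_i, y_i): zero for identical
frequency vectors, one when no OTU is shared.  Weighted UniFrac weights each
branch of a rooted tree by the absolute difference between the fractions of
each sample descending through it; the normalized variant divides by the
abundance-weighted total branch length and lies in [0, 1].  Samples are
subsampled to a fixed read depth before distances are computed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from otubench.clustering import AssignmentResult, OTUSet

__all__ = [
    "OTUTable",
    "SplitReport",
    "build_otu_table",
    "richness",
    "subsample_counts",
    "weighted_jaccard",
    "weighted_unifrac",
    "distance_histogram",
    "rarefaction_curve",
    "splitting_report",
    "coassignment_matrix",
    "tree_from_newick",
    "upgma_tree_from_sequences",
]


class OTUTable:
    """Samples x OTUs integer count matrix (thin wrapper over a DataFrame)."""

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def total(self, sample: str) -> int:
        return int(self.counts.loc[sample].sum())

    def sample_counts(self, sample: str) -> pd.Series:
        if sample not in self.counts.index:
            raise KeyError(f"unknown sample {sample!r}")
        return self.counts.loc[sample]

    def frequencies(self, sample: str) -> pd.Series:
        counts = self.sample_counts(sample)
        n = counts.sum()
        if n == 0:
            raise ValueError(f"sample {sample!r} has no reads")
        return counts / n

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OTUTable":
        counts = pd.read_csv(path, sep="\t", index_col="sample_id")
        counts.index.name = None
        return cls(counts)


def build_otu_table(otu_sets: Mapping[str, OTUSet]) -> OTUTable:
    """Counts of reads per (sample, OTU); fails and discarded reads excluded."""
    otu_universe: list[str] = []
    seen = set()
    rows: dict[str, dict[str, int]] = {}
    for sample_id, otu_set in otu_sets.items():
        row: dict[str, int] = defaultdict(int)
        for a in otu_set.assignments:
            if a.otu_id is None:
                continue
            row[a.otu_id] += otu_set.query_abundance.get(a.query_id, 1)
            if a.otu_id not in seen:
                seen.add(a.otu_id)
                otu_universe.append(a.otu_id)
        rows[sample_id] = dict(row)
    counts = pd.DataFrame(
        [[rows[s].get(o, 0) for o in otu_universe] for s in otu_sets],
        index=list(otu_sets), columns=otu_universe, dtype=int)
    return OTUTable(counts)


def richness(table: OTUTable, sample: str) -> int:
    """Number of OTUs with nonzero count in the sample."""
    return int((table.sample_counts(sample) > 0).sum())


def subsample_counts(counts: pd.Series | np.ndarray, depth: int,
                     seed: int | np.random.Generator = 0):
    """Uniform subsampling of reads without replacement to a fixed depth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = counts.values if isinstance(counts, pd.Series) else np.asarray(counts)
    n = int(values.sum())
    if depth > n:
        raise ValueError(f"depth {depth} exceeds sample size {n}")
    pool = np.repeat(np.arange(values.size), values)
    chosen = rng.choice(pool, size=depth, replace=False)
    sub = np.bincount(chosen, minlength=values.size)
    if isinstance(counts, pd.Series):
        return pd.Series(sub, index=counts.index)
    return sub


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            universe = x.index.union(y.index)
            x = x.reindex(universe, fill_value=0.0)
            y = y.reindex(universe, fill_value=0.0)
        return x.values.astype(float), y.values.astype(float)
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must share the OTU universe")
    return x, y


def weighted_jaccard(x, y) -> float:
    """J = 1 - sum min(x_i, y_i) / sum max(x_i, y_i)."""
    xv, yv = _paired(x, y)
    denom = np.maximum(xv, yv).sum()
    if denom == 0:
        raise ValueError("weighted Jaccard undefined for two all-zero vectors")
    return float(1.0 - np.minimum(xv, yv).sum() / denom)


def tree_from_newick(newick: str) -> TreeNode:
    from io import StringIO

    return TreeNode.read(StringIO(newick))


def weighted_unifrac(x, y, tree: TreeNode, normalized: bool = True) -> float:
    """Abundance-weighted UniFrac over a rooted tree with branch lengths.

    num = sum_b l_b |p_x(b) - p_y(b)|, den = sum_b l_b (p_x(b) + p_y(b)),
    where p_s(b) is the fraction of sample s descending through branch b.
    Returns num/den (normalized, in [0, 1]) or the raw sum.
    """
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(y, pd.Series):
        y = y.to_dict()
    leaves = {leaf.name for leaf in tree.tips()}
    for freqs in (x, y):
        unmapped = {otu for otu, f in freqs.items() if f > 0 and otu not in leaves}
        if unmapped:
            raise ValueError(f"OTUs not mapped to tree leaves: {sorted(unmapped)}")

    num = den = 0.0
    # postorder accumulation of the descending fraction per branch
    below: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            px = float(x.get(node.name, 0.0))
            py = float(y.get(node.name, 0.0))
        else:
            px = sum(below[id(c)][0] for c in node.children)
            py = sum(below[id(c)][1] for c in node.children)
        below[id(node)] = (px, py)
        length = node.length or 0.0
        if node.parent is not None and length > 0:
            num += length * abs(px - py)
            den += length * (px + py)
    if not normalized:
        return num
    if den == 0:
        raise ValueError("weighted UniFrac undefined: zero total weighted branch length")
    return num / den


def upgma_tree_from_sequences(seqs: Sequence[tuple[str, str]]) -> TreeNode:
    """Average-linkage tree over pairwise identity distances (1 - identity).

    A convenience for UniFrac over reference OTUs; not a phylogenetic
    inference.
    """
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    from otubench._align import pairwise_identity

    ids = [s[0] for s in seqs]
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(seqs[i][1], seqs[j][1])
            dm[i, j] = dm[j, i] = d
    linkage = average(squareform(dm, checks=False))
    return TreeNode.from_linkage_matrix(linkage, ids)


def distance_histogram(distances: Iterable[float], bin_width: float = 0.05
                       ) -> pd.Series:
    """Bin distances in [0, 1] into left-closed bins; frequencies sum to 1."""
    values = np.asarray(list(distances), dtype=float)
    if values.size == 0:
        raise ValueError("no distances to bin")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("distances must lie in [0, 1]")
    edges = np.round(np.arange(0.0, 1.0 + bin_width, bin_width), 10)
    hist, _ = np.histogram(values, bins=edges)
    labels = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:.2f},{edges[-1]:.2f}]")
    return pd.Series(hist / values.size, index=labels)


def rarefaction_curve(counts: pd.Series, depths: Sequence[int],
                      iterations: int = 10, seed: int = 0) -> pd.Series:
    """Mean richness over repeated subsampling at each depth."""
    rng = np.random.default_rng(seed)
    means = {}
    for depth in depths:
        vals = []
        for _ in range(iterations):
            sub = subsample_counts(counts, depth, rng)
            vals.append(int((sub > 0).sum()))
        means[depth] = float(np.mean(vals))
    return pd.Series(means, name="mean_richness")


# ---------------------------------------------------------------------------
# Splitting / lumping / co-assignment reports


@dataclass
class SplitReport:
    """How strains map onto OTUs: splitting, lumping and outright failure."""

    per_strain_otus: dict[str, set[str]]
    split_strains: list[str]            # strains whose tags span >= 2 OTUs
    n_split_otus: int                   # total OTUs over the split strains
    lumped_groups: dict[str, set[str]]  # otu_id -> strains (>= 2) sharing it
    failed_strains: list[str]           # all tags failed


def splitting_report(known_tag_assignments:
                     Mapping[tuple[str, str, str], AssignmentResult]
                     ) -> SplitReport:
    """Classify strains by the OTUs their known tags were assigned to.

    Keys are (strain_id, paralog_id, tag_name).  A strain may be both split
    (its own tags span several OTUs) and lumped (it shares an OTU with
    another strain).
    """
    per_strain: dict[str, set[str]] = defaultdict(set)
    strains: set[str] = set()
    otu_to_strains: dict[str, set[str]] = defaultdict(set)
    for (strain, _paralog, _tag_name), result in known_tag_assignments.items():
        strains.add(strain)
        if result.otu_id is not None:
            per_strain[strain].add(result.otu_id)
            otu_to_strains[result.otu_id].add(strain)
    split = sorted(s for s, otus in per_strain.items() if len(otus) >= 2)
    lumped = {otu: members for otu, members in otu_to_strains.items()
              if len(members) >= 2}
    failed = sorted(strains - set(per_strain))
    return SplitReport(
        per_strain_otus=dict(per_strain),
        split_strains=split,
        n_split_otus=sum(len(per_strain[s]) for s in split),
        lumped_groups=lumped,
        failed_strains=failed,
    )


def coassignment_matrix(assignments:
                        Mapping[tuple[str, str], AssignmentResult],
                        tag_names: Sequence[str]
                        ) -> tuple[pd.DataFrame, float]:
    """Probability that two tags of the same source land in the same OTU.

    Keys are (source_id, tag_name).  Entry (a, b) is the fraction of sources
    with non-fail assignments for both tags that received the same OTU;
    the companion scalar is the fraction of *all* sources whose tags were all
    assigned to a single OTU.
    """
    if len(tag_names) < 2:
        raise ValueError("need at least two tag names")
    by_source: dict[str, dict[str, str | None]] = defaultdict(dict)
    for (source, tag_name), result in assignments.items():
        by_source[source][tag_name] = result.otu_id
    mat = pd.DataFrame(np.nan, index=list(tag_names), columns=list(tag_names))
    for a in tag_names:
        for b in tag_names:
            both = [(otus[a], otus[b]) for otus in by_source.values()
                    if otus.get(a) is not None and otus.get(b) is not None]
            if both:
                mat.loc[a, b] = float(np.mean([ua == ub for ua, ub in both]))
    n_sources = len(by_source)
    all_same = 0
    for otus in by_source.values():
        ids = [otus.get(t) for t in tag_names]
        if all(i is not None for i in ids) and len(set(ids)) == 1:
            all_same += 1
    return mat, (all_same / n_sources if n_sources else 0.0)
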
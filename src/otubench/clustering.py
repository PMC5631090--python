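"""OTU assignment methods under test.

Closed-reference assignment matches each query against a 97%-identity
clustered reference database and assigns it to a reference OTU at >= 97%
identity, else designates it a *fail*.  Open-reference assignment runs the
closed pass first, clusters the fails de novo (greedy centroid clustering in
decreasing abundance order), and removes OTUs below a minimum read count
(singleton discarding).  Exact mode computes identities against every
reference and is order-independent; heuristic mode ranks references by shared
k-mer counts and abandons the search after a bounded number of rejected
alignments, reproducing the false-negative phenomenology of heuristic
database search without attempting byte-compatibility with any particular
tool.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from otubench._align import pairwise_identity
from otubench.simulate import SampleReads

__all__ = [
    "RefEntry",
    "ReferenceDB",
    "AssignmentResult",
    "OTU",
    "OTUSet",
    "dereplicate",
    "dereplicate_reads",
    "cluster_reference_97",
    "closed_reference_assign",
    "denovo_cluster",
    "open_reference",
    "find_exact_duplicates",
    "decompose_fail_causes",
]

Query = tuple[str, str, int]  # (query_id, sequence, abundance)


@dataclass(frozen=True)
class RefEntry:
    ref_id: str
    sequence: str
    lineage: str = ""


@dataclass
class ReferenceDB:
    entries: list[RefEntry]
    clustered_97: bool = False

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("reference ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.ref_id for e in self.entries]

    def sequence(self, ref_id: str) -> str:
        return next(e.sequence for e in self.entries if e.ref_id == ref_id)

    def lineage(self, ref_id: str) -> str:
        return next(e.lineage for e in self.entries if e.ref_id == ref_id)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], **kw) -> "ReferenceDB":
        return cls([RefEntry(r, s) for r, s in pairs], **kw)


@dataclass(frozen=True)
class AssignmentResult:
    """Per-query outcome: an OTU id, or a fail (otu_id None)."""

    query_id: str
    otu_id: str | None
    identity: float | None
    stage: str  # "closed" | "denovo"
    fail_cause: str | None = None
    discarded: bool = False  # removed by the minimum-OTU-size rule

    @property
    def is_fail(self) -> bool:
        return self.otu_id is None and not self.discarded


@dataclass(frozen=True)
class OTU:
    otu_id: str
    representative: str
    origin: str  # "reference" | "denovo"


@dataclass
class OTUSet:
    otus: list[OTU]
    assignments: list[AssignmentResult]
    threshold: float = 0.97
    #: query_id -> read count (abundance after dereplication)
    query_abundance: dict[str, int] = field(default_factory=dict)

    def otu_ids(self) -> list[str]:
        return [o.otu_id for o in self.otus]

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for a in self.assignments:
            if a.otu_id is not None:
                out[a.otu_id].append(a.query_id)
        return dict(out)

    def otu_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = Counter()
        for a in self.assignments:
            if a.otu_id is not None:
                sizes[a.otu_id] += self.query_abundance.get(a.query_id, 1)
        return dict(sizes)

    def richness(self) -> int:
        return len({a.otu_id for a in self.assignments if a.otu_id is not None})


# ---------------------------------------------------------------------------
# Dereplication


def dereplicate(seqs: Iterable[tuple[str, str]]) -> tuple[list[Query], dict[str, list[str]]]:
    """Collapse exact-duplicate sequences.

    Returns (queries, members): queries as (rep_id, sequence, count) with the
    first-seen id as representative, and the member ids behind each
    representative.
    """
    reps: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    order: list[str] = []
    for sid, seq in seqs:
        rep = reps.get(seq)
        if rep is None:
            reps[seq] = sid
            members[sid] = [sid]
            order.append(seq)
        else:
            members[rep].append(sid)
    queries = [(reps[seq], seq, len(members[reps[seq]])) for seq in order]
    return queries, members


def dereplicate_reads(sample: SampleReads) -> tuple[list[Query], dict[str, list[str]]]:
    return dereplicate((r.read_id, r.sequence) for r in sample.reads)


# ---------------------------------------------------------------------------
# Reference clustering and assignment


def cluster_reference_97(full_refs: ReferenceDB, threshold: float = 0.97
                         ) -> ReferenceDB:
    """Greedy centroid selection in input order.

    A sequence founds a new centroid iff its identity to every existing
    centroid is below the threshold; the output contains centroids only.
    """
    centroids: list[RefEntry] = []
    for entry in full_refs.entries:
        if all(pairwise_identity(entry.sequence, c.sequence) < threshold
               for c in centroids):
            centroids.append(entry)
    return ReferenceDB(centroids, clustered_97=True)


def _best_hit(seq: str, refs: ReferenceDB) -> tuple[str, float]:
    """Highest-identity reference; ties broken by lowest ref_id."""
    best_id, best_ident = None, -1.0
    for e in refs.entries:
        ident = pairwise_identity(seq, e.sequence)
        if ident > best_ident or (ident == best_ident and e.ref_id < best_id):
            best_id, best_ident = e.ref_id, ident
    return best_id, best_ident


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def closed_reference_assign(queries: Sequence[Query],
                            ref97: ReferenceDB,
                            threshold: float = 0.97,
                            mode: str = "exact",
                            k: int = 8,
                            max_accepts: int = 1,
                            max_rejects: int = 32) -> list[AssignmentResult]:
    """Assign each query to a reference OTU at >= threshold identity, else FAIL.

    The threshold comparison is inclusive.  In heuristic mode a FAIL is
    annotated ``heuristic_miss`` when exact mode would have assigned it, and
    ``below_threshold`` otherwise.
    """
    if len(ref97) == 0:
        raise ValueError("reference database is empty")
    if not ref97.clustered_97:
        raise ValueError("closed-reference assignment requires a clustered reference")
    if mode not in ("exact", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")

    results: list[AssignmentResult] = []
    ref_kmers = ({e.ref_id: _kmer_set(e.sequence, k) for e in ref97.entries}
                 if mode == "heuristic" else None)
    for qid, seq, _abund in queries:
        if mode == "exact":
            ref_id, ident = _best_hit(seq, ref97)
            if ident >= threshold:
                results.append(AssignmentResult(qid, ref_id, ident, "closed"))
            else:
                results.append(AssignmentResult(qid, None, ident, "closed"))
            continue
        # heuristic: rank by shared k-mer count, bounded rejects
        qkmers = _kmer_set(seq, k)
        ranked = sorted(ref97.entries,
                        key=lambda e: (-len(qkmers & ref_kmers[e.ref_id]), e.ref_id))
        hit = None
        rejects = 0
        for e in ranked:
            ident = pairwise_identity(seq, e.sequence)
            if ident >= threshold:
                hit = (e.ref_id, ident)
                break
            rejects += 1
            if rejects >= max_rejects:
                break
        if hit is not None:
            results.append(AssignmentResult(qid, hit[0], hit[1], "closed"))
        else:
            _, exact_best = _best_hit(seq, ref97)
            cause = "heuristic_miss" if exact_best >= threshold else "below_threshold"
            results.append(AssignmentResult(qid, None, None, "closed",
                                            fail_cause=cause))
    return results


def denovo_cluster(seqs: Sequence[Query], threshold: float = 0.97) -> OTUSet:
    """Greedy de novo clustering in decreasing abundance order.

    Ties are broken by lexicographic sequence then input order.  A query
    joins the first centroid (in creation order) at >= threshold identity,
    else founds a new centroid.
    """
    ordered = sorted(enumerate(seqs), key=lambda t: (-t[1][2], t[1][1], t[0]))
    otus: list[OTU] = []
    assignments: list[AssignmentResult] = []
    for _, (qid, seq, _abund) in ordered:
        assigned = False
        for otu in otus:
            ident = pairwise_identity(seq, otu.representative)
            if ident >= threshold:
                assignments.append(AssignmentResult(qid, otu.otu_id, ident, "denovo"))
                assigned = True
                break
        if not assigned:
            otu = OTU(f"denovo:{qid}", seq, "denovo")
            otus.append(otu)
            assignments.append(AssignmentResult(qid, otu.otu_id, 1.0, "denovo"))
    return OTUSet(otus=otus, assignments=assignments, threshold=threshold,
                  query_abundance={qid: ab for qid, _s, ab in seqs})


def open_reference(queries: Sequence[Query],
                   ref97: ReferenceDB,
                   threshold: float = 0.97,
                   min_otu_size: int = 2,
                   mode: str = "exact",
                   **heuristic_kw) -> OTUSet:
    """Closed-reference first, de novo on the fails, then size filtering.

    OTUs whose total assigned read count falls below ``min_otu_size`` are
    removed and their queries marked discarded.  Read counts use the query
    abundances (dereplicated read counts), not unique-sequence counts.
    """
    closed = closed_reference_assign(queries, ref97, threshold, mode, **heuristic_kw)
    by_id = {qid: (qid, seq, ab) for qid, seq, ab in queries}
    fails = [by_id[a.query_id] for a in closed if a.otu_id is None]
    denovo = denovo_cluster(fails, threshold) if fails else OTUSet([], [], threshold, {})

    abundance = {qid: ab for qid, _s, ab in queries}
    assignments = [a for a in closed if a.otu_id is not None] + denovo.assignments
    hit_refs = {a.otu_id for a in closed if a.otu_id is not None}
    otus = ([OTU(e.ref_id, e.sequence, "reference")
             for e in ref97.entries if e.ref_id in hit_refs]
            + denovo.otus)

    sizes: Counter = Counter()
    for a in assignments:
        sizes[a.otu_id] += abundance.get(a.query_id, 1)
    small = {otu_id for otu_id, n in sizes.items() if n < min_otu_size}

    final: list[AssignmentResult] = []
    for a in assignments:
        if a.otu_id in small:
            final.append(AssignmentResult(a.query_id, None, a.identity, a.stage,
                                          fail_cause="min_size_discarded",
                                          discarded=True))
        else:
            final.append(a)
    return OTUSet(otus=[o for o in otus if o.otu_id not in small],
                  assignments=final, threshold=threshold,
                  query_abundance=abundance)


# ---------------------------------------------------------------------------
# Reference QC scans


def find_exact_duplicates(refs: ReferenceDB) -> list[tuple[str, str]]:
    """All unordered id pairs with byte-identical sequences (exact hashing)."""
    groups: dict[str, list[str]] = defaultdict(list)
    for e in refs.entries:
        groups[e.sequence].append(e.ref_id)
    pairs: list[tuple[str, str]] = []
    for ids in groups.values():
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
    return sorted(pairs)


def decompose_fail_causes(queries: Sequence[Query],
                          full_refs: ReferenceDB,
                          ref97: ReferenceDB,
                          threshold: float = 0.97,
                          source_ids: Mapping[str, str | None] | None = None,
                          **heuristic_kw) -> dict[str, str]:
    """Explain heuristic-mode fails.

    For every query that fails in heuristic mode: ``heuristic_miss`` if exact
    mode assigns it (a search false negative); ``below_threshold_vs_ref97``
    if its best exact identity is below the threshold although its source
    sequence is present in the full reference database; ``true_novel``
    otherwise.  ``source_ids`` maps query ids to the id of the full-length
    source sequence, when known.
    """
    source_ids = source_ids or {}
    full_ids = set(full_refs.ids)
    heuristic = closed_reference_assign(queries, ref97, threshold,
                                        mode="heuristic", **heuristic_kw)
    causes: dict[str, str] = {}
    by_id = {qid: seq for qid, seq, _ab in queries}
    for a in heuristic:
        if a.otu_id is not None:
            continue
        _, exact_best = _best_hit(by_id[a.query_id], ref97)
        if exact_best >= threshold:
            causes[a.query_id] = "heuristic_miss"
        elif source_ids.get(a.query_id) in full_ids:
            causes[a.query_id] = "below_threshold_vs_ref97"
        else:
            causes[a.query_id] = "true_novel"
    return causes


# ---------------------------------------------------------------------------
# uc-like output


def write_otu_map(otu_set: OTUSet, path: str | Path) -> None:
    """otu_id -> member query ids, one OTU per line (uc-like TSV)."""
    with open(path, "w") as fh:
        for otu_id, member_ids in sorted(otu_set.members().items()):
            fh.write(otu_id + "\t" + "\t".join(member_ids) + "\n")


def write_fails(otu_set: OTUSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in otu_set.assignments:
            if a.is_fail:
                fh.write(a.query_id + "\n")
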
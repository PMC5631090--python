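"""Lineage handling, taxonomy transfer and genus-level accuracy metrics.

Lineages use the seven-rank Greengenes-style string layout
``k__...; p__...; c__...; o__...; f__...; g__...; s__...``.  OTU taxonomy is
predicted by transferring the lineage of the nearest reference sequence.
Genus predictions for a sample are scored against the designed community's
genus set: with N distinct correct names, M distinct predicted names and TP
the correct predictions, the discovery rate is DR = TP/N, the true
prediction rate TPR = TP/M and the false prediction rate FPR = FP/M;
percentages are rendered as floored integers.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from otubench._align import pairwise_identity
from otubench.clustering import OTUSet, ReferenceDB
from otubench.simulate import Provenance
from otubench.tags import KnownTag

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "Lineage",
    "parse_lineage",
    "format_lineage",
    "assign_taxonomy_nearest",
    "GenusEval",
    "evaluate_genus_predictions",
    "check_taxonomy_consistency",
    "attribute_otus",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = "kpcofgs"

#: Sentinel for an OTU whose representative matches no reference closely enough.
UNCLASSIFIED = None


@dataclass(frozen=True)
class Lineage:
    ranks: tuple[str, str, str, str, str, str, str]

    def __getattr__(self, name):
        if name in RANKS:
            return self.ranks[RANKS.index(name)]
        raise AttributeError(name)


def parse_lineage(s: str) -> Lineage:
    """Parse a ``k__; p__; ...`` string; missing ranks become empty."""
    values = [""] * 7
    if s.strip():
        last_idx = -1
        for part in s.split(";"):
            part = part.strip()
            if not part:
                continue
            if len(part) < 3 or part[1:3] != "__" or part[0].lower() not in _PREFIXES:
                raise ValueError(f"malformed lineage component {part!r}")
            idx = _PREFIXES.index(part[0].lower())
            if idx <= last_idx:
                raise ValueError(f"rank order violated at {part!r} in {s!r}")
            last_idx = idx
            values[idx] = part[3:].strip()
    return Lineage(tuple(values))


def format_lineage(lineage: Lineage) -> str:
    return "; ".join(f"{p}__{v}" for p, v in zip(_PREFIXES, lineage.ranks))


def assign_taxonomy_nearest(otu_rep: str, refs: ReferenceDB,
                            min_identity: float = 0.90) -> Lineage | None:
    """Lineage of the highest-identity reference, or UNCLASSIFIED.

    Ties are broken by the lexicographically lowest reference id.
    """
    if len(refs) == 0:
        raise ValueError("reference database is empty")
    best_id, best_ident = None, -1.0
    for e in refs.entries:
        ident = pairwise_identity(otu_rep, e.sequence)
        if ident > best_ident or (ident == best_ident and e.ref_id < best_id):
            best_id, best_ident = e.ref_id, ident
    if best_ident < min_identity:
        return UNCLASSIFIED
    return parse_lineage(refs.lineage(best_id))


@dataclass(frozen=True)
class GenusEval:
    """Genus prediction scorecard: counts plus DR/TPR/FPR."""

    n: int   # distinct correct names
    m: int   # distinct predicted names
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp + self.fp != self.m or self.tp + self.fn != self.n:
            raise ValueError("inconsistent counts: need TP+FP=M and TP+FN=N")

    @property
    def dr(self) -> float:
        return self.tp / self.n

    @property
    def tpr(self) -> float:
        return self.tp / self.m if self.m else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / self.m if self.m else 0.0

    @staticmethod
    def _pct(x: float) -> int:
        return math.floor(100.0 * x)

    @property
    def dr_pct(self) -> int:
        return self._pct(self.dr)

    @property
    def tpr_pct(self) -> int:
        return self._pct(self.tpr)

    @property
    def fpr_pct(self) -> int:
        return self._pct(self.fpr)

    @classmethod
    def from_counts(cls, n: int, m: int, tp: int) -> "GenusEval":
        return cls(n=n, m=m, tp=tp, fp=m - tp, fn=n - tp)

    def as_row(self) -> dict:
        return {"N": self.n, "M": self.m, "TP": self.tp, "FP": self.fp,
                "FN": self.fn, "DR": f"{self.dr_pct}%",
                "TPR": f"{self.tpr_pct}%", "FPR": f"{self.fpr_pct}%"}


def evaluate_genus_predictions(predicted: Iterable[str],
                               truth: Iterable[str]) -> GenusEval:
    """Set-based genus scoring (duplicates and order are irrelevant)."""
    predicted = set(predicted)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty: DR undefined")
    tp = len(predicted & truth)
    return GenusEval(n=len(truth), m=len(predicted), tp=tp,
                     fp=len(predicted - truth), fn=len(truth - predicted))


def check_taxonomy_consistency(lineages: Iterable[Lineage]
                               ) -> dict[str, set[str]]:
    """Genera placed in two or more families — a violation of a valid taxonomy.

    Genera with empty names are ignored, as are empty family fields.
    """
    families: dict[str, set[str]] = defaultdict(set)
    for lineage in lineages:
        genus = lineage.genus
        family = lineage.family
        if genus and family:
            families[genus].add(family)
    return {g: fams for g, fams in families.items() if len(fams) >= 2}


def attribute_otus(otu_set: OTUSet,
                   provenance: Mapping[str, Provenance],
                   known_tags: Sequence[KnownTag],
                   read_members: Mapping[str, Sequence[str]] | None = None
                   ) -> dict[str, str]:
    """Label each OTU by what produced it.

    ``correct`` when the representative equals a known tag; otherwise the
    majority provenance category of member reads (error_derived,
    chimera_derived, crosstalk_derived), or ``mixed`` when no category
    exceeds half the members.  ``read_members`` expands dereplicated query
    ids back to read ids; when omitted, query ids are taken as read ids.
    """
    tag_seqs = {t.sequence for t in known_tags}
    labels: dict[str, str] = {}
    members = otu_set.members()
    reps = {o.otu_id: o.representative for o in otu_set.otus}
    for otu_id, query_ids in members.items():
        if reps.get(otu_id) in tag_seqs:
            labels[otu_id] = "correct"
            continue
        read_ids: list[str] = []
        for qid in query_ids:
            read_ids.extend(read_members[qid] if read_members else [qid])
        cats = Counter()
        for rid in read_ids:
            if rid not in provenance:
                raise KeyError(f"missing provenance for read {rid!r}")
            cats[provenance[rid].category] += 1
        total = sum(cats.values())
        category, count = cats.most_common(1)[0]
        if count * 2 <= total:
            labels[otu_id] = "mixed"
        else:
            labels[otu_id] = {
                "error": "error_derived",
                "chimera": "chimera_derived",
                "crosstalk": "crosstalk_derived",
                "clean": "mixed",
            }[category]
    return labels
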
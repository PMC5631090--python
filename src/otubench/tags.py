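"""Primer matching and extraction of amplicon tags from 16S rRNA sequences.

A *tag* is the segment of the 16S gene between a pair of PCR primers, named
by the hyper-variable region(s) it spans (V4, V35, ...).  Given full-length
reference sequences, this module locates degenerate primers (ungapped, with a
mismatch budget), extracts the inter-primer segment, and builds the catalogue
of *known tags* — the sequences reads would have if sequencing were
error-free.  It also provides single-substitution variant enumeration and the
pairwise identity measure used throughout the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Seq import Seq

from otubench._align import hamming_distance, pairwise_identity  # noqa: F401

__all__ = [
    "IUPAC_CODES",
    "NO_AMPLICON",
    "Primer",
    "PrimerPair",
    "KnownTag",
    "PrimerHit",
    "reverse_complement",
    "match_primer",
    "extract_tag",
    "enumerate_1sub_variants",
    "pairwise_identity",
    "build_known_tags",
    "filter_full_span",
    "read_fasta",
    "write_fasta",
    "write_known_tags_fasta",
    "read_known_tags_fasta",
    "load_primer_pairs",
]

#: IUPAC nucleotide codes mapped to the set of bases they match.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Sentinel returned when no amplicon can be extracted for a primer pair.
NO_AMPLICON = None

_STRICT = frozenset("ACGT")


def _validate_nt(seq: str, *, degenerate: bool, what: str) -> None:
    allowed = IUPAC_CODES.keys() if degenerate else _STRICT
    bad = set(seq) - set(allowed)
    if bad:
        raise ValueError(f"invalid nucleotide code(s) {sorted(bad)} in {what}")


@dataclass(frozen=True)
class Primer:
    """A PCR primer given 5'->3' as an IUPAC string."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        _validate_nt(self.sequence, degenerate=True, what=f"primer {self.name!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair defining one amplicon region."""

    tag_name: str
    forward: Primer
    reverse: Primer
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward":
            raise ValueError("forward primer must have orientation='forward'")
        if self.reverse.orientation != "reverse":
            raise ValueError("reverse primer must have orientation='reverse'")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class KnownTag:
    """An error-free amplicon for one (strain, paralog, region)."""

    strain_id: str
    paralog_id: str
    tag_name: str
    sequence: str
    copies: int = 2

    def __post_init__(self) -> None:
        _validate_nt(self.sequence, degenerate=False, what="known tag")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass(frozen=True)
class PrimerHit:
    """An ungapped primer placement: 0-based half-open coordinates."""

    start: int
    end: int
    strand: str
    mismatches: int


def reverse_complement(seq: str) -> str:
    """Reverse complement, degenerate codes included."""
    return str(Seq(seq).reverse_complement())


def match_primer(seq: str, primer: Primer | str, max_mismatches: int = 2,
                 strand: str = "+") -> list[PrimerHit]:
    """Every ungapped placement of *primer* on *seq* with <= max_mismatches.

    Degenerate primer codes match their IUPAC base sets; the subject sequence
    must be strict A/C/G/T.  Hits are returned sorted by start position.
    """
    pattern = primer.sequence if isinstance(primer, Primer) else primer
    if not seq:
        raise ValueError("subject sequence must be non-empty")
    _validate_nt(seq, degenerate=False, what="subject sequence")
    _validate_nt(pattern, degenerate=True, what="primer")
    m = len(pattern)
    sets = [IUPAC_CODES[c] for c in pattern]
    hits: list[PrimerHit] = []
    for start in range(len(seq) - m + 1):
        mm = 0
        for base, allowed in zip(seq[start:start + m], sets):
            if base not in allowed:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            hits.append(PrimerHit(start, start + m, strand, mm))
    return hits


def extract_tag(full_seq: str, pair: PrimerPair) -> str | None:
    """Extract the segment strictly between the primer-binding loci.

    The forward primer is matched on the plus strand; the reverse primer is
    matched as its reverse complement downstream of the forward hit.  With
    multiple placements the leftmost forward hit and the rightmost compatible
    reverse hit are used, maximizing the amplicon span.  Returns
    ``NO_AMPLICON`` when either primer has no placement within the mismatch
    budget or the segment is empty.
    """
    fwd_hits = match_primer(full_seq, pair.forward, pair.max_mismatches)
    if not fwd_hits:
        return NO_AMPLICON
    fwd = fwd_hits[0]
    rc = reverse_complement(pair.reverse.sequence)
    rev_hits = [h for h in match_primer(full_seq, rc, pair.max_mismatches, strand="-")
                if h.start >= fwd.end]
    if not rev_hits:
        return NO_AMPLICON
    rev = rev_hits[-1]
    segment = full_seq[fwd.end:rev.start]
    return segment if segment else NO_AMPLICON


def enumerate_1sub_variants(seq: str) -> set[str]:
    """All 3·L sequences differing from *seq* by exactly one substitution."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    _validate_nt(seq, degenerate=False, what="sequence")
    variants: set[str] = set()
    for i, base in enumerate(seq):
        for other in "ACGT":
            if other != base:
                variants.add(seq[:i] + other + seq[i + 1:])
    return variants


def build_known_tags(strain_seqs: Mapping[str, Sequence[str]],
                     pairs: Sequence[PrimerPair],
                     copies: int = 2) -> list[KnownTag]:
    """Known tags for every (strain, paralog, primer pair) with an amplicon.

    Each extracted tag is entered with the given copy number (two by default,
    so that correct sequences are not lost to singleton discarding);
    identical paralog tags within a strain and region are collapsed with
    summed copies.
    """
    if not strain_seqs:
        raise ValueError("at least one strain required")
    if not pairs:
        raise ValueError("at least one primer pair required")
    collapsed: dict[tuple[str, str, str], tuple[str, int]] = {}
    for strain_id, paralog_seqs in strain_seqs.items():
        for p_idx, full_seq in enumerate(paralog_seqs):
            paralog_id = f"p{p_idx + 1}"
            for pair in pairs:
                tag = extract_tag(full_seq, pair)
                if tag is NO_AMPLICON:
                    continue
                key = (strain_id, pair.tag_name, tag)
                if key in collapsed:
                    first_paralog, n = collapsed[key]
                    collapsed[key] = (first_paralog, n + copies)
                else:
                    collapsed[key] = (paralog_id, copies)
    return [
        KnownTag(strain_id, paralog_id, tag_name, tag_seq, n)
        for (strain_id, tag_name, tag_seq), (paralog_id, n) in collapsed.items()
    ]


def filter_full_span(refs: Iterable[tuple[str, str]],
                     pairs: Sequence[PrimerPair]) -> list[str]:
    """Ids of references with extractable amplicons for *every* primer pair.

    Mirrors the construction of a full-span reference subset: truncated
    sequences lacking any binding locus are excluded.
    """
    kept: list[str] = []
    for ref_id, seq in refs:
        if all(extract_tag(seq, pair) is not NO_AMPLICON for pair in pairs):
            kept.append(ref_id)
    return kept


# ---------------------------------------------------------------------------
# FASTA and primer-config I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def write_known_tags_fasta(path: str | Path, tags: Iterable[KnownTag]) -> None:
    """Header layout: ``strain|paralog|tag_name|copies=k``."""
    write_fasta(path, (
        (f"{t.strain_id}|{t.paralog_id}|{t.tag_name}|copies={t.copies}", t.sequence)
        for t in tags
    ))


def read_known_tags_fasta(path: str | Path) -> list[KnownTag]:
    tags = []
    for header, seq in read_fasta(path):
        strain_id, paralog_id, tag_name, copies_field = header.split("|")
        tags.append(KnownTag(strain_id, paralog_id, tag_name, seq,
                             int(copies_field.removeprefix("copies="))))
    return tags


def load_primer_pairs(path: str | Path) -> list[PrimerPair]:
    """Primer pairs from a YAML config: list of {name, forward, reverse, max_mismatches}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    pairs = []
    for e in entries:
        pairs.append(PrimerPair(
            tag_name=e["name"],
            forward=Primer(f"{e['name']}F", e["forward"].upper(), "forward"),
            reverse=Primer(f"{e['name']}R", e["reverse"].upper(), "reverse"),
            max_mismatches=int(e.get("max_mismatches", 2)),
        ))
    return pairs
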
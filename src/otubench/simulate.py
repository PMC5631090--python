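"""Synthetic mock-community generator with ground-truth read provenance.

Emulates the benchmark's study material: a community of ~20 strains, each
with 1-5 16S rRNA paralogs, sampled under an Even profile (equal 16S gene
abundance) or a Staggered profile (abundances spanning three orders of
magnitude).  Reads are amplicon tags carrying independent per-base
substitution errors at a configurable rate (0.004 models the benchmark's
low-error regime, Phred Q24), optionally degraded Q=2 tails, PCR bimeras, and
cross-talk between multiplexed samples.  Every read records its provenance —
source template, error positions, chimera parents, origin sample — so that
downstream OTU inflation can be attributed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from otubench.tags import (
    KnownTag,
    NO_AMPLICON,
    Primer,
    PrimerPair,
    extract_tag,
    reverse_complement,
)

__all__ = [
    "Strain",
    "MockCommunity",
    "ErrorModel",
    "Provenance",
    "ReadRecord",
    "SampleReads",
    "default_primer_pairs",
    "make_mock_community",
    "community_tags",
    "phred_from_error_prob",
    "error_prob_from_phred",
    "simulate_reads",
    "inject_chimeras",
    "inject_crosstalk",
    "write_fastq",
    "read_fastq",
    "write_provenance_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Standard 16S primers used by the generator: 515F/806R ("V4" region) and
# 341F/805R-style pair anchoring a second, non-overlapping region ("V35").
_V4_FWD = "GTGYCAGCMGCCGCGGTAA"
_V4_REV = "GGACTACNVGGGTWTCTAAT"
_V35_FWD = "CCTACGGGAGGCAGCAG"
_V35_REV = "CCGTCAATTCMTTTRAGT"


def default_primer_pairs(max_mismatches: int = 2) -> list[PrimerPair]:
    """The two primer pairs the generator plants binding sites for."""
    return [
        PrimerPair("V35",
                   Primer("V35F", _V35_FWD, "forward"),
                   Primer("V35R", _V35_REV, "reverse"),
                   max_mismatches),
        PrimerPair("V4",
                   Primer("V4F", _V4_FWD, "forward"),
                   Primer("V4R", _V4_REV, "reverse"),
                   max_mismatches),
    ]


@dataclass(frozen=True)
class Strain:
    strain_id: str
    genus: str
    family: str
    #: (paralog_id, full-length 16S sequence, operon copy number)
    paralogs: tuple[tuple[str, str, int], ...]


@dataclass
class MockCommunity:
    """Ground truth: strains with paralog sequences plus abundance profiles."""

    strains: list[Strain]
    #: sample_id -> strain_id -> relative abundance (sums to 1)
    profiles: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("community must contain at least one strain")
        ids = {s.strain_id for s in self.strains}
        for sample_id, profile in self.profiles.items():
            unknown = set(profile) - ids
            if unknown:
                raise ValueError(f"profile {sample_id!r} references unknown strains {unknown}")
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"profile {sample_id!r} abundances sum to {total}, not 1")

    def strain(self, strain_id: str) -> Strain:
        return next(s for s in self.strains if s.strain_id == strain_id)

    def full_sequences(self) -> list[tuple[str, str]]:
        """(strain|paralog id, sequence) for every paralog."""
        return [(f"{s.strain_id}|{pid}", seq)
                for s in self.strains for pid, seq, _ in s.paralogs]

    def to_yaml(self, path: str | Path) -> None:
        """Serialize the full ground truth (sequences included) as a manifest."""
        import yaml

        doc = {
            "strains": [
                {"strain_id": s.strain_id, "genus": s.genus,
                 "family": s.family,
                 "paralogs": [{"paralog_id": pid, "sequence": seq,
                               "copies": copies}
                              for pid, seq, copies in s.paralogs]}
                for s in self.strains],
            "profiles": {k: dict(v) for k, v in self.profiles.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MockCommunity":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        strains = [
            Strain(d["strain_id"], d["genus"], d["family"],
                   tuple((p["paralog_id"], p["sequence"], p["copies"])
                         for p in d["paralogs"]))
            for d in doc["strains"]]
        return cls(strains=strains, profiles=doc["profiles"])


@dataclass
class ErrorModel:
    """Independent per-base substitution errors with a flat quality string.

    ``assigned_q`` defaults to round(-10 log10 rate), the Phred score
    equivalent to the substitution rate (0.004 -> Q24, 0.002 -> Q27).  With
    ``tail_rate`` > 0 a fraction of reads receives a 3'-terminal run of
    Q=``tail_q`` bases (up to ``tail_max_frac`` of the read), emulating the
    degraded tails that quality filters are meant to remove.
    """

    per_base_sub_rate: float
    assigned_q: int | None = None
    tail_rate: float = 0.0
    tail_q: int = 2
    tail_max_frac: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_sub_rate <= 1.0:
            raise ValueError("per_base_sub_rate must be in [0, 1]")
        if self.assigned_q is None:
            self.assigned_q = (phred_from_error_prob(self.per_base_sub_rate)
                               if self.per_base_sub_rate > 0 else 40)


@dataclass(frozen=True)
class Provenance:
    """Ground-truth origin of one read."""

    source: tuple[str, str] | None = None  # (strain_id, paralog_id)
    error_positions: tuple[int, ...] = ()
    chimera: tuple[str, str, int] | None = None  # (parent_a label, parent_b label, breakpoint)
    chimera_parent_seqs: tuple[str, str] | None = None
    origin_sample: str | None = None  # set when the read is cross-talk

    @property
    def n_errors(self) -> int:
        return len(self.error_positions)

    @property
    def category(self) -> str:
        """Partition label: crosstalk > chimera > error > clean."""
        if self.origin_sample is not None:
            return "crosstalk"
        if self.chimera is not None:
            return "chimera"
        return "error" if self.error_positions else "clean"


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sample_id: str
    sequence: str
    quality: tuple[int, ...]
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError("quality and sequence lengths differ")


@dataclass
class SampleReads:
    sample_id: str
    reads: list[ReadRecord]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError("read ids must be unique within a sample")


# ---------------------------------------------------------------------------
# Community construction


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _instantiate(rng: np.random.Generator, iupac_seq: str) -> str:
    """Concrete A/C/G/T realization of a degenerate primer site."""
    from otubench.tags import IUPAC_CODES

    return "".join(
        c if c in "ACGT" else sorted(IUPAC_CODES[c])[int(rng.integers(len(IUPAC_CODES[c])))]
        for c in iupac_seq
    )


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def make_mock_community(n_strains: int = 21,
                        paralogs_per_strain: tuple[int, int] = (1, 5),
                        paralog_divergence: float = 0.005,
                        profile_kinds: Iterable[str] = ("even", "staggered"),
                        seed: int = 0,
                        core_length: int = 150,
                        n_genera: int | None = None) -> MockCommunity:
    """Generate a ground-truth community.

    Each strain's 16S gene is synthesized as
    ``lead + V35F + core + rc(V35R) + spacer + V4F + core + rc(V4R) + tail``
    with independent random cores per strain and region, so the two tag
    regions are non-overlapping by construction.  Paralogs mutate the cores at
    ``paralog_divergence``.  The Even profile is exactly uniform; the
    Staggered profile draws abundances log-uniformly over three orders of
    magnitude before normalizing.  A few strains share a genus (by default
    mirroring the 21-strain / 18-genus mock design) so that genus-level truth
    is smaller than the strain count.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    kinds = list(profile_kinds)
    if not kinds:
        raise ValueError("profile_kinds must be non-empty")
    bad = set(kinds) - {"even", "staggered"}
    if bad:
        raise ValueError(f"unknown profile kinds {bad}")

    rng = np.random.default_rng(seed)
    if n_genera is None:
        n_genera = max(1, round(n_strains * 18 / 21))
    genus_of = [i % n_genera for i in range(n_strains)]

    lo, hi = paralogs_per_strain
    strains: list[Strain] = []
    for i in range(n_strains):
        core_v35 = _random_seq(rng, core_length)
        core_v4 = _random_seq(rng, core_length)
        lead = _random_seq(rng, 20)
        spacer = _random_seq(rng, 30)
        tail = _random_seq(rng, 20)
        site_35f = _instantiate(rng, _V35_FWD)
        site_35r = reverse_complement(_instantiate(rng, _V35_REV))
        site_4f = _instantiate(rng, _V4_FWD)
        site_4r = reverse_complement(_instantiate(rng, _V4_REV))
        n_paralogs = int(rng.integers(lo, hi + 1))
        paralogs = []
        for p in range(n_paralogs):
            c35 = _mutate(rng, core_v35, paralog_divergence) if p else core_v35
            c4 = _mutate(rng, core_v4, paralog_divergence) if p else core_v4
            gene = (lead + site_35f + c35 + site_35r
                    + spacer + site_4f + c4 + site_4r + tail)
            copies = int(rng.integers(1, 3))
            paralogs.append((f"p{p + 1}", gene, copies))
        g = genus_of[i]
        strains.append(Strain(
            strain_id=f"strain{i + 1:02d}",
            genus=f"Genus{g + 1:02d}",
            family=f"Family{g + 1:02d}",
            paralogs=tuple(paralogs),
        ))

    profiles: dict[str, dict[str, float]] = {}
    ids = [s.strain_id for s in strains]
    for kind in kinds:
        if kind == "even":
            profiles["even"] = {sid: 1.0 / n_strains for sid in ids}
        else:
            weights = 10.0 ** rng.uniform(0.0, 3.0, size=n_strains)
            weights /= weights.sum()
            profiles["staggered"] = dict(zip(ids, weights.tolist()))
    # exact normalization guard
    for profile in profiles.values():
        total = sum(profile.values())
        for sid in profile:
            profile[sid] /= total
    return MockCommunity(strains=strains, profiles=profiles)


def community_tags(community: MockCommunity, pairs: Sequence[PrimerPair]) -> list[KnownTag]:
    """Known tags for simulation: copy numbers follow the paralog operon counts."""
    out: list[KnownTag] = []
    for s in community.strains:
        collapsed: dict[tuple[str, str], tuple[str, int]] = {}
        for pid, gene, copies in s.paralogs:
            for pair in pairs:
                tag = extract_tag(gene, pair)
                if tag is NO_AMPLICON:
                    continue
                key = (pair.tag_name, tag)
                if key in collapsed:
                    first, n = collapsed[key]
                    collapsed[key] = (first, n + copies)
                else:
                    collapsed[key] = (pid, copies)
        for (tag_name, tag), (pid, n) in collapsed.items():
            out.append(KnownTag(s.strain_id, pid, tag_name, tag, n))
    return out


# ---------------------------------------------------------------------------
# Phred arithmetic


def phred_from_error_prob(p: float) -> int:
    """Q = round(-10 log10 p); p=0.004 -> Q24, p=0.002 -> Q27."""
    if not 0.0 < p <= 1.0:
        raise ValueError("error probability must be in (0, 1]")
    return round(-10.0 * math.log10(p))


def error_prob_from_phred(q: int) -> float:
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(community: MockCommunity,
                   tags: Sequence[KnownTag],
                   sample_id: str,
                   n_reads: int,
                   error_model: ErrorModel,
                   seed: int,
                   profile: str | None = None) -> SampleReads:
    """Draw reads from the community's tag templates.

    Templates are drawn proportional to strain abundance times paralog copy
    number; each base is substituted independently at the model's rate to a
    uniformly chosen different base.  The quality string is flat at the
    model's assigned Q (plus an optional degraded Q=2 tail).  Deterministic
    given the seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    profile_key = profile if profile is not None else sample_id
    if profile_key not in community.profiles:
        raise ValueError(f"no abundance profile {profile_key!r}")
    abundances = community.profiles[profile_key]
    templates = [t for t in tags if abundances.get(t.strain_id, 0.0) > 0]
    profiled = {sid for sid, a in abundances.items() if a > 0}
    missing = profiled - {t.strain_id for t in templates}
    if missing:
        raise ValueError(f"profiled strains without tags: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    weights = np.array([abundances[t.strain_id] * t.copies for t in templates])
    weights /= weights.sum()
    picks = rng.choice(len(templates), size=n_reads, p=weights)

    rate = error_model.per_base_sub_rate
    q = int(error_model.assigned_q)
    reads: list[ReadRecord] = []
    for i, pick in enumerate(picks):
        t = templates[pick]
        seq = t.sequence
        err_pos: tuple[int, ...] = ()
        if rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(arr.size) < rate)
            for j in hits:
                choices = _BASES[_BASES != arr[j]]
                arr[j] = rng.choice(choices)
            if hits.size:
                seq = arr.tobytes().decode()
                err_pos = tuple(int(j) for j in hits)
        quality = [q] * len(seq)
        if error_model.tail_rate > 0 and rng.random() < error_model.tail_rate:
            max_tail = max(1, int(error_model.tail_max_frac * len(seq)))
            tail_len = int(rng.integers(1, max_tail + 1))
            quality[len(seq) - tail_len:] = [error_model.tail_q] * tail_len
        reads.append(ReadRecord(
            read_id=f"{sample_id}.r{i + 1}",
            sample_id=sample_id,
            sequence=seq,
            quality=tuple(quality),
            provenance=Provenance(source=(t.strain_id, t.paralog_id),
                                  error_positions=err_pos),
        ))
    return SampleReads(sample_id=sample_id, reads=reads, seed=seed)


def inject_chimeras(sample: SampleReads, rate: float, seed: int) -> SampleReads:
    """Replace a fraction ~rate of reads with single-crossover bimeras.

    Parent templates are taken from two other reads of the sample (hence
    sampled by abundance); the crossover position is uniform over interior
    positions.  Returns a new SampleReads; the input is not modified.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return sample
    if len({r.sequence for r in sample.reads}) < 2:
        raise ValueError("chimera injection requires >= 2 distinct templates")
    rng = np.random.default_rng(seed)
    n = len(sample.reads)
    mask = rng.random(n) < rate
    reads = list(sample.reads)
    for i in np.flatnonzero(mask):
        ia, ib = rng.choice(n, size=2, replace=False)
        a, b = sample.reads[int(ia)], sample.reads[int(ib)]
        min_len = min(len(a.sequence), len(b.sequence))
        if min_len < 2:
            continue
        bp = int(rng.integers(1, min_len))
        seq = a.sequence[:bp] + b.sequence[bp:]
        quality = a.quality[:bp] + b.quality[bp:]
        pa, pb = a.provenance, b.provenance

        def _label(r: ReadRecord) -> str:
            p = r.provenance
            if p is not None and p.source is not None:
                return f"{p.source[0]}|{p.source[1]}"
            return r.read_id

        err = tuple(sorted(
            [j for j in (pa.error_positions if pa else ()) if j < bp]
            + [j for j in (pb.error_positions if pb else ()) if j >= bp]
        ))
        old = reads[int(i)]
        reads[int(i)] = ReadRecord(
            read_id=old.read_id,
            sample_id=old.sample_id,
            sequence=seq,
            quality=quality,
            provenance=Provenance(
                chimera=(_label(a), _label(b), bp),
                chimera_parent_seqs=(a.sequence, b.sequence),
                error_positions=err,
            ),
        )
    return SampleReads(sample_id=sample.sample_id, reads=reads, seed=sample.seed)


def inject_crosstalk(samples: Sequence[SampleReads], rate: float,
                     seed: int) -> list[SampleReads]:
    """Re-label a fraction ~rate of each sample's reads to another sample.

    Destination samples are chosen uniformly among the other samples; moved
    reads are marked with their origin.  Total read count is conserved.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return list(samples)
    if len(samples) < 2:
        raise ValueError("cross-talk requires >= 2 samples")
    rng = np.random.default_rng(seed)
    sample_ids = [s.sample_id for s in samples]
    buckets: dict[str, list[ReadRecord]] = {sid: [] for sid in sample_ids}
    for s_idx, sample in enumerate(samples):
        others = [i for i in range(len(samples)) if i != s_idx]
        mask = rng.random(len(sample.reads)) < rate
        for r_idx, read in enumerate(sample.reads):
            if mask[r_idx]:
                dest = sample_ids[int(rng.choice(others))]
                prov = read.provenance or Provenance()
                buckets[dest].append(replace(
                    read, sample_id=dest,
                    provenance=replace(prov, origin_sample=sample.sample_id)))
            else:
                buckets[sample.sample_id].append(read)
    return [SampleReads(sample_id=sid, reads=buckets[sid], seed=s.seed)
            for sid, s in zip(sample_ids, samples)]


# ---------------------------------------------------------------------------
# FASTQ and provenance I/O (provenance lives in a sidecar TSV, never in FASTQ)


def write_fastq(sample: SampleReads, path: str | Path) -> None:
    """Sanger (Phred+33) FASTQ."""
    with open(path, "w") as fh:
        for r in sample.reads:
            qual = "".join(chr(min(q, 93) + 33) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path, sample_id: str | None = None) -> SampleReads:
    from Bio import SeqIO

    reads = []
    sid = sample_id or Path(path).stem
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(ReadRecord(
            read_id=rec.id, sample_id=sid, sequence=str(rec.seq),
            quality=tuple(rec.letter_annotations["phred_quality"]),
        ))
    return SampleReads(sample_id=sid, reads=reads)


def write_provenance_tsv(samples: Iterable[SampleReads], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\tcategory\tsource\tn_errors\tchimera\torigin_sample\n")
        for sample in samples:
            for r in sample.reads:
                p = r.provenance or Provenance()
                source = f"{p.source[0]}|{p.source[1]}" if p.source else ""
                chim = (f"{p.chimera[0]};{p.chimera[1]};{p.chimera[2]}"
                        if p.chimera else "")
                fh.write(f"{r.read_id}\t{r.sample_id}\t{p.category}\t{source}\t"
                         f"{p.n_errors}\t{chim}\t{p.origin_sample or ''}\n")
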
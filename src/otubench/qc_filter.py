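"""Phred-score read filter in the style of QIIME v1.9 split_libraries_fastq.

A base is *bad* when its Phred score is at or below ``q_bad`` (default 3,
i.e. error probability above 0.5).  A read is truncated immediately before
the first position where a run of more than ``r_run`` consecutive bad bases
begins — the mechanism that removes the Q=2 runs found at 3' ends — and
discarded when the retained segment is shorter than ``p_frac`` of the
original length or contains more than ``n_ambig`` ambiguous (N) bases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from otubench.simulate import ReadRecord, SampleReads

__all__ = ["FilterParams", "FilterOutcome", "FilterStats",
           "quality_filter_read", "filter_sample"]


@dataclass(frozen=True)
class FilterParams:
    q_bad: int = 3
    r_run: int = 3
    p_frac: float = 0.75
    n_ambig: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_frac <= 1.0:
            raise ValueError("p_frac must be in [0, 1]")
        if min(self.q_bad, self.r_run, self.n_ambig) < 0:
            raise ValueError("q_bad, r_run and n_ambig must be >= 0")


@dataclass(frozen=True)
class FilterOutcome:
    status: str  # "pass" | "truncated_pass" | "discarded"
    kept_length: int
    reason: str = ""


@dataclass(frozen=True)
class FilterStats:
    n_input: int
    n_passed: int
    n_truncated: int
    n_rejected: int

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_input if self.n_input else 0.0

    @property
    def fraction_truncated(self) -> float:
        return self.n_truncated / self.n_input if self.n_input else 0.0


def _truncation_point(quality: tuple[int, ...], q_bad: int, r_run: int) -> int | None:
    """Start of the first run of more than r_run consecutive bad bases."""
    run_start = None
    run_len = 0
    for i, q in enumerate(quality):
        if q <= q_bad:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > r_run:
                return run_start
        else:
            run_len = 0
    return None


def quality_filter_read(read: ReadRecord, params: FilterParams
                        ) -> tuple[FilterOutcome, ReadRecord | None]:
    """Apply the truncate-then-check rule to one read."""
    if len(read.sequence) != len(read.quality):
        raise ValueError("sequence and quality lengths differ")
    original = len(read.sequence)
    cut = _truncation_point(read.quality, params.q_bad, params.r_run)
    keep = original if cut is None else cut

    if keep < params.p_frac * original:
        return FilterOutcome("discarded", 0, "retained segment too short"), None

    seq = read.sequence[:keep]
    if seq.count("N") > params.n_ambig:
        return FilterOutcome("discarded", 0, "too many ambiguous bases"), None

    if keep == original:
        return FilterOutcome("pass", keep), read
    prov = read.provenance
    if prov is not None and prov.error_positions:
        prov = replace(prov, error_positions=tuple(
            p for p in prov.error_positions if p < keep))
    truncated = ReadRecord(read.read_id, read.sample_id, seq,
                           read.quality[:keep], prov)
    return FilterOutcome("truncated_pass", keep, "low-quality 3' run"), truncated


def filter_sample(sample: SampleReads, params: FilterParams | None = None
                  ) -> tuple[SampleReads, FilterStats]:
    """Filter every read of a sample; stats are over the input count."""
    params = params or FilterParams()
    kept: list[ReadRecord] = []
    n_trunc = n_rej = 0
    for read in sample.reads:
        outcome, filtered = quality_filter_read(read, params)
        if outcome.status == "discarded":
            n_rej += 1
            continue
        if outcome.status == "truncated_pass":
            n_trunc += 1
        kept.append(filtered)
    stats = FilterStats(len(sample.reads), len(kept), n_trunc, n_rej)
    return SampleReads(sample.sample_id, kept, sample.seed), stats
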
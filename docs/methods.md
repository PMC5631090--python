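# Methods

## Overview

The package benchmarks 97%-identity closed- and open-reference OTU
assignment on synthetic mock communities. Every stage is a pure, seeded
function: a configuration plus a seed determines the community, the reads,
the assignments and every reported number bit-for-bit.

## Sequence identity

Identity between two sequences is the fraction of matching columns in their
optimal global alignment, with terminal gap columns excluded.

- **Equal lengths** (the overwhelmingly common case here, since amplicons
  are extracted between fixed primer loci and the simulator uses a fixed
  core length): the comparison is ungapped, identity = matches/L. This is
  the arithmetic that makes a 250-nt sequence with one substitution
  249/250 = 99.6% identical to its source, and two distinct one-substitution
  variants 248/250 = 99.2% identical to each other. A fully gapped optimum
  could exceed matches/L only on periodic/low-complexity sequences, where a
  shifted alignment is an artifact, so the ungapped convention is used
  unconditionally for equal lengths.
- **Unequal lengths** (quality-truncated reads, chimeras of unequal
  parents): Biopython's pairwise aligner with match +1, mismatch −2, gap
  open −10, gap extend −1 and free terminal gaps. Scoring this stiff keeps
  near-identical alignments ungapped. Identity is computed *glocally*: the
  shorter sequence's unaligned terminal residues still count as columns, so
  a truncated read scores 1.0 against its full-length template, but a short
  spurious overlap cannot masquerade as near-identity. A consequence of
  excluding the longer sequence's overhangs is that identity 1.0 means
  "contiguous substring", not "equal"; equality holds iff identity is 1.0
  *and* lengths match. Arguments are canonicalized before alignment so the
  measure is exactly symmetric even when co-optimal alignments exist.

## Primer matching and tags

Primers are matched ungapped with IUPAC degenerate codes and a mismatch
budget (default 2). A *tag* is the segment strictly between the forward and
reverse primer loci — the primer-binding sites themselves are excluded,
which is a convention of this package (either choice is defensible; this one
makes the tag independent of primer degeneracy). With multiple placements,
the leftmost forward and rightmost downstream reverse hit are used,
maximizing the amplicon deterministically. Known tags are entered in two
copies by default so that correct sequences survive singleton discarding.

## The synthetic community

`make_mock_community` synthesizes each strain's 16S gene as
`lead + V35 site + core + site + spacer + V4 site + core + site + tail`,
with independent random cores per strain (150 nt by default) and two real
primer pairs (515F/806R for "V4"; a 341F/805R-style pair for "V35"). The two
tag regions are therefore non-overlapping by construction, which is exactly
the regime in which cross-region OTU co-assignment is interesting. Paralogs
mutate the cores at 0.5% divergence — comparable to one-substitution
sequencing error, which is why paralogs are a natural cause of strain
splitting. Strains map onto genera so that the genus count is smaller than
the strain count (21 strains / 18 genera by default, the classic mock
design); families are 1:1 with genera.

Profiles: Even is exactly uniform over strains; Staggered draws abundances
log-uniformly over three decades and normalizes (the range is the designed
property; the distribution within it is this package's choice).

Reads: templates are drawn proportional to strain abundance × paralog copy
number; each base substitutes independently at the configured rate to a
uniformly random different base. Quality strings are flat at
Q = round(−10·log₁₀ rate), with an optional degraded tail mode that writes a
3′ run of Q=2 over up to 20% of the read — the pattern the quality filter
exists to remove. Chimeras are single-crossover bimeras whose parents are
two other reads of the sample (hence abundance-weighted); cross-talk
relabels a fraction of reads to a uniformly chosen other sample. Neither a
chimera rate nor a cross-talk rate is a published property of the emulated
datasets; the defaults (1% and 0.1%) are order-of-magnitude choices.
Provenance (source template, error positions, chimera parents and
breakpoint, origin sample) is carried on every read and partitions reads
into clean / error / chimera / crosstalk.

What the simulator does *not* model: platform-specific error profiles
(homopolymer errors, quality decay curves), indels, amplification bias,
multi-parent chimeras. Passing tests therefore demonstrate the assignment
algorithms' behavior under idealized substitution-only noise, not
performance on any particular instrument's reads.

## The reference database

For each tag region the covered strains' distinct tags are greedily
clustered at 97% (input order; a sequence founds a centroid iff below
threshold to all existing centroids). The count of these centroids is the
*true group count* — the richness a perfect method should report.

The database actually searched adds, per centroid, a configurable number of
*near-neighbor* entries one substitution away (two by default). This models
a documented pathology of real 97%-clustered references: residual entries
above the clustering threshold (including outright duplicate pairs) that
should have been merged. Near-neighbors are what let substitution errors
inflate richness under best-hit assignment: a read whose error lands on the
neighbor's differing position becomes strictly closer to the neighbor and
registers a spurious OTU. With a desk-scale database the inflation is capped
at centroids × (1 + neighbors); a production-scale database with ~10⁵
entries produces the corresponding order-of-magnitude inflation.
`ref_coverage < 1` drops strains from the reference entirely, forcing de
novo OTUs in open-reference mode.

## Quality filter

A base is bad when Q ≤ `q_bad` (default 3, error probability > 0.5). A read
is truncated immediately before the first run of more than `r_run` (default
3) consecutive bad bases, then discarded if the retained length is below
`p_frac` (default 0.75) of the original or the retained segment has more
than `n_ambig` (default 0) ambiguous bases. The boundary choice — keep the
bases before the run, cut at the run's start — together with these defaults
mirrors the widely used split-libraries behavior. The filter is idempotent,
and stricter settings never pass more reads.

## Assignment

Queries are dereplicated (exact duplicates collapsed; abundance = read
count) before clustering. Exact mode computes identity to every reference
and takes the best hit, ties broken by lowest reference id, threshold
inclusive (≥ 0.97); it is invariant to query and reference order. Heuristic
mode ranks references by shared 8-mer count and abandons the search after 32
consecutive sub-threshold alignments (first acceptable hit wins) — it exists
to reproduce the false-negative phenomenology of heuristic database search,
not to byte-match any particular tool, and its fails are annotated
`heuristic_miss` when exact mode would have assigned.

De novo clustering processes queries in decreasing abundance (ties:
lexicographic sequence, then input order); a query joins the first centroid
at ≥ threshold, else founds one. Open-reference = closed pass, de novo on
the fails, then removal of OTUs whose total *read* count (not unique
sequence count) is below `min_otu_size` (default 2); removed reads are
marked discarded, and the conservation identity
assigned + failed + discarded = passed holds at all times. One documented
consequence: because the size filter applies to all OTUs, open-reference
richness can be *below* closed-reference richness when scatter produces many
low-count reference OTUs.

Fail causes are decomposed per query: `heuristic_miss` (search false
negative), `below_threshold_vs_ref97` (the source sequence is in the full
reference but its tag is < 97% to the clustered subset — the unavoidable
failure mode of closed-reference assignment), or `true_novel`.

## Diversity metrics

Samples are subsampled without replacement to a fixed depth (default 5,000
reads) *before* frequencies and distances are computed. Weighted Jaccard is
J = 1 − Σ min/Σ max over frequency vectors; its replicate-noise floor scales
like √(K/N) for K OTUs at depth N, which is why small-community fixtures are
used when asserting the "near zero for correct OTUs" property. Weighted
UniFrac is the normalized variant, Σ l·|pₓ−p_y| / Σ l·(pₓ+p_y) over branches
(range [0, 1]); the unnormalized sum is also exposed since either weighting
convention is in use in the field. The tree over reference OTUs is built by
average-linkage (UPGMA) on identity distances — a convenience hierarchy over
known sequences, not a phylogenetic inference. Distance histograms use
left-closed 0.05 bins with the last bin closed. Rarefaction curves average
richness over 10 subsampling iterations per depth.

## Taxonomy evaluation

OTU representatives receive the lineage of their highest-identity reference
(≥ 0.90, else unclassified; unclassified predictions are excluded from M).
Genus scoring is set-based — duplicates and order are irrelevant — with
case-sensitive exact name matching after stripping rank prefixes.
Percentages are rendered as floored integers (23/39 → 58%), the convention
consistent with the published scorecards this mirrors. The consistency check
reports every genus placed in two or more families, ignoring empty names.

OTU attribution labels an OTU `correct` iff its representative equals a
known tag, else by the majority provenance category of its member reads
(`error_derived`, `chimera_derived`, `crosstalk_derived`), with `mixed` when
no category exceeds half — including the anomalous case of a clean-majority
OTU with a wrong representative.

## Problem sizes and determinism

Default benchmark: 21 strains, 4 samples (Even/Staggered × 2 replicates) of
6,000 reads, subsample depth 5,000. Test fixtures use 5–8 strains and
400–7,000 reads per sample — sizes chosen so properties are measured with
comfortable statistical margins while the whole suite runs in well under a
minute of compute. Monotonicity properties (richness vs error and chimera
rate) are asserted on means over 10 seeds. All randomness flows through
`numpy.random.default_rng` from explicit seeds; per-stage child seeds are
derived deterministically from the configuration seed.

## Known limitations

- The de novo stage clusters each sample independently, so de novo OTU ids
  are not comparable across samples; beta diversity is therefore computed on
  closed-reference tables (as in the study design this mirrors).
- The subsampled intermediate step of the canonical open-reference protocol
  (a second closed pass over a random subsample of fails) is simplified to
  closed → de novo → size filter; the analyses depend on the composite's
  outcome, not on that optimization.
- Chao-1 and Phylogenetic Diversity are out of scope by design.
- The reference near-neighbor construction is a model of database
  redundancy, not a reconstruction of how any real reference was built.
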
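# otubench

Benchmarking how closed- and open-reference OTU assignment distort microbial
diversity estimates, using synthetic mock communities with read-level ground
truth.

## The problem

16S rRNA amplicon surveys conventionally group reads into Operational
Taxonomic Units (OTUs) at 97% identity. *Closed-reference* assignment maps
each read to a pre-clustered reference database entry at ≥97% identity and
discards the rest as *fails*; *open-reference* assignment additionally
clusters the fails de novo and removes singleton OTUs. Both methods are
widely used upstream of alpha-diversity (richness), beta-diversity
(between-sample distance) and taxonomy inference — so their artifacts
propagate into biological conclusions.

This package re-implements the assignment algorithms and every evaluation
around them, and exercises them on mock communities where the true answer is
known for each read:

- **Simulator** (`otubench.simulate`): ~20-strain communities with 1–5 16S
  paralogs per strain, Even and Staggered (three-decade) abundance profiles,
  per-base substitution errors (0.004 ≙ Phred Q24, 0.002 ≙ Q27), degraded
  Q=2 read tails, PCR bimeras and inter-sample cross-talk — with full
  provenance per read.
- **Assignment** (`otubench.clustering`): greedy 97% centroid clustering,
  exact and heuristic (k-mer-ranked, bounded-reject) closed-reference search,
  abundance-ordered de novo clustering, the open-reference composite,
  exact-duplicate scans and fail-cause decomposition.
- **Metrics** (`otubench.metrics`): OTU tables, richness, rarefaction,
  subsampling to a fixed depth, the weighted Jaccard distance

  J(X, Y) = 1 − Σᵢ min(xᵢ, yᵢ) / Σᵢ max(xᵢ, yᵢ),   xᵢ = nᵢ/N,

  normalized weighted UniFrac over a tree of OTUs, 0.05-bin distance
  histograms, strain splitting/lumping reports, and tag co-assignment
  probabilities.
- **Taxonomy** (`otubench.taxonomy`): Greengenes-style lineage parsing,
  nearest-reference lineage transfer, genus scorecards (N, M, TP, FP, FN;
  DR = TP/N, TPR = TP/M, FPR = FP/M with floored percentages), and the
  genus-in-multiple-families consistency check.
- **Pipeline** (`otubench.pipeline`): the seeded end-to-end benchmark and
  the idealized known-tags experiment.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`. For example:

```bash
python analysis/03_read_benchmark.py --seed 1
```

prints, among other things, richness versus substitution error rate for a
single Even sample of a 21-strain community (true = number of 97%-identity
groups of the known tags):

```
            true  closed  open
error_rate
0.000         21      21    21
0.002         21      26    21
0.004         21      29    27
0.008         21      40    35
```

With error-free reads both methods recover exactly the true group count;
a low 0.4% error rate already inflates closed-reference richness by ~40%
because errored reads scatter onto near-duplicate reference entries. And

```bash
python analysis/04_beta_diversity.py --seed 1
```

```
replicates, correct OTUs : Jaccard 0.026  UniFrac 0.013
replicates, split OTUs   : Jaccard 0.131  UniFrac 0.055
```

shows the beta-diversity contrast: comparing a clean and a noisy run of the
*same* community, the weighted Jaccard distance inflates fivefold while
weighted UniFrac barely moves, because the spurious OTUs sit next to the
correct OTU in the tree.

The other drivers build the community artifacts (`01`), run the idealized
known-tags experiment (`02`), and score taxonomy predictions plus the
hierarchy consistency check (`05`).

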
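# pbletools

Analysis toolkit for transposon integration assays with piggyBac-like
elements (pbles) — cut-and-paste DNA transposons that insert at the
tetranucleotide TTAA, duplicating it on both flanks (the target-site
duplication, TSD), and whose ends carry ~13-bp terminal inverted repeats
(TIRs) plus subterminal inverted-repeat (STIR/IIR) blocks.

It is written for people who run cell-based integration assays (a
selectable cassette flanked by pble ends on a donor plasmid, junctions
recovered by LAM-PCR and sequenced) and for people relating
transposase ChIP-seq peaks to repeat annotations. Three capabilities,
plus a fully seeded synthetic-data generator so everything is testable
without downloads:

- **`pbletools.irscan`** — exhaustive detection of pble-like inverted
  repeats (arm 5–15 bp, spacer 2–10 bp, Hamming distance between the left
  arm and the reverse complement of the right arm ≤ 0 for 5-bp arms, ≤ 1
  for arms ≥ 6 bp), non-overlapping motif censuses and tandem-unit runs.
- **`pbletools.junctions`** — split-read calling of chromosome↔donor
  breakpoint pairs from junction reads, deduplication with a strict
  spread filter, and classification of each unique junction into the 2×2
  of TSD propriety (chromosomal tetranucleotide = TTAA) × TIR propriety
  (donor breakpoint exactly at a TIR outer terminus), with per-donor
  percentage tables, a fold-over-random statistic
  (observed % / expected % under uniform breakpoint placement), and
  per-coordinate breakpoint histograms.
- **`pbletools.overlap`** — permutation significance of peak/annotation
  overlap: the peak set is shuffled (lengths and chromosomes preserved,
  placements non-overlapping and uniform), the overlap count of each
  shuffle forms the null, and `z = (obs − μ₀)/σ₀` is converted to a
  normal-tail p (the empirical rank p is reported alongside), plus
  exclusion-list filtering and peak width/read-density summaries.

## Worked example

`python examples/03_junction_classification.py` plants 100 integration
events (four-way signature mixture 0.112/0.016/0.039/0.833) in a
synthetic 90-kb genome, simulates error-free 250-nt junction reads at
depth 3 per element end, and runs call → dedupe → classify → summarise:

```
600 reads -> 200 unique junctions (0 internal, 0 unsplit)
  PROPER_TSD_TIR              15.0% (30 junctions; 15 planted events)
  PROPER_TSD_IMPROPER_TIR      1.0% (2 junctions; 1 planted events)
  IMPROPER_TSD_PROPER_TIR      4.0% (8 junctions; 4 planted events)
  IMPROPER_BOTH               80.0% (160 junctions; 80 planted events)
proper-signature rate is 4.8x the 3.1% random expectation
```

Each event yields one 5'-end and one 3'-end junction, so every planted
class count is recovered exactly (doubled), and the proper-signature
percentage is compared with the expectation if breakpoints were placed
uniformly over the LAM-PCR-accessible window.

`python examples/04_overlap_permutation.py` shows the permutation test on
a peak set with 60% planted annotation overlap (observed 60 vs null
10.5 ± 3.0, z ≈ 16.7) next to a matched null dataset (z ≈ 0.2, p ≈ 0.42).

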
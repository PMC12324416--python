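# Methods

## Background and scope

piggyBac-like elements (pbles) are cut-and-paste DNA transposons that
insert at the tetranucleotide TTAA, which is duplicated on both flanks of
a canonical insertion (the target-site duplication, TSD). Their outermost
ends carry ~13-bp terminal inverted repeats (TIRs; the 5' TIR is the
reverse complement of the 3' TIR) and, depending on the element, 19-bp
subterminal inverted repeats (STIRs) or inner IRs just inside the TIRs.
In cell-based integration assays a donor plasmid carries a selectable
cassette between two pble ends; junctions between chromosomes and the
integrated donor are amplified by linear amplification-mediated PCR
(LAM-PCR), one reaction per element end, and sequenced as ~250-nt reads.

`pbletools` implements the three computational procedures such an assay
needs — pble-like inverted-repeat/motif annotation, junction calling with
four-way signature classification, and permutation overlap statistics for
ChIP-seq-style peak sets — together with a synthetic-data generator so
every stage is testable without external downloads.

## Inverted-repeat scanner

An inverted repeat is a triple (left start *i*, arm length *a*, spacer
*s*): arms `seq[i, i+a)` and `seq[i+a+s, i+2a+s)` such that the Hamming
distance between the left arm and the reverse complement of the right arm
is at most *k(a)*. Defaults follow the signature of pble subterminal/inner
IRs: *a* ∈ [5, 15], *s* ∈ [2, 10], *k(a)* = 0 for *a* < 6 and 1 for
*a* ≥ 6. `N` never matches anything, including another `N` (implemented
by encoding the complement of `N` as a sixth symbol).

The scan is exhaustive over (i, a, s) and vectorised over *i* (one numpy
comparison per arm offset per (a, s) pair, O(Σa·S·L) byte operations).
By default only the longest admissible arm per (*i*, *s*) locus is
reported ("maximal" mode), which suppresses nested shorter arms at the
same locus while keeping the reporting dense; full enumeration is
available with `maximal=False` and is what the brute-force oracle in the
test suite checks against (exhaustive output is strand-symmetric; the
maximality filter is defined on left starts and therefore is not, which
is why the strand-symmetry property is asserted in exhaustive mode).

Motif censuses (`count_motif_nonoverlapping`) use a greedy left-to-right
scan: after a match at *i* the scan resumes at *i* + |motif|; with
`both_strands` the reverse-complement motif is counted in a second
independent scan and summed. Tandem runs (`find_tandem_runs`) are maximal
head-to-tail repeats of an exact unit with the copy number in the score
field; the greedy scan does not re-report phase-shifted sub-runs of a
reported run.

`annotate_donor_ends` widens the spacer range to the whole inter-block
distance (STIR partners sit at opposite element ends) and restricts
output to arm pairs lying entirely within the two subterminal blocks.

## Donor constructs and the synthetic-data generator

A donor construct is laid out as

```
backbone(100) | TTAA | TIR5(13) | sub5(55) | cassette(>=200) | sub3(55) | TIR3(13) | TTAA | backbone(100)
```

with all blocks contiguous and TIR5 = revcomp(TIR3). Templates differ in
their subterminal blocks: `ifp2_like`/`mer75_like` plant a 19-bp STIR arm
pair 3 bp inside the 5' TIR inner end whose partner ends 31 bp before the
3' TIR inner end; `mer75b_like` plants a local IR at the 5' end only;
`mer85_like`/`looper_like` plant local inner IRs with different sequences
at each end; `plain` is random. The bases adjacent to a planted STIR arm
are forced not to extend the palindromic pairing, so the annotated arm
boundary is sharp at every seed (without this, a 1-in-4 chance base makes
the 19-bp pair ambiguous by ±1 bp). The template sequences reproduce the
*structure* of real pble ends, not their literal sequences.

Background genomes are i.i.d. with a configurable GC fraction (default
0.41, human-like); planted features (TTAA sites, (TGGAA)n satellite
arrays, SSR runs, IR pairs, pble copies) override the background at
non-overlapping positions recorded exactly in a truth table. This is the
simplest null that exercises every scanner; it has none of the long-range
repeat structure, assembly gaps or base-composition heterogeneity of a
real genome, so passing tests demonstrate correctness of the logic, not
performance on real data.

Integration events (`simulate_integrations`) draw class counts from a
single multinomial over the four signature classes; the default mixture
(0.112, 0.016, 0.039, 0.833) is the observed four-way split of the most
transposition-permissive human-pble donor in the reference junction
table. Event anatomy:

- **proper TSD + proper TIR** — the TIR-to-TIR unit inserted at a TTAA
  site with the tetranucleotide duplicated on both flanks;
- **proper TSD, improper TIR** — duplicated TTAA, but each end either
  truncated (5-40 bp removed from the outer end) or carrying 5-40 bp of
  donor flank beyond the TIR terminus (carryover is measured from the TIR
  outer terminus, so it includes the donor's own TTAA plus backbone);
  truncation and carryover are exclusive per event and applied to both
  ends symmetrically;
- **improper TSD, proper TIR** — intact unit duplicated at a divergent
  (non-TTAA) tetranucleotide, modelling proper transposition at a
  divergent target;
- **improper both** — truncation/carryover at a non-TTAA site without
  duplication (blunt integration).

Insertion sites are resampled (bounded retries) so that every junction is
*locally unambiguous*: no chance micro-homology between donor and
chromosome extends an exact match past the true breakpoint. The 4-bp
ambiguity intrinsic to TSD duplication is retained — it is a property of
the biology, and the caller resolves it explicitly (below). Without this
resampling about a quarter of junctions would carry ≥1 bp of breakpoint
ambiguity that no caller could resolve from sequence alone, and exact
truth recovery would be impossible by construction rather than by defect.

Junction reads start at a primer anchor at the cassette boundary and run
outward across the element end into chromosomal sequence, one read family
per end (the two ends are never paired within one read, mirroring the two
independent LAM-PCR reactions). Errors are substitutions only; the
exact-seed caller makes no indel claims and indel robustness is a
non-goal. Reads are emitted donor-first regardless of event orientation.

## Junction calling and classification

Stage 1 discards reads that are exact substrings (either strand) of the
cassette — pure internal reads carry no junction information. Stage 2
computes the longest read prefix occurring in the donor construct (either
strand; binary search over length, monotone containment) and the longest
read suffix occurring in the genome (any contig, either strand), and
requires prefix + suffix to cover the read up to a 2-base slack.
Admissible splits form a window (the overlap of the two matches, clamped
so both parts are ≥ `min_seed` = 20); because of the duplicated TSD this
window is 4 bp wide at every proper junction. The caller prefers a split
whose donor-side breakpoint falls on an annotated TIR outer terminus —
the construct annotation is a known input, exactly as in the real assay —
and otherwise takes the maximal-genome split. A window of `min_seed` or
wider (a long donor/genome shared substring spanning the breakpoint)
flags the event as ambiguous.

Unique junctions are groups over (contig, chromosomal breakpoint, element
end, orientation) with summed support. The donor-side alignment end of a
read is its chosen split coordinate (the aligner-equivalent soft-clips
the TSD into the genome side); the consensus donor breakpoint is the
modal value, and the junction is retained iff the absolute difference
between the consensus and the most deviating alignment end is strictly
below 3 ("difference below 3" read as a strict inequality on the
breakpoint-vs-maximal-extent difference; the spread field is max − min of
the alignment ends).

Classification is the 2×2 of TSD propriety — the plus-strand
tetranucleotide on the chromosomal side immediately outside the junction
equals TTAA (judged from the single visible junction side, as LAM-PCR
sees one end per read; TTAA is its own reverse complement, so the call is
orientation-independent for canonical sites) — and TIR propriety — the
donor breakpoint exactly at the relevant TIR outer terminus, a 1-bp slip
being improper. Breakpoints inside the cassette are UNCLASSIFIED and
excluded from class totals. Percentages are count/total rounded to one
decimal; the four counts always sum to the unique-junction total.

`expected_random_fraction(window, positions=4)` gives the percentage of
uniformly placed breakpoints that would be scored proper; the window
length (primer anchor to ~100 bp beyond the element end) is an input
because it depends on primer placement. `fold_over_random` is the
observed/expected ratio rounded to one decimal.

## Permutation overlap statistics

Overlap counts are computed on merged annotation intervals with
half-open arithmetic (≥1 bp overlap; each query counted once). The
permutation test shuffles the *query* (peak) set — annotations held fixed
— preserving each interval's length and chromosome and keeping placements
mutually non-overlapping; `z = (observed − null mean)/null sd`
(sd with one delta degree of freedom) is converted to a normal-tail
probability (default tail: enrichment), and the empirical permutation
rank p (add-one corrected) is reported alongside. A degenerate null
(sd = 0, e.g. annotations covering whole contigs) null-flags z and p.

Non-overlapping placement uses the exact gap construction: k intervals of
total length T on a contig of length L are placed by drawing k
non-decreasing offsets from [0, L − T] (sorted uniforms, floored) and
adding back cumulative lengths in a per-draw random length order. This is
uniform over admissible configurations up to the negligible discretisation
of the floor step, never needs retries when the intervals fit (infeasible
inputs raise), and vectorises over thousands of permutations — which is
what keeps the 500-replicate type-I calibration suite at a few seconds.
Rejection sampling was deliberately not used for this core path.

`make_interval_sets` places an exact planted fraction of peaks onto
annotations; its `background="avoid"` default rejects accidental overlap
of the remaining peaks (so the observed count equals the planted count
exactly, convenient for construction tests). For null *calibration* the
avoid background is wrong — it biases the observed count below the
shuffle null — so calibration uses peaks placed by the same uniform
non-overlapping process as the permutation null (`shuffle_intervals`),
which is the exchangeable null the test assumes.

## Problem sizes and numerical choices

- Test/acceptance genomes: 4 × 30 kb (junctions) and 4 × 500 kb interval
  universes (overlap stats); 200 simulated events at depth 3 for exact
  recovery; 100 × 300-nt sequences for IR oracle equivalence; 500 null
  datasets × 1000 permutations for type-I calibration and 200 replicates
  at 90% planted enrichment for power. These sizes give stable statistics
  while keeping the full suite to well under a minute of compute.
- The substitution-robustness property uses per-end depth 15 at rate
  0.005: LAM-PCR libraries are heavily duplicated, and with exact-seed
  splitting a read is informative essentially only when error-free
  (probability ≈ 0.29 at 250 nt), so depth is chosen to make at least one
  clean read per end near-certain.
- Ties in modal donor-breakpoint consensus resolve to the smallest value;
  greedy motif ties resolve leftmost-first; IR output is sorted by (left
  start, arm, spacer).
- All generators are pure functions of their integer seed
  (`numpy.random.default_rng`); reruns are byte-identical.

## Known limitations

- The caller is exact-seed by design: it supports the synthetic
  substitutions-only error model, not gapped alignment or real LAM-PCR
  chemistry (primer/linker trimming, restriction-site effects).
- Shuffles are uniform over full contig lengths; no GC-, gap- or
  blacklist-aware placement model (exclusion filtering of the *observed*
  peak set is supported).
- The IR scanner is correctness-first; genome-scale runs work but are not
  performance-tuned, and degenerate-alphabet motifs are unsupported.
- Whether a Z-based normal-tail p or the empirical rank is preferred is
  left to the user; both are reported, and they agree closely whenever
  the null mean is more than a few counts.
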
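"""Chromosome-donor junction calling and four-way signature classification.

Junction reads (one family per element end, donor-first) are split into a
donor part and a chromosomal part by exact matching: the longest read
prefix found in the donor construct (either strand) and the longest read
suffix found in the genome (either strand). A junction is emitted at the
split; because a canonical insertion duplicates the TTAA target, every
proper junction carries an intrinsic 4-bp breakpoint ambiguity, which is
resolved by preferring a split whose donor-side breakpoint falls on an
annotated TIR outer terminus (the construct annotation is a known input),
falling back to the maximal-genome split.

Unique junctions are grouped by (contig, chromosomal breakpoint, element
end, orientation); a junction is retained if the absolute difference
between its consensus donor-side breakpoint and the most deviating
donor-side alignment end among its supporting reads is strictly below 3.
Each retained junction is classified into the 2x2 of target-site-
duplication propriety (chromosomal tetranucleotide == TTAA) and TIR
propriety (donor breakpoint exactly at the relevant TIR outer terminus).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .core import GenomeSequence, reverse_complement
from .synth import (
    CLASSES,
    IMPROPER_BOTH,
    IMPROPER_TSD_PROPER_TIR,
    PROPER_TSD_IMPROPER_TIR,
    PROPER_TSD_TIR,
    UNCLASSIFIED,
    DonorConstruct,
    _longest_prefix_len,
    _longest_suffix_len,
)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class JunctionEvent:
    """One chromosome-donor breakpoint pair (raw, per read, or unique)."""

    contig: str
    chrom_pos: int
    orientation: str          # '+' / '-' insertion orientation
    donor_pos: int            # donor-side breakpoint, construct coordinates
    end: str                  # five_prime / three_prime
    support: int = 1
    spread: int = 0           # max - min donor-side alignment ends
    ambiguous: bool = False
    flank_up: str = ""
    flank_down: str = ""
    clipped: bool = False
    tsd_call: str | None = None
    klass: str = UNCLASSIFIED
    donor_ends: list[int] = field(default_factory=list)  # per supporting read
    read_names: list[str] = field(default_factory=list)


@dataclass
class CallResult:
    events: list[JunctionEvent]
    n_reads: int
    n_stage1_discarded: int
    n_no_split: int


def call_junctions(
    reads: list[tuple[str, str]],
    genome: GenomeSequence,
    donor: DonorConstruct,
    min_seed: int = 20,
    slack: int = 2,
) -> CallResult:
    """Two-stage exact-seed split caller for donor-first junction reads.

    Stage 1 discards reads fully contained (exact match, either strand) in
    the donor cassette — pure internal reads carry no junction. Stage 2
    requires donor prefix + genome suffix to cover the read up to ``slack``
    bases; reads with no admissible split are dropped and counted. Events
    whose donor and genome matches share a substring of >= ``min_seed``
    spanning the breakpoint are flagged ambiguous.
    """
    donor_fwd = donor.sequence
    donor_rc = reverse_complement(donor_fwd)
    Ld = len(donor_fwd)
    cassette_seq = donor_fwd[donor.cassette[0]:donor.cassette[1]]
    genome_fwd = {c: s for c, s in genome.contigs.items()}
    genome_rc = {c: reverse_complement(s) for c, s in genome.contigs.items()}
    genome_texts = list(genome_fwd.values()) + list(genome_rc.values())

    events: list[JunctionEvent] = []
    n_stage1 = 0
    n_no_split = 0

    for name, read in reads:
        n = len(read)
        if n < 2 * min_seed:
            raise ValueError(f"read {name!r} shorter than 2*min_seed")
        if read in cassette_seq or reverse_complement(read) in cassette_seq:
            n_stage1 += 1
            continue

        k = _longest_prefix_len(read, [donor_fwd, donor_rc])
        m = _longest_suffix_len(read, genome_texts)
        if k + m < n - slack or k < min_seed or m < min_seed:
            n_no_split += 1
            continue

        # donor-side mapping of the prefix
        prefix = read[:k]
        v = donor_rc.find(prefix)
        if v != -1:
            end = FIVE_PRIME
            donor_of = lambda i: Ld - v - i
            terminus = donor.tir5_terminus
        else:
            u = donor_fwd.find(prefix)
            if u == -1:  # cannot happen: k was verified by containment
                n_no_split += 1
                continue
            end = THREE_PRIME
            donor_of = lambda i: u + i
            terminus = donor.tir3_terminus

        # genome-side mapping of the suffix
        suffix = read[n - m:]
        chrom = None
        for c, s in genome_fwd.items():
            q = s.find(suffix)
            if q != -1:
                chrom, genome_strand = c, "fwd"
                chrom_of = lambda i, q=q: q + (i - (n - m))
                break
        if chrom is None:
            for c, s in genome_rc.items():
                r = s.find(suffix)
                if r != -1:
                    chrom, genome_strand = c, "rc"
                    L = len(s)
                    chrom_of = lambda i, L=L, r=r: L - r - (i - (n - m))
                    break
        if chrom is None:
            n_no_split += 1
            continue

        if end == FIVE_PRIME:
            orientation = "+" if genome_strand == "rc" else "-"
        else:
            orientation = "+" if genome_strand == "fwd" else "-"

        gap = (n - m) - k
        if gap > 0:  # up to `slack` unmatched bases at the junction
            i = k
        else:
            i_lo = max(n - m, min_seed)
            i_hi = min(k, n - min_seed)
            if i_lo > i_hi:
                n_no_split += 1
                continue
            # prefer a split landing on the TIR outer terminus (TSD window)
            i_term = None
            for cand in range(i_lo, i_hi + 1):
                if donor_of(cand) == terminus:
                    i_term = cand
                    break
            i = i_term if i_term is not None else i_lo

        events.append(
            JunctionEvent(
                contig=chrom,
                chrom_pos=chrom_of(i),
                orientation=orientation,
                donor_pos=donor_of(i),
                end=end,
                support=1,
                ambiguous=(k + m - n) >= min_seed,
                donor_ends=[donor_of(i)],
                read_names=[name],
            )
        )

    return CallResult(events, len(reads), n_stage1, n_no_split)


def dedupe_and_filter(
    events: list[JunctionEvent], max_spread_diff: int = 3
) -> list[JunctionEvent]:
    """Collapse supporting reads into unique junctions and spread-filter.

    Events are grouped by (contig, chromosomal position, element end,
    orientation) with summed support. The consensus donor-side breakpoint
    is the modal value; the junction is retained iff the absolute
    difference between the consensus and the most deviating donor-side
    alignment end is strictly below ``max_spread_diff``.
    """
    groups: dict[tuple, list[JunctionEvent]] = defaultdict(list)
    for ev in events:
        groups[(ev.contig, ev.chrom_pos, ev.end, ev.orientation)].append(ev)

    unique: list[JunctionEvent] = []
    for (contig, pos, end, orientation), members in groups.items():
        ends = [d for ev in members for d in ev.donor_ends]
        consensus, _ = Counter(ends).most_common(1)[0]
        diff = max(abs(d - consensus) for d in ends)
        if diff >= max_spread_diff:
            continue
        unique.append(
            JunctionEvent(
                contig=contig,
                chrom_pos=pos,
                orientation=orientation,
                donor_pos=consensus,
                end=end,
                support=sum(ev.support for ev in members),
                spread=max(ends) - min(ends),
                ambiguous=any(ev.ambiguous for ev in members),
                donor_ends=ends,
                read_names=[n for ev in members for n in ev.read_names],
            )
        )
    unique.sort(key=lambda e: (e.contig, e.chrom_pos, e.end))
    return unique


@dataclass
class FlankInfo:
    flank_up: str
    flank_down: str
    tsd_call: str | None
    clipped: bool


def extract_flanks(
    genome: GenomeSequence,
    contig: str,
    position: int,
    end: str = FIVE_PRIME,
    orientation: str = "+",
    flank_len: int = 10,
) -> FlankInfo:
    """10-bp chromosomal flanks around a breakpoint plus the TSD call.

    ``flank_up`` is the sequence ending at ``position``, ``flank_down`` the
    sequence starting at it; near contig edges flanks are shorter and
    flagged clipped. The TSD call is the plus-strand tetranucleotide on the
    chromosomal side immediately outside the donor junction — upstream for
    a 5'-end junction in '+' orientation or a 3'-end junction in '-',
    downstream otherwise — so a canonical insertion reads TTAA for either
    end and orientation (TTAA is its own reverse complement).
    """
    seq = genome.contigs[contig]
    if not 0 <= position <= len(seq):
        raise ValueError(f"position {position} outside contig {contig!r}")
    up = seq[max(0, position - flank_len):position]
    down = seq[position:position + flank_len]
    clipped = len(up) < flank_len or len(down) < flank_len
    tsd_side_up = (end == FIVE_PRIME) == (orientation == "+")
    if tsd_side_up:
        tsd = seq[position - 4:position] if position >= 4 else None
    else:
        tsd = seq[position:position + 4] if position + 4 <= len(seq) else None
    return FlankInfo(up, down, tsd, clipped)


def classify(event: JunctionEvent, donor: DonorConstruct) -> str:
    """Four-way signature class of a unique junction.

    Proper TIR requires the donor-side breakpoint exactly at the outer
    terminus of the relevant TIR (a 1-bp slip is improper); proper TSD
    requires the chromosomal-side tetranucleotide to equal the donor's TSD
    motif. Breakpoints inside the cassette are UNCLASSIFIED.
    """
    c0, c1 = donor.cassette
    if c0 <= event.donor_pos < c1:
        return UNCLASSIFIED
    terminus = (donor.tir5_terminus if event.end == FIVE_PRIME
                else donor.tir3_terminus)
    proper_tir = event.donor_pos == terminus
    proper_tsd = event.tsd_call == donor.tsd_motif
    if proper_tsd and proper_tir:
        return PROPER_TSD_TIR
    if proper_tsd:
        return PROPER_TSD_IMPROPER_TIR
    if proper_tir:
        return IMPROPER_TSD_PROPER_TIR
    return IMPROPER_BOTH


def annotate_events(
    events: list[JunctionEvent], genome: GenomeSequence, donor: DonorConstruct
) -> list[JunctionEvent]:
    """Fill flanks, TSD call and class for unique junctions, in place."""
    for ev in events:
        info = extract_flanks(genome, ev.contig, ev.chrom_pos, ev.end,
                              ev.orientation)
        ev.flank_up, ev.flank_down = info.flank_up, info.flank_down
        ev.tsd_call, ev.clipped = info.tsd_call, info.clipped
        ev.klass = classify(ev, donor)
    return events


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class ClassCounts:
    """Per-donor counts and percentages of the four signature classes."""

    donor: str
    counts: dict[str, int]
    total: int
    percentages: dict[str, float]
    expected_random_pct: float | None = None

    @classmethod
    def from_counts(
        cls,
        counts,
        donor: str = "donor",
        expected_random_pct: float | None = None,
    ) -> "ClassCounts":
        """Build from four category counts, in the canonical class order."""
        if not isinstance(counts, dict):
            counts = dict(zip(CLASSES, counts))
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no classified junctions to summarise")
        pct = {k: round(100 * counts.get(k, 0) / total, 1) for k in CLASSES}
        return cls(donor=donor, counts={k: counts.get(k, 0) for k in CLASSES},
                   total=total, percentages=pct,
                   expected_random_pct=expected_random_pct)

    def to_row(self) -> dict:
        row = {"donor": self.donor, "total": self.total}
        for k in CLASSES:
            row[f"pct_{k.lower()}"] = self.percentages[k]
            row[f"n_{k.lower()}"] = self.counts[k]
        row["expected_random_pct"] = self.expected_random_pct
        return row


def summarize(
    events: list[JunctionEvent],
    donor_name: str = "donor",
    expected_random_pct: float | None = None,
) -> ClassCounts:
    """Class counts/percentages over classified unique junctions.

    UNCLASSIFIED junctions (donor breakpoint inside the cassette) are
    excluded from the totals.
    """
    counts = Counter(ev.klass for ev in events if ev.klass != UNCLASSIFIED)
    return ClassCounts.from_counts(dict(counts), donor=donor_name,
                                   expected_random_pct=expected_random_pct)


def summaries_to_table(summaries: list[ClassCounts]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def expected_random_fraction(window_len: int, proper_positions: int = 4) -> float:
    """Percentage of breakpoints scored proper if placed uniformly at random.

    ``window_len`` is the donor-coordinate window accessible to LAM-PCR
    (primer anchor to ~100 bp beyond the element end); ``proper_positions``
    is the number of positions scored as a proper terminus.
    """
    if window_len < proper_positions or proper_positions <= 0:
        raise ValueError("need window_len >= proper_positions > 0")
    return 100.0 * proper_positions / window_len


def fold_over_random(observed_pct: float, expected_pct: float) -> float:
    """Observed/expected proper-signature percentage, rounded to 1 decimal."""
    if expected_pct <= 0:
        raise ValueError("expected_pct must be > 0")
    return round(observed_pct / expected_pct, 1)


def breakpoint_histogram(events: list[JunctionEvent]) -> pd.DataFrame:
    """Junction counts per donor coordinate, with end and class recorded."""
    counter: Counter = Counter()
    for ev in events:
        counter[(ev.donor_pos, ev.end, ev.klass)] += 1
    rows = [
        {"donor_pos": pos, "end": end, "klass": klass, "count": c}
        for (pos, end, klass), c in sorted(counter.items())
    ]
    return pd.DataFrame(rows, columns=["donor_pos", "end", "klass", "count"])


def events_to_table(events: list[JunctionEvent]) -> pd.DataFrame:
    rows = [
        {
            "contig": ev.contig, "chrom_pos": ev.chrom_pos,
            "orientation": ev.orientation, "end": ev.end,
            "donor_pos": ev.donor_pos, "support": ev.support,
            "spread": ev.spread, "tsd_call": ev.tsd_call or ".",
            "flank_up": ev.flank_up, "flank_down": ev.flank_down,
            "klass": ev.klass, "ambiguous": ev.ambiguous,
        }
        for ev in events
    ]
    return pd.DataFrame(rows)
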
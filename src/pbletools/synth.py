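"""Synthetic genomes, donor constructs, integration events, junction reads
and peak/annotation interval sets with known ground truth.

The generator emulates the data structure assumed by the junction and
overlap analyses: donor plasmids whose piggyBac-like element (pble) is
flanked by the TTAA target tetranucleotide and 100-bp plasmid-backbone
regions, with 13-bp terminal inverted repeats (TIRs) and subterminal IR
blocks; integration events of the four junction-signature classes; 250-nt
junction reads starting at a primer anchor on the donor side and running
across the junction into chromosomal sequence (one read family per element
end, mirroring the two independent linear-amplification reactions); and
peak sets with a planted fraction of annotation overlap.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GenomeSequence, Interval, reverse_complement

# four-way junction signature classes
PROPER_TSD_TIR = "PROPER_TSD_TIR"
PROPER_TSD_IMPROPER_TIR = "PROPER_TSD_IMPROPER_TIR"
IMPROPER_TSD_PROPER_TIR = "IMPROPER_TSD_PROPER_TIR"
IMPROPER_BOTH = "IMPROPER_BOTH"
UNCLASSIFIED = "UNCLASSIFIED"
CLASSES = (PROPER_TSD_TIR, PROPER_TSD_IMPROPER_TIR, IMPROPER_TSD_PROPER_TIR,
           IMPROPER_BOTH)

DONOR_TEMPLATES = ("ifp2_like", "mer75_like", "mer75b_like", "mer85_like",
                   "looper_like", "plain")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Donor constructs
# ---------------------------------------------------------------------------


@dataclass
class DonorConstruct:
    """Donor plasmid region: backbone flanks, TTAA-flanked pble, cassette.

    Layout (all blocks contiguous, coordinates on ``sequence``)::

        backbone_left | tsd_left | tir5 | sub5 | cassette | sub3 | tir3 | tsd_right | backbone_right

    The 5' TIR is the reverse complement of the 3' TIR. ``primer_five`` /
    ``primer_three`` are the donor coordinates where the junction reads of
    the 5'- and 3'-end amplification reactions start (reads run outward,
    across the element end, into chromosomal sequence).
    """

    name: str
    sequence: str
    backbone_left: tuple[int, int]
    tsd_left: tuple[int, int]
    tir5: tuple[int, int]
    sub5: tuple[int, int]
    cassette: tuple[int, int]
    sub3: tuple[int, int]
    tir3: tuple[int, int]
    tsd_right: tuple[int, int]
    backbone_right: tuple[int, int]
    tsd_motif: str = "TTAA"
    primer_five: int = 0
    primer_three: int = 0
    # planted subterminal IR arm pairs ((left start, end), (right start, end))
    planted_stirs: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        blocks = [self.backbone_left, self.tsd_left, self.tir5, self.sub5,
                  self.cassette, self.sub3, self.tir3, self.tsd_right,
                  self.backbone_right]
        pos = 0
        for b in blocks:
            if b[0] != pos or b[1] < b[0]:
                raise ValueError("donor blocks must be contiguous and ordered")
            pos = b[1]
        if pos != len(self.sequence):
            raise ValueError("donor blocks must tile the full sequence")
        if self.tir5_seq != reverse_complement(self.tir3_seq):
            raise ValueError("5' TIR must be the reverse complement of the 3' TIR")
        for tsd in (self.tsd_left, self.tsd_right):
            if self.sequence[tsd[0]:tsd[1]] != self.tsd_motif:
                raise ValueError("pble ends must be flanked by the TSD motif")

    @property
    def tir5_seq(self) -> str:
        return self.sequence[self.tir5[0]:self.tir5[1]]

    @property
    def tir3_seq(self) -> str:
        return self.sequence[self.tir3[0]:self.tir3[1]]

    @property
    def pble_span(self) -> tuple[int, int]:
        """TIR-outer-terminus to TIR-outer-terminus (the mobilised unit)."""
        return (self.tir5[0], self.tir3[1])

    @property
    def tir5_terminus(self) -> int:
        return self.tir5[0]

    @property
    def tir3_terminus(self) -> int:
        return self.tir3[1]


def make_donor(
    pble_template: str = "ifp2_like",
    cassette_len: int = 1000,
    seed: int = 0,
    tir_len: int = 13,
    backbone_len: int = 100,
    subterm_len: int = 55,
    tsd_motif: str = "TTAA",
) -> DonorConstruct:
    """Build a donor construct with the end architecture of a pble template.

    ``ifp2_like`` and ``mer75_like`` carry a 19-bp subterminal IR arm pair
    spanning the element: one arm 3 bp inside the 5' TIR inner end, the
    partner ending 31 bp before the 3' TIR inner end. ``mer75b_like``
    carries a local subterminal IR at the 5' end only; ``mer85_like`` and
    ``looper_like`` carry local inner IRs (different sequences) at both
    ends; ``plain`` has fully random subterminal blocks.
    """
    if pble_template not in DONOR_TEMPLATES:
        raise ValueError(f"unknown template {pble_template!r}")
    if cassette_len < 200:
        raise ValueError("cassette_len must be >= 200")
    if subterm_len < 55:
        raise ValueError("subterm_len must be >= 55 to hold the planted arms")
    rng = np.random.default_rng(seed)

    tir5 = _random_seq(rng, tir_len)
    tir3 = reverse_complement(tir5)
    cassette = _random_seq(rng, cassette_len)
    bb_left = _random_seq(rng, backbone_len)
    bb_right = _random_seq(rng, backbone_len)

    planted: list[tuple[tuple[int, int], tuple[int, int]]] = []

    def _local_ir(block_len: int, arm: int = 8, spacer: int = 5):
        """Random block with a local IR (arm + spacer + rc(arm)) at offset 3."""
        a = _random_seq(rng, arm)
        sp = _random_seq(rng, spacer)
        tail = _random_seq(rng, block_len - 3 - 2 * arm - spacer)
        return _random_seq(rng, 3) + a + sp + reverse_complement(a) + tail, \
            (3, 3 + arm), (3 + arm + spacer, 3 + 2 * arm + spacer)

    if pble_template in ("ifp2_like", "mer75_like"):
        stir = _random_seq(rng, 19)
        sub5 = _random_seq(rng, 3) + stir + _random_seq(rng, subterm_len - 22)
        # partner arm ends 31 bp before the 3' TIR inner end
        sub3 = (_random_seq(rng, subterm_len - 50)
                + reverse_complement(stir) + _random_seq(rng, 31))
        arms5 = (3, 22)
        arms3 = (subterm_len - 50, subterm_len - 31)
        # pin the arm boundaries: the bases adjacent to the planted arms
        # must not extend the palindromic pairing, so the annotated 19-bp
        # pair is sharply defined at offsets 3 and 31 (a base b never
        # pairs with itself, so copying the partner's adjacent base works)
        s3 = list(sub3)
        s3[subterm_len - 31] = sub5[2]    # outer-adjacent pair
        s3[subterm_len - 51] = sub5[22]   # inner-adjacent pair
        sub3 = "".join(s3)
    elif pble_template == "mer75b_like":
        sub5, a5, b5 = _local_ir(subterm_len)
        sub3 = _random_seq(rng, subterm_len)
        arms5 = arms3 = None
        planted.append((a5, b5))  # offsets within sub5, fixed up below
    elif pble_template in ("mer85_like", "looper_like"):
        sub5, a5, b5 = _local_ir(subterm_len)
        sub3, a3, b3 = _local_ir(subterm_len)
        arms5 = arms3 = None
        planted.append((a5, b5))
        planted.append((a3, b3))
    else:  # plain
        sub5 = _random_seq(rng, subterm_len)
        sub3 = _random_seq(rng, subterm_len)
        arms5 = arms3 = None

    parts = [bb_left, tsd_motif, tir5, sub5, cassette, sub3, tir3, tsd_motif,
             bb_right]
    coords = []
    pos = 0
    for part in parts:
        coords.append((pos, pos + len(part)))
        pos += len(part)
    (c_bbl, c_tsdl, c_tir5, c_sub5, c_cass, c_sub3, c_tir3, c_tsdr,
     c_bbr) = coords

    stirs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    if arms5 is not None:
        stirs.append((
            (c_sub5[0] + arms5[0], c_sub5[0] + arms5[1]),
            (c_sub3[0] + arms3[0], c_sub3[0] + arms3[1]),
        ))
    else:
        base = {0: c_sub5[0], 1: c_sub3[0]}
        for k, (la, ra) in enumerate(planted):
            off = base[0] if pble_template == "mer75b_like" or k == 0 else base[1]
            stirs.append(((off + la[0], off + la[1]), (off + ra[0], off + ra[1])))

    return DonorConstruct(
        name=pble_template,
        sequence="".join(parts),
        backbone_left=c_bbl,
        tsd_left=c_tsdl,
        tir5=c_tir5,
        sub5=c_sub5,
        cassette=c_cass,
        sub3=c_sub3,
        tir3=c_tir3,
        tsd_right=c_tsdr,
        backbone_right=c_bbr,
        tsd_motif=tsd_motif,
        primer_five=c_cass[0],
        primer_three=c_cass[1],
        planted_stirs=stirs,
    )


# ---------------------------------------------------------------------------
# Genomes with planted features
# ---------------------------------------------------------------------------


def make_genome(
    lengths,
    gc_fraction: float = 0.41,
    seed: int = 0,
    planted: dict | None = None,
    max_tries: int = 200,
) -> tuple[GenomeSequence, dict[str, list[Interval]]]:
    """I.i.d. background genome with optional planted features.

    ``lengths`` is a contig-name -> length mapping or a list of lengths
    (auto-named ``contig1``...). ``planted`` may hold:

    - ``ttaa_sites``: int, number of extra planted TTAA motifs
    - ``tggaa_arrays``: list of copy numbers of (TGGAA)n satellite arrays
    - ``ssr_runs``: list of (unit, copies) simple-sequence-repeat runs
    - ``ir_pairs``: list of (arm_len, spacer_len) inverted-repeat pairs
    - ``pble_copies``: list of DonorConstruct whose pble spans are copied in

    Returns the genome and a truth table: planted-class -> exact intervals.
    Placement is non-overlapping with bounded retries; infeasible placement
    raises ValueError.
    """
    if not isinstance(lengths, dict):
        lengths = {f"contig{i + 1}": L for i, L in enumerate(lengths)}
    for name, L in lengths.items():
        if L < 500:
            raise ValueError(f"contig {name!r} shorter than 500 bp")
    rng = np.random.default_rng(seed)

    arrays = {}
    gc = gc_fraction
    for name, L in lengths.items():
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arrays[name] = _BASES[rng.choice(4, size=L, p=p)].copy()

    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in lengths}
    truth: dict[str, list[Interval]] = {}

    def _place(feature_seq: str, klass: str, label: str) -> None:
        w = len(feature_seq)
        names = [n for n, L in lengths.items() if L >= w]
        if not names:
            raise ValueError(f"feature of length {w} does not fit any contig")
        weights = np.array([lengths[n] - w + 1 for n in names], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            name = names[rng.choice(len(names), p=weights)]
            start = int(rng.integers(0, lengths[name] - w + 1))
            end = start + w
            if any(start < e and s < end for s, e in occupied[name]):
                continue
            arrays[name][start:end] = np.frombuffer(
                feature_seq.encode("ascii"), dtype=np.uint8
            )
            occupied[name].append((start, end))
            truth.setdefault(klass, []).append(
                Interval(name, start, end, label=label)
            )
            return
        raise ValueError(f"could not place feature of length {w} "
                         f"after {max_tries} tries")

    planted = planted or {}
    for _ in range(int(planted.get("ttaa_sites", 0))):
        _place("TTAA", "ttaa_sites", "TTAA")
    for copies in planted.get("tggaa_arrays", []):
        _place("TGGAA" * copies, "tggaa_arrays", f"(TGGAA){copies}")
    for unit, copies in planted.get("ssr_runs", []):
        _place(unit * copies, "ssr_runs", f"({unit}){copies}")
    for arm_len, spacer_len in planted.get("ir_pairs", []):
        arm = _random_seq(rng, arm_len)
        seq = arm + _random_seq(rng, spacer_len) + reverse_complement(arm)
        _place(seq, "ir_pairs", f"ir_arm{arm_len}_sp{spacer_len}")
    for donor in planted.get("pble_copies", []):
        s0, s1 = donor.pble_span
        _place(donor.sequence[s0:s1], "pble_copies", donor.name)

    genome = GenomeSequence(
        {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Integration events and junction reads
# ---------------------------------------------------------------------------


@dataclass
class TrueIntegration:
    """Ground truth for one simulated integration event."""

    index: int
    contig: str
    position: int           # insertion point p on the original contig
    orientation: str        # '+' or '-'
    true_class: str
    tir_truncation: int     # bp removed from each outer end (0 = intact)
    backbone_carryover: int  # bp of donor flank retained beyond each TIR terminus
    tsd_at_site: str        # tetranucleotide at [p, p+4) on the plus strand
    duplicated: bool        # target tetranucleotide duplicated on both flanks

    def __post_init__(self) -> None:
        if self.true_class in (PROPER_TSD_TIR, PROPER_TSD_IMPROPER_TIR):
            assert self.tsd_at_site == "TTAA"
        if self.true_class in (PROPER_TSD_TIR, IMPROPER_TSD_PROPER_TIR):
            assert self.tir_truncation == 0 and self.backbone_carryover == 0
        else:
            assert (self.tir_truncation > 0) != (self.backbone_carryover > 0)


@dataclass
class SimulatedIntegration:
    """One event plus its two junction read templates and true junctions.

    ``read5_template``/``read3_template`` read donor-first: from the primer
    anchor, outward across the element end, into chromosomal sequence.
    ``junction5``/``junction3`` are (contig, chrom breakpoint, donor
    breakpoint, orientation) for the 5'- and 3'-end junctions.
    """

    truth: TrueIntegration
    read5_template: str
    read3_template: str
    junction5: tuple[str, int, int, str]
    junction3: tuple[str, int, int, str]


def _longest_prefix_len(read: str, texts: list[str]) -> int:
    lo, hi = 0, len(read)
    while lo < hi:  # binary search: containment is monotone in length
        mid = (lo + hi + 1) // 2
        if any(read[:mid] in t for t in texts):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _longest_suffix_len(read: str, texts: list[str]) -> int:
    lo, hi = 0, len(read)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if any(read[-mid:] in t for t in texts):
            lo = mid
        else:
            hi = mid - 1
    return lo


def simulate_integrations(
    genome: GenomeSequence,
    donor: DonorConstruct,
    n: int,
    class_mixture: tuple[float, float, float, float] = (0.112, 0.016, 0.039, 0.833),
    truncation_range: tuple[int, int] = (5, 40),
    carryover_range: tuple[int, int] = (5, 40),
    seed: int = 0,
    flank_window: int = 400,
    max_tries: int = 500,
) -> tuple[list[SimulatedIntegration], list[TrueIntegration]]:
    """Simulate ``n`` integration events with a four-class signature mixture.

    Class counts are multinomial(``n``, ``class_mixture``) (the first draw
    from the seeded generator). Proper-TSD events insert the pble at a TTAA
    site with the tetranucleotide duplicated on both flanks; improper-TSD
    proper-TIR events duplicate a divergent (non-TTAA) tetranucleotide;
    improper-TIR events carry either a symmetric TIR truncation or a
    symmetric donor-flank carryover (never both). Insertion sites are
    resampled so that each junction is locally unambiguous at the sequence
    level (no chance micro-homology extends a match past the true
    breakpoint); the intrinsic 4-bp ambiguity of the duplicated target site
    is retained.
    """
    if any(p < 0 for p in class_mixture) or not math.isclose(
        sum(class_mixture), 1.0, abs_tol=1e-9
    ):
        raise ValueError("class_mixture must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, class_mixture)

    W = flank_window
    tsd = donor.tsd_motif

    # admissible TTAA sites per contig (far enough from contig edges)
    ttaa_pool: list[tuple[str, int]] = []
    total_ttaa = 0
    for name, seq in genome.contigs.items():
        i = seq.find(tsd)
        while i != -1:
            total_ttaa += 1
            if W <= i and i + 4 <= len(seq) - W:
                ttaa_pool.append((name, i))
            i = seq.find(tsd, i + 1)
    if total_ttaa < n:
        raise ValueError(f"genome contains {total_ttaa} {tsd} sites, need >= {n}")

    contig_names = list(genome.contigs)
    contig_weights = np.array([genome.lengths[c] for c in contig_names], float)
    contig_weights /= contig_weights.sum()

    used: dict[str, list[int]] = {c: [] for c in contig_names}
    donor_texts = [donor.sequence, reverse_complement(donor.sequence)]
    genome_texts = [s for s in genome.contigs.values()]
    genome_texts += [reverse_complement(s) for s in genome.contigs.values()]

    def _free(contig: str, p: int) -> bool:
        return all(abs(p - q) > 8 for q in used[contig])

    def _random_site(require):
        for _ in range(max_tries):
            c = contig_names[rng.choice(len(contig_names), p=contig_weights)]
            seq = genome.contigs[c]
            p = int(rng.integers(W, len(seq) - W - 4))
            if _free(c, p) and require(seq, p):
                return c, p
        raise RuntimeError("could not find an admissible insertion site")

    def _build(c, p, dup, ins_start, ins_end, orientation):
        seq = genome.contigs[c]
        insert = donor.sequence[ins_start:ins_end]
        a5 = donor.primer_five - ins_start
        b3 = donor.primer_three - ins_start
        left = seq[p + 4 - W : p + 4] if dup else seq[p - W : p]
        right = seq[p : p + W]
        if orientation == "+":
            read5 = reverse_complement(insert[:a5]) + reverse_complement(left)
            read3 = insert[b3:] + right
            j5 = (c, p + 4 if dup else p, ins_start, "+")
            j3 = (c, p, ins_end, "+")
        else:
            read5 = reverse_complement(insert[:a5]) + right
            read3 = insert[b3:] + reverse_complement(left)
            j5 = (c, p, ins_start, "-")
            j3 = (c, p + 4 if dup else p, ins_end, "-")
        return read5, read3, j5, j3, a5, len(insert) - b3

    def _unambiguous(read, i_true, trunc):
        m_g = _longest_suffix_len(read, genome_texts)
        if len(read) - m_g != i_true:
            return False
        if trunc:
            k_p = _longest_prefix_len(read, donor_texts)
            if k_p - i_true >= trunc:
                return False
        return True

    events: list[SimulatedIntegration] = []
    index = 0
    class_order = [PROPER_TSD_TIR, PROPER_TSD_IMPROPER_TIR,
                   IMPROPER_TSD_PROPER_TIR, IMPROPER_BOTH]

    for klass, count in zip(class_order, counts):
        for _ in range(int(count)):
            dup = klass in (PROPER_TSD_TIR, PROPER_TSD_IMPROPER_TIR,
                            IMPROPER_TSD_PROPER_TIR)
            improper_tir = klass in (PROPER_TSD_IMPROPER_TIR, IMPROPER_BOTH)
            placed = False
            for _ in range(max_tries):
                orientation = "+" if rng.random() < 0.5 else "-"
                trunc = carry = 0
                if improper_tir:
                    if rng.random() < 0.5:
                        trunc = int(rng.integers(truncation_range[0],
                                                 truncation_range[1] + 1))
                    else:
                        carry = int(rng.integers(carryover_range[0],
                                                 carryover_range[1] + 1))
                ins_start = donor.tir5[0] + trunc - carry
                ins_end = donor.tir3[1] - trunc + carry

                if klass in (PROPER_TSD_TIR, PROPER_TSD_IMPROPER_TIR):
                    if not ttaa_pool:
                        raise RuntimeError("ran out of admissible TTAA sites")
                    j = int(rng.integers(len(ttaa_pool)))
                    c, p = ttaa_pool[j]
                    if not _free(c, p):
                        continue
                elif klass == IMPROPER_TSD_PROPER_TIR:
                    c, p = _random_site(
                        lambda s, q: s[q : q + 4] != tsd and "N" not in s[q - 4 : q + 8]
                    )
                else:
                    c, p = _random_site(
                        lambda s, q: s[q : q + 4] != tsd and s[q - 4 : q] != tsd
                        and "N" not in s[q - 4 : q + 8]
                    )

                r5, r3, j5, j3, i5, i3 = _build(c, p, dup, ins_start, ins_end,
                                                orientation)
                if improper_tir and not (
                    _unambiguous(r5, i5, trunc) and _unambiguous(r3, i3, trunc)
                ):
                    continue

                seq = genome.contigs[c]
                truth = TrueIntegration(
                    index=index, contig=c, position=p, orientation=orientation,
                    true_class=klass, tir_truncation=trunc,
                    backbone_carryover=carry, tsd_at_site=seq[p : p + 4],
                    duplicated=dup,
                )
                events.append(SimulatedIntegration(truth, r5, r3, j5, j3))
                used[c].append(p)
                if klass in (PROPER_TSD_TIR, PROPER_TSD_IMPROPER_TIR):
                    ttaa_pool = [(cc, qq) for cc, qq in ttaa_pool
                                 if not (cc == c and abs(qq - p) <= 8)]
                index += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place an unambiguous {klass} event "
                    f"after {max_tries} tries"
                )

    return events, [e.truth for e in events]


def simulate_reads(
    events: list[SimulatedIntegration],
    read_len: int = 250,
    per_event_depth: int = 3,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Junction reads per event end, as (name, sequence) pairs.

    Each read starts at the donor-side primer anchor and runs across the
    junction into chromosomal sequence. Errors are substitutions only,
    i.i.d. per base at ``substitution_rate``. Read names encode the event
    index and element end (``ev<i>|five_prime|<r>``).
    """
    rng = np.random.default_rng(seed)
    reads = []
    for ev in events:
        for end, template in (("five_prime", ev.read5_template),
                              ("three_prime", ev.read3_template)):
            if len(template) < read_len:
                raise ValueError("read_len exceeds the simulated junction window")
            base = template[:read_len]
            for r in range(per_event_depth):
                seq = base
                if substitution_rate > 0:
                    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                    hit = np.nonzero(rng.random(read_len) < substitution_rate)[0]
                    for i in hit:
                        choices = [b for b in b"ACGT" if b != arr[i]]
                        arr[i] = choices[int(rng.integers(3))]
                    seq = arr.tobytes().decode("ascii")
                reads.append((f"ev{ev.truth.index}|{end}|{r}", seq))
    return reads


# ---------------------------------------------------------------------------
# Peak / annotation interval sets
# ---------------------------------------------------------------------------


def make_interval_sets(
    genome_lengths: dict[str, int],
    n_peaks: int,
    peak_width,
    annotations: list[Interval],
    enrichment_fraction: float,
    seed: int = 0,
    background: str = "avoid",
    max_tries: int = 1000,
) -> tuple[list[Interval], list[Interval]]:
    """Place ``n_peaks`` peaks, a planted fraction overlapping annotations.

    Exactly ``ceil(enrichment_fraction * n_peaks)`` peaks overlap an
    annotation by >= 1 bp. The remainder are placed uniformly at random,
    rejecting annotation overlap when ``background="avoid"`` (so the
    observed overlap count equals the planted count exactly) or without
    rejection when ``background="uniform"`` (an honest random background,
    appropriate for null calibration).
    """
    if not 0 <= enrichment_fraction <= 1:
        raise ValueError("enrichment_fraction must be in [0, 1]")
    if background not in ("avoid", "uniform"):
        raise ValueError("background must be 'avoid' or 'uniform'")
    rng = np.random.default_rng(seed)
    names = list(genome_lengths)
    weights = np.array([genome_lengths[c] for c in names], float)
    weights /= weights.sum()
    by_contig: dict[str, list[Interval]] = {}
    for a in annotations:
        by_contig.setdefault(a.contig, []).append(a)

    def _width() -> int:
        if isinstance(peak_width, int):
            return peak_width
        lo, hi = peak_width
        return int(rng.integers(lo, hi + 1))

    n_enriched = math.ceil(enrichment_fraction * n_peaks)
    peaks: list[Interval] = []

    for i in range(n_enriched):
        placed = False
        for _ in range(max_tries):
            a = annotations[int(rng.integers(len(annotations)))]
            w = _width()
            L = genome_lengths[a.contig]
            lo = max(0, a.start - w + 1)
            hi = min(a.end - 1, L - w)
            if lo > hi:
                continue
            start = int(rng.integers(lo, hi + 1))
            peaks.append(Interval(a.contig, start, start + w, label=f"peak{i}"))
            placed = True
            break
        if not placed:
            raise ValueError("could not place an annotation-overlapping peak")

    for i in range(n_enriched, n_peaks):
        placed = False
        for _ in range(max_tries):
            c = names[rng.choice(len(names), p=weights)]
            w = _width()
            if genome_lengths[c] < w:
                continue
            start = int(rng.integers(0, genome_lengths[c] - w + 1))
            iv = Interval(c, start, start + w, label=f"peak{i}")
            if background == "avoid" and any(
                iv.overlaps(a) for a in by_contig.get(c, [])
            ):
                continue
            peaks.append(iv)
            placed = True
            break
        if not placed:
            raise ValueError(
                "annotations too dense to place a non-overlapping peak"
            )

    return peaks, annotations
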
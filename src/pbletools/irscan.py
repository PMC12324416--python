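"""Inverted-repeat, motif and tandem-run annotation.

Detects piggyBac-like inverted repeats (IRs): two arms of equal length whose
left arm equals the reverse complement of the right arm up to a small number
of mismatches, separated by a short spacer. Default parameters follow the
signature of subterminal/inner IRs of piggyBac-like transposon ends: arm
length 5-15 bp, spacer 2-10 bp, 0 mismatches for 5-bp arms and up to 1
mismatch for arms of 6 bp or more.

The scanner is exhaustive over (left start, arm length, spacer) triples and,
by default, reports for each (left start, spacer) locus only the longest
admissible arm ("maximal" mode); full enumeration is available with
``maximal=False`` and is what the brute-force oracle in the test suite
compares against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Interval, _validate_sequence, reverse_complement

# base codes: A C G T N -> 0 1 2 3 4; complement side maps N to 5 so that a
# position containing N can never match anything, including another N
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 5], dtype=np.uint8)


@dataclass(frozen=True)
class InvertedRepeat:
    """An arm pair + spacer on one contig. Coordinates 0-based half-open."""

    contig: str
    left_arm: Interval
    right_arm: Interval
    arm_len: int
    spacer_len: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.left_arm.end + self.spacer_len != self.right_arm.start:
            raise ValueError("left_arm.end + spacer_len must equal right_arm.start")
        if self.left_arm.length != self.right_arm.length != self.arm_len:
            raise ValueError("arm lengths inconsistent")


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr


def find_inverted_repeats(
    seq: str,
    min_arm: int = 5,
    max_arm: int = 15,
    min_spacer: int = 2,
    max_spacer: int = 10,
    max_mismatch: int = 1,
    mismatch_min_arm: int = 6,
    contig: str = ".",
    maximal: bool = True,
) -> list[InvertedRepeat]:
    """Exhaustively detect inverted repeats in ``seq``.

    An arm pair (left start ``i``, arm ``a``, spacer ``s``) is reported iff
    ``min_arm <= a <= max_arm``, ``min_spacer <= s <= max_spacer`` and the
    Hamming distance between the left arm and the reverse complement of the
    right arm is at most 0 for ``a < mismatch_min_arm`` and at most
    ``max_mismatch`` otherwise. Positions holding N never match. With
    ``maximal=True`` only the longest admissible arm per (``i``, ``s``) is
    kept. Output is sorted by (left start, arm length, spacer).
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 1 <= min_arm <= max_arm:
        raise ValueError("need 1 <= min_arm <= max_arm")
    if not 0 <= min_spacer <= max_spacer:
        raise ValueError("need 0 <= min_spacer <= max_spacer")

    seq = _validate_sequence(seq)
    x = _encode(seq)
    c = _COMP_CODE[x]
    L = len(seq)

    hits: list[tuple[int, int, int, int]] = []  # (i, arm, spacer, mismatches)
    # taken[s - min_spacer][i] marks (i, s) loci already claimed by a longer arm
    taken: list[np.ndarray] | None = None
    if maximal:
        taken = [np.zeros(L, dtype=bool) for _ in range(max_spacer - min_spacer + 1)]

    for a in range(min_arm, max_arm + 1)[::-1]:
        allowed = 0 if a < mismatch_min_arm else max_mismatch
        for s in range(min_spacer, max_spacer + 1):
            span = 2 * a + s
            n_pos = L - span + 1
            if n_pos <= 0:
                continue
            mm = np.zeros(n_pos, dtype=np.int16)
            for j in range(a):
                # pair j of the arms: seq[i+j] vs complement(seq[i + span-1-j])
                mm += x[j : j + n_pos] != c[span - 1 - j : span - 1 - j + n_pos]
            idx = np.nonzero(mm <= allowed)[0]
            if maximal and idx.size:
                mask = taken[s - min_spacer]
                idx = idx[~mask[idx]]
                mask[idx] = True
            for i in idx:
                hits.append((int(i), a, s, int(mm[i])))

    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    out = []
    for i, a, s, m in hits:
        out.append(
            InvertedRepeat(
                contig=contig,
                left_arm=Interval(contig, i, i + a, label="ir_arm"),
                right_arm=Interval(contig, i + a + s, i + 2 * a + s, label="ir_arm"),
                arm_len=a,
                spacer_len=s,
                mismatches=m,
            )
        )
    return out


def inverted_repeats_to_intervals(irs: list[InvertedRepeat]) -> list[Interval]:
    """Full IR footprints (left arm start to right arm end) as intervals."""
    return [
        Interval(
            ir.contig,
            ir.left_arm.start,
            ir.right_arm.end,
            label=f"ir_arm{ir.arm_len}_sp{ir.spacer_len}_mm{ir.mismatches}",
            score=float(ir.mismatches),
        )
        for ir in irs
    ]


@dataclass(frozen=True)
class MotifCount:
    motif: str
    contig: str
    count: int
    strands: str  # "+" or "+/-"


def count_motif_nonoverlapping(
    seq: str, motif: str, both_strands: bool = False, contig: str = "."
) -> MotifCount:
    """Count exact, non-overlapping motif occurrences by greedy left-to-right scan.

    After a match at position ``i`` the scan resumes at ``i + len(motif)``
    (leftmost-first tie-break). With ``both_strands`` the reverse complement
    of the motif is counted in a second, independent scan and the counts are
    summed.
    """
    if not motif:
        raise ValueError("empty motif")
    motif = _validate_sequence(motif, name="motif")
    if "N" in motif:
        raise ValueError("motif must be over A/C/G/T")
    seq = _validate_sequence(seq)

    def _scan(m: str) -> int:
        count = 0
        i = seq.find(m)
        while i != -1:
            count += 1
            i = seq.find(m, i + len(m))
        return count

    total = _scan(motif)
    if both_strands:
        total += _scan(reverse_complement(motif))
    return MotifCount(motif=motif, contig=contig, count=total,
                      strands="+/-" if both_strands else "+")


def find_tandem_runs(
    seq: str, unit: str, min_copies: int, contig: str = "."
) -> list[Interval]:
    """Maximal runs of >= ``min_copies`` exact head-to-tail copies of ``unit``.

    Runs are reported with the copy count in ``score``. A run is maximal in
    the sense that it cannot be extended by a full unit on either side; the
    scan is greedy left-to-right, so for self-overlapping units phase-shifted
    sub-runs inside a reported run are not re-reported.
    """
    if len(unit) < 2:
        raise ValueError("unit length must be >= 2")
    unit = _validate_sequence(unit, name="unit")
    seq = _validate_sequence(seq)
    u = len(unit)
    runs = []
    i = 0
    L = len(seq)
    while i <= L - u * min_copies:
        if seq[i : i + u] == unit:
            c = 1
            while seq[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            if c >= min_copies:
                runs.append(
                    Interval(contig, i, i + c * u, label=f"({unit})n", score=float(c))
                )
                i += c * u
            else:
                i += 1
        else:
            i += 1
    return runs


def annotate_donor_ends(
    donor,
    min_arm: int = 5,
    max_arm: int = 15,
    max_mismatch: int = 1,
    mismatch_min_arm: int = 6,
    min_spacer: int = 2,
    max_spacer: int | None = None,
) -> list[InvertedRepeat]:
    """IRs of a donor construct whose arms fall within its subterminal blocks.

    Subterminal IRs may pair across the whole element (one arm per end), so
    the spacer range defaults to everything up to the distance spanned by the
    two subterminal blocks. Coordinates are on the full construct sequence.
    """
    lo = donor.sub5[0]
    hi = donor.sub3[1]
    region = donor.sequence[lo:hi]
    if max_spacer is None:
        max_spacer = len(region) - 2 * min_arm
    irs = find_inverted_repeats(
        region,
        min_arm=min_arm,
        max_arm=max_arm,
        min_spacer=min_spacer,
        max_spacer=max_spacer,
        max_mismatch=max_mismatch,
        mismatch_min_arm=mismatch_min_arm,
        contig=donor.name,
    )

    def _in_blocks(start: int, end: int) -> bool:
        for b0, b1 in (donor.sub5, donor.sub3):
            if b0 <= start and end <= b1:
                return True
        return False

    out = []
    for ir in irs:
        la = Interval(donor.name, ir.left_arm.start + lo, ir.left_arm.end + lo,
                      label="ir_arm")
        ra = Interval(donor.name, ir.right_arm.start + lo, ir.right_arm.end + lo,
                      label="ir_arm")
        if _in_blocks(la.start, la.end) and _in_blocks(ra.start, ra.end):
            out.append(
                InvertedRepeat(donor.name, la, ra, ir.arm_len, ir.spacer_len,
                               ir.mismatches)
            )
    return out
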
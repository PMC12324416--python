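"""Independent brute-force oracles used to cross-check the fast scanners."""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_inverted_repeats(
    seq,
    min_arm=5,
    max_arm=15,
    min_spacer=2,
    max_spacer=10,
    max_mismatch=1,
    mismatch_min_arm=6,
    maximal=True,
):
    """Enumerate every (left start, arm, spacer) triple and check the
    Hamming condition directly; with ``maximal`` keep only the longest
    admissible arm per (left start, spacer). Returns (i, arm, spacer, mm)
    tuples sorted like the production scanner's output."""
    L = len(seq)
    results = []
    for i in range(L):
        for s in range(min_spacer, max_spacer + 1):
            best = None
            for a in range(min_arm, max_arm + 1):
                if i + 2 * a + s > L:
                    break
                left = seq[i : i + a]
                right = seq[i + a + s : i + 2 * a + s]
                mm = 0
                for x, y in zip(left, reversed(right)):
                    if x == "N" or y == "N" or _COMP[y] != x:
                        mm += 1
                allowed = 0 if a < mismatch_min_arm else max_mismatch
                if mm <= allowed:
                    if maximal:
                        best = (a, mm)
                    else:
                        results.append((i, a, s, mm))
            if maximal and best is not None:
                results.append((i, best[0], s, best[1]))
    return sorted(results, key=lambda t: (t[0], t[1], t[2]))


def brute_force_overlap_count(query, annotations):
    """Quadratic pair check: queries overlapping >= 1 annotation by >= 1 bp."""
    count = 0
    for q in query:
        for a in annotations:
            if q.contig == a.contig and q.start < a.end and a.start < q.end:
                count += 1
                break
    return count


def ir_tuples(irs):
    """Map production InvertedRepeat objects onto oracle tuples."""
    return sorted(
        (ir.left_arm.start, ir.arm_len, ir.spacer_len, ir.mismatches)
        for ir in irs
    )
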
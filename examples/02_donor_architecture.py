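"""Build donor constructs and verify their pble end architecture.

A donor carries a selectable cassette between two pble ends: 13-bp
terminal inverted repeats (TIRs) flanked by the TTAA target motif and
100-bp plasmid-backbone regions, with subterminal IR blocks just inside
the TIRs. The `ifp2_like` template plants a 19-bp subterminal arm pair at
3 bp (5' side) and 31 bp (3' side) from the TIR inner ends; scanning the
construct with max_arm >= 19 must recover it.
"""

import pbletools as pt

for template in ("ifp2_like", "mer75b_like", "plain"):
    donor = pt.make_donor(template, cassette_len=1000, seed=1)
    irs = pt.annotate_donor_ends(donor, max_arm=19)
    planted = [
        ir for ir in irs
        if ir.arm_len == 19 and ir.mismatches == 0
        and ir.left_arm.start >= donor.tir5[1]
        and ir.right_arm.end <= donor.tir3[0]
        and ir.left_arm.start - donor.tir5[1] <= 5
    ]
    line = f"{template:12s} construct {len(donor.sequence)} bp, " \
           f"{len(irs)} subterminal IRs"
    if planted:
        ir = planted[0]
        line += (f"; planted 19-bp arm pair at offsets "
                 f"{ir.left_arm.start - donor.tir5[1]} and "
                 f"{donor.tir3[0] - ir.right_arm.end} from the TIR inner ends")
    print(line)
# ifp2_like reports the pair at offsets 3 and 31; mer75b_like has its
# planted IR at the 5' end only; plain shows only chance IRs.
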
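"""Align UHP pairs and score their substitutions with the McLachlan matrix.

Shows the column classification (conserved / changed / gapped), the pooled
mean McLachlan score over changed columns against the matrix background,
and the per-amino-acid gain profile.

Run:  python examples/02_align_uhp_pairs.py
"""

from uhpscan import (
    aa_gain_profile,
    align_uhp,
    load_mclachlan,
    matrix_background_mean,
    mclachlan_stats,
)

pairs = [
    ("ev1", "MKTAYIAKQRQISFVK", "MKTAFIAKERQLSFVK"),
    ("ev2", "GDSLLWHEKQ", "GDSLIWHEQ"),
    ("ev3", "PPNARTVGSW", "PPNARTVGSW"),
]

matrix = load_mclachlan()
alignments = [align_uhp(a, b, eid) for eid, a, b in pairs]

for aln in alignments:
    top = "".join(c.residue_a for c in aln.columns)
    bottom = "".join(c.residue_b for c in aln.columns)
    marks = "".join(
        {"conserved": "|", "changed": ".", "gapped": " "}[c.status]
        for c in aln.columns
    )
    print(f"{aln.event_id}  score={aln.score:.1f}  "
          f"conserved={aln.n_conserved} changed={aln.n_changed} "
          f"gapped={aln.n_gapped}")
    print(f"  {top}\n  {marks}\n  {bottom}\n")

pooled, per_event = mclachlan_stats(alignments, matrix)
print(f"pooled mean over changed columns : {pooled:.2f}")
print(f"matrix background (190 pairs)    : "
      f"{matrix_background_mean(matrix):.2f}")

gain = aa_gain_profile(alignments, matrix)
print("\nper-amino-acid gain (observed substitution score - background):")
for aa, value in sorted(gain.gain.items()):
    print(f"  {aa}: {value:+.2f}")
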
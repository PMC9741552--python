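"""Ligand-binding residue overlap and conservation within UHP regions.

Constructs residue annotations for a toy protein set with UHP regions,
plants binding residues depleted inside the UHP regions, and runs both
the depletion test and the binding-column conservation contrast.

Run:  python examples/04_binding_overlap.py
"""

import numpy as np

from uhpscan import align_uhp, binding_conservation, overlap_stats
from uhpscan.structure import ResidueAnnotation

rng = np.random.default_rng(3)

annotations, binding_rows = [], []
for p in range(25):
    pid = f"p{p}"
    for pos in range(1, 51):
        side = "A" if pos <= 12 else "none"
        annotations.append(
            ResidueAnnotation(pid, pos, "A", 92.0, False, 60.0, 0.5,
                              True, "helix", side)
        )
        rate = 0.02 if side == "A" else 0.12  # planted depletion in UHPs
        if rng.random() < rate:
            binding_rows.append((pid, pos, "LIG"))

stats = overlap_stats(binding_rows, annotations)
print(f"residues inside UHP regions : {stats.uhp_residue_fraction}%")
print(f"binding residues inside UHPs: {stats.uhp_binding_fraction}%")
print(f"2x2 table (binding/other x in/out): {stats.table}")
print(f"odds ratio = {stats.odds_ratio:.2f}, Fisher p = {stats.fisher_p:.2e}\n")

# conservation of the binding columns between the two UHP sides
alignments = [
    align_uhp("MKTAYIAKQRQISF", "MKTAFIAKERQLSF", "ev1"),
    align_uhp("GDSLLWHEKQPLVN", "GDSLIWHEKQPIVN", "ev2"),
]
flags = {("ev1", 1): True, ("ev1", 5): True, ("ev2", 4): True}
cons = binding_conservation(flags, alignments)
print(f"binding columns conserved : {cons.binding_conserved_fraction:.2f}")
print(f"other columns conserved   : {cons.other_conserved_fraction:.2f}")
print(f"Fisher p = {cons.fisher_p:.3f}")
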
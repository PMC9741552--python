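"""Overlap and conservation of predicted ligand-binding residues.

Binding-residue predictions (in the style of firestar output) are consumed
as a table of (protein_id, position, ligand); the analyses ask whether UHP
regions are depleted of binding residues relative to the rest of the same
proteins, and whether binding residues that do fall inside a UHP region
are preferentially conserved between the two sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import CONSERVED, UHPAlignment
from .stats import fisher_two_sided, percent

__all__ = [
    "load_binding_table",
    "OverlapStats",
    "overlap_stats",
    "BindingConservation",
    "binding_conservation",
]


def load_binding_table(rows) -> pd.DataFrame:
    """Normalise a binding-residue table: columns protein_id, position,
    ligand; duplicate (protein, position) rows collapsed."""
    df = pd.DataFrame(rows, columns=["protein_id", "position", "ligand"])
    df["position"] = df["position"].astype(int)
    if (df["position"] < 1).any():
        raise ValueError("binding positions are 1-based and must be >= 1")
    return df.drop_duplicates(subset=["protein_id", "position"]).reset_index(drop=True)


@dataclass
class OverlapStats:
    uhp_residue_fraction: float  # % of residues (1 d.p.) inside UHP regions
    uhp_binding_fraction: float  # % of binding residues inside UHP regions
    table: tuple  # ((binding_in, binding_out), (nonbinding_in, nonbinding_out))
    odds_ratio: float
    fisher_p: float


def overlap_stats(binding: pd.DataFrame, annotations) -> OverlapStats | None:
    """Depletion test of binding residues within UHP regions.

    ``annotations`` is an iterable of ResidueAnnotation restricted to the
    proteins of interest; only proteins present in the binding table are
    counted.  Returns None when there are no binding residues (an absent
    result, not zero)."""
    binding = load_binding_table(binding)
    if binding.empty:
        return None
    proteins = set(binding["protein_id"])
    binding_pos = {(r.protein_id, r.position) for r in binding.itertuples()}
    b_in = b_out = n_in = n_out = 0
    for a in annotations:
        if a.protein_id not in proteins:
            continue
        in_uhp = a.uhp_side in ("A", "B")
        is_binding = (a.protein_id, a.position) in binding_pos
        if is_binding and in_uhp:
            b_in += 1
        elif is_binding:
            b_out += 1
        elif in_uhp:
            n_in += 1
        else:
            n_out += 1
    total = b_in + b_out + n_in + n_out
    n_binding = b_in + b_out
    if n_binding == 0 or total == 0:
        return None
    table = ((b_in, b_out), (n_in, n_out))
    odds, p = fisher_two_sided(table)
    return OverlapStats(
        uhp_residue_fraction=percent(b_in + n_in, total),
        uhp_binding_fraction=percent(b_in, n_binding),
        table=table,
        odds_ratio=odds,
        fisher_p=p,
    )


@dataclass
class BindingConservation:
    binding_conserved_fraction: float | None  # over binding columns, 0-1
    other_conserved_fraction: float | None  # over non-binding columns, same events
    table: tuple
    fisher_p: float | None


def binding_conservation(
    binding_columns: dict,
    alignments: list[UHPAlignment],
) -> BindingConservation:
    """Conservation contrast between binding and non-binding UHP columns.

    ``binding_columns`` maps (event_id, side-A UHP position 1-based) to True
    for positions holding a predicted binding residue; only events that
    appear as keys (i.e. proteins with binding predictions) enter the
    non-binding background.  A binding residue aligned to a gap counts as
    not maintained."""
    events_with_binding = {e for (e, _p) in binding_columns}
    b_cons = b_tot = o_cons = o_tot = 0
    for aln in alignments:
        if aln.event_id not in events_with_binding:
            continue
        pos = 0
        for col in aln.columns:
            if col.residue_a == "-":
                continue
            pos += 1
            conserved = col.status == CONSERVED
            if binding_columns.get((aln.event_id, pos), False):
                b_tot += 1
                b_cons += conserved
            else:
                o_tot += 1
                o_cons += conserved
    table = ((b_cons, b_tot - b_cons), (o_cons, o_tot - o_cons))
    if b_tot == 0:
        return BindingConservation(None, o_cons / o_tot if o_tot else None, table, None)
    _, p = fisher_two_sided(table)
    return BindingConservation(
        binding_conserved_fraction=b_cons / b_tot,
        other_conserved_fraction=o_cons / o_tot if o_tot else None,
        table=table,
        fisher_p=p,
    )
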
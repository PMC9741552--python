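"""Pairwise alignment of UHP region pairs and substitution statistics.

The two sides of a tandem duplicated exon substitution event are homologous
end-to-end, so they are aligned globally (Needleman-Wunsch, BLOSUM62,
affine gap open 10 / extend 1).  Conservation statistics are then computed
with the McLachlan (1972) similarity matrix, which scores every amino-acid
pair 0-9: the mean McLachlan score of *changed* alignment columns measures
how conservative the substitutions between the two isoforms are, and is
compared against the matrix-wide background mean over the 190 non-identical
amino-acid pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AlignmentColumn",
    "UHPAlignment",
    "AAGainProfile",
    "load_mclachlan",
    "align_uhp",
    "mclachlan_stats",
    "matrix_background_mean",
    "aa_gain_profile",
    "conservation_by_category",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"X"}

CONSERVED, CHANGED, GAPPED = "conserved", "changed", "gapped"


@dataclass(frozen=True)
class AlignmentColumn:
    residue_a: str  # '-' for a gap
    residue_b: str
    status: str


@dataclass
class UHPAlignment:
    event_id: str
    columns: list[AlignmentColumn]
    score: float = 0.0

    @property
    def n_conserved(self) -> int:
        return sum(c.status == CONSERVED for c in self.columns)

    @property
    def n_changed(self) -> int:
        return sum(c.status == CHANGED for c in self.columns)

    @property
    def n_gapped(self) -> int:
        return sum(c.status == GAPPED for c in self.columns)

    def changed_scores(self, matrix) -> list[float]:
        """McLachlan scores of changed columns (X-containing columns have no
        defined score and are skipped)."""
        out = []
        for c in self.columns:
            if c.status == CHANGED and "X" not in (c.residue_a, c.residue_b):
                out.append(float(matrix[c.residue_a][c.residue_b]))
        return out

    def mean_changed_score(self, matrix) -> float | None:
        scores = self.changed_scores(matrix)
        return float(np.mean(scores)) if scores else None


@dataclass
class AAGainProfile:
    """Per-amino-acid substitution gain.

    gain(a) = mean McLachlan score of a's observed substitutions minus a's
    mean matrix score against the other 19 amino acids.  Amino acids with no
    observed substitution are absent."""

    observed_mean: dict = field(default_factory=dict)
    background_mean: dict = field(default_factory=dict)
    gain: dict = field(default_factory=dict)
    n_obs: dict = field(default_factory=dict)


def load_mclachlan():
    """The McLachlan (1972) matrix shipped with the package."""
    path = resources.files("uhpscan.data") / "mclachlan.mat"
    with resources.as_file(path) as p:
        return substitution_matrices.read(str(p))


def _global_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    return al


def align_uhp(uhp_a: str, uhp_b: str, event_id: str = "") -> UHPAlignment:
    """Globally align the two UHP sides and assign per-column statuses.

    conserved = identical residues, both present (X never counts as
    conserved); gapped = exactly one side is a gap; changed otherwise.
    Ties between equally scoring alignments are broken deterministically by
    taking the aligner's first reported alignment.
    """
    if not uhp_a or not uhp_b:
        raise ValueError("empty UHP sequence")
    for seq, name in ((uhp_a, "uhp_a"), (uhp_b, "uhp_b")):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {name}")
    al = _global_aligner()
    alns = al.align(uhp_a, uhp_b)
    best = alns[0]
    ga, gb = best[0], best[1]
    columns = []
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            status = GAPPED
        elif x == y and x != "X":
            status = CONSERVED
        else:
            status = CHANGED
        columns.append(AlignmentColumn(x, y, status))
    return UHPAlignment(event_id=event_id, columns=columns, score=float(alns.score))


def mclachlan_stats(
    alignments: list[UHPAlignment],
    matrix=None,
    event_weighted: bool = False,
) -> tuple[float | None, dict]:
    """Mean McLachlan score over changed columns, pooled across events.

    The default pools columns (every changed column weighs equally); the
    ``event_weighted`` alternative averages per-event means instead.
    Returns (pooled_mean, per_event_means); pooled_mean is None when no
    changed column exists."""
    matrix = matrix if matrix is not None else load_mclachlan()
    per_event = {a.event_id: a.mean_changed_score(matrix) for a in alignments}
    all_scores = [s for a in alignments for s in a.changed_scores(matrix)]
    if not all_scores:
        return None, per_event
    if event_weighted:
        means = [m for m in per_event.values() if m is not None]
        return float(np.mean(means)), per_event
    return float(np.mean(all_scores)), per_event


def matrix_background_mean(matrix=None, include_diagonal: bool = False) -> float:
    """Unweighted mean of the matrix over unordered amino-acid pairs.

    By default the 190 non-identical pairs (a substitution implies a != b);
    ``include_diagonal`` adds the 20 identity scores for sensitivity
    analysis."""
    matrix = matrix if matrix is not None else load_mclachlan()
    vals = []
    for i, a in enumerate(AMINO_ACIDS):
        for b in AMINO_ACIDS[i:] if include_diagonal else AMINO_ACIDS[i + 1 :]:
            vals.append(float(matrix[a][b]))
    return float(np.mean(vals))


def aa_gain_profile(
    alignments: list[UHPAlignment],
    matrix=None,
    side: str = "A",
) -> AAGainProfile:
    """Per-amino-acid gain over the matrix background.

    The amino acid attributed to each changed column is taken from the
    configured side (side A by convention — the side mapped onto the
    structural model)."""
    matrix = matrix if matrix is not None else load_mclachlan()
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    obs: dict[str, list[float]] = {}
    for aln in alignments:
        for col in aln.columns:
            if col.status != CHANGED:
                continue
            a = col.residue_a if side == "A" else col.residue_b
            b = col.residue_b if side == "A" else col.residue_a
            if "X" in (a, b):
                continue
            obs.setdefault(a, []).append(float(matrix[a][b]))
    profile = AAGainProfile()
    for a, scores in sorted(obs.items()):
        bg = float(np.mean([matrix[a][b] for b in AMINO_ACIDS if b != a]))
        profile.observed_mean[a] = float(np.mean(scores))
        profile.background_mean[a] = bg
        profile.gain[a] = profile.observed_mean[a] - bg
        profile.n_obs[a] = len(scores)
    return profile


def conservation_by_category(
    alignments: list[UHPAlignment],
    residue_flags: dict,
) -> dict:
    """Conserved/changed/gapped fractions per residue category.

    ``residue_flags`` maps (event_id, side-A position) — 1-based within the
    UHP — to an iterable of category labels (e.g. {'binding'},
    {'disordered'}).  Unflagged side-A residues fall in category 'none'.
    Categories may overlap.  Fractions are over side-A residues (columns
    where side A is not a gap).  A flag for a position beyond the side-A
    length is an error."""
    lengths = {}
    status_at: dict[tuple[str, int], str] = {}
    for aln in alignments:
        pos = 0
        for col in aln.columns:
            if col.residue_a != "-":
                pos += 1
                status_at[(aln.event_id, pos)] = col.status
        lengths[aln.event_id] = pos
    for (event_id, pos) in residue_flags:
        if event_id not in lengths:
            raise KeyError(f"flag references unknown event {event_id}")
        if not 1 <= pos <= lengths[event_id]:
            raise ValueError(
                f"flagged position {pos} outside UHP of event {event_id}"
            )
    tallies: dict[str, dict[str, int]] = {}
    for key, status in status_at.items():
        cats = set(residue_flags.get(key) or ())
        if not cats:
            cats = {"none"}
        for cat in cats:
            t = tallies.setdefault(cat, {CONSERVED: 0, CHANGED: 0, GAPPED: 0})
            t[status] += 1
    out = {}
    for cat, t in tallies.items():
        n = sum(t.values())
        out[cat] = {
            "n": n,
            CONSERVED: t[CONSERVED] / n,
            CHANGED: t[CHANGED] / n,
            GAPPED: t[GAPPED] / n,
        }
    return out
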
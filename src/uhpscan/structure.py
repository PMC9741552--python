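"""Per-residue structural features from predicted models.

Models are read from PDB or mmCIF with the per-residue confidence (pLDDT,
0-100) stored in the B-factor column, as AlphaFold writes it.  Features:

* disorder — a residue is disordered iff it lies in a run of >= 3
  consecutive residues with pLDDT <= 50;
* solvent accessibility — Shrake-Rupley ASA (probe 1.4 A, 960 points per
  atom) normalised by the Tien et al. (2013) theoretical maximum ASA to
  give RSA in [0,1]; a residue is exposed iff RSA >= 0.2;
* secondary structure — an 8-state DSSP string collapsed to
  helix (H,G,I) / strand (E,B) / coil, or a dihedral-based fallback
  assignment computed from backbone coordinates.

The exposure contingency contrasts exposed/buried counts inside and
outside UHP regions with a chi-squared test (disordered residues are
removed first, since their coordinates are not meaningful).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.SASA import ShrakeRupley

from .stats import chi2_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "ResidueAnnotation",
    "ExposureContingency",
    "UHPMapping",
    "MAX_ASA",
    "read_model",
    "read_chunked_model",
    "call_disorder",
    "compute_sasa",
    "collapse_ss8",
    "assign_ss3_from_coords",
    "resolve_uhp_in_model",
    "exposure_contingency",
]

PLDDT_CUTOFF = 50.0
MIN_DISORDER_RUN = 3
RSA_CUTOFF = 0.2

# Tien et al. (2013) theoretical maximum ASA (A^2), used to normalise
# per-residue ASA into relative solvent accessibility
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
}


@dataclass
class Residue:
    position: int  # 1-based index in the display isoform
    aa: str
    plddt: float
    coords: dict  # atom name -> np.ndarray(3), backbone + side chain


@dataclass
class ResidueAnnotation:
    protein_id: str
    position: int
    aa: str
    plddt: float
    disordered: bool
    asa: float
    rsa: float
    exposed: bool
    ss3: str
    uhp_side: str  # 'A', 'B' or 'none'
    binding: bool = False


@dataclass
class ExposureContingency:
    table: np.ndarray  # rows exposed/buried x cols in-UHP/not-in-UHP
    chi2: float
    p: float


@dataclass
class UHPMapping:
    side: str | None  # 'A' or 'B', None when excluded
    start: int | None  # 1-based position of the UHP in the display protein
    end: int | None
    reason: str | None = None  # exclusion reason when side is None


def _parse(path: str):
    path = str(path)
    if path.endswith((".cif", ".mmcif")):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    return parser.get_structure("model", path)


def read_model(path: str) -> list[Residue]:
    """Read a single-chain model; pLDDT is the CA atom's B-factor.

    Residues without a CA atom are skipped with a warning."""
    structure = _parse(path)
    model = next(structure.get_models())
    chain = next(model.get_chains())
    out = []
    for res in chain.get_residues():
        if res.id[0].strip():
            continue  # hetero/water
        name = res.get_resname()
        aa = THREE_TO_ONE.get(name, "X")
        if "CA" not in res:
            logger.warning("residue %s%d lacks CA; skipped", name, res.id[1])
            continue
        coords = {atom.get_name(): atom.coord.copy() for atom in res}
        out.append(
            Residue(
                position=res.id[1],
                aa=aa,
                plddt=float(res["CA"].get_bfactor()),
                coords=coords,
            )
        )
    return out


def read_chunked_model(manifest: list[tuple[str, int]]) -> list[Residue]:
    """Merge chunked model files covering one long protein.

    ``manifest`` rows are (path, start_offset) with start_offset the 1-based
    display-protein position of the chunk's first residue.  Where chunks
    overlap, the earlier file wins."""
    merged: dict[int, Residue] = {}
    for path, start in manifest:
        residues = read_model(path)
        if not residues:
            continue
        base = residues[0].position
        for r in residues:
            pos = start + (r.position - base)
            if pos not in merged:
                merged[pos] = Residue(pos, r.aa, r.plddt, r.coords)
    return [merged[p] for p in sorted(merged)]


def call_disorder(plddt_series) -> np.ndarray:
    """Boolean disorder mask: True inside maximal runs of >= 3 consecutive
    residues with pLDDT <= 50 (boundary inclusive)."""
    arr = np.asarray(plddt_series, dtype=float)
    low = arr <= PLDDT_CUTOFF
    out = np.zeros_like(low)
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= MIN_DISORDER_RUN:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


_DEFAULT_RADIUS = 2.0


def _as_biopdb_chain(residues: list[Residue]):
    """Build a Bio.PDB chain from Residue records (works for synthetic
    backbone-only models as well as parsed files)."""
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("m")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    for res in residues:
        sb.init_residue(one_to_three.get(res.aa, "UNK"), " ", res.position, " ")
        for name, xyz in res.coords.items():
            elem = name.strip()[0].upper()
            sb.init_atom(
                name, np.asarray(xyz, dtype=float), res.plddt, 1.0, " ",
                name.center(4), element=elem,
            )
    return sb.get_structure()


def compute_sasa(
    residues: list[Residue],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley ASA (A^2) per residue (probe 1.4 A, 960 sphere points
    per atom by default; deterministic given n_points).

    Unknown elements fall back to a default van der Waals radius with a
    warning."""
    from Bio.PDB.SASA import ATOMIC_RADII

    elements = {
        name.strip()[0].upper() for res in residues for name in res.coords
    }
    radii = dict(ATOMIC_RADII)
    for elem in elements:
        if elem not in radii:
            warnings.warn(f"unknown element {elem!r}; default radius used")
            radii[elem] = _DEFAULT_RADIUS
    structure = _as_biopdb_chain(residues)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points, radii_dict=radii)
    sr.compute(structure, level="R")
    chain = next(next(structure.get_models()).get_chains())
    by_pos = {r.id[1]: float(r.sasa) for r in chain.get_residues()}
    return np.array([by_pos[res.position] for res in residues])


def rsa_from_asa(asa: float, aa: str) -> float:
    """Relative solvent accessibility, clipped to [0,1]."""
    max_asa = MAX_ASA.get(aa)
    if max_asa is None:
        return float("nan")
    return float(min(1.0, max(0.0, asa / max_asa)))


def collapse_ss8(ss8: str) -> list[str]:
    """Collapse an 8-state secondary-structure string to 3 states."""
    return [SS8_TO_SS3.get(c, "coil") for c in ss8]


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def assign_ss3_from_coords(residues: list[Residue]) -> list[str]:
    """Dihedral-based fallback secondary-structure assignment.

    phi/psi are computed from backbone N, CA, C coordinates; residues in
    the alpha region are helix, in the beta region strand, all else
    (including chain termini) coil."""
    out = []
    n = len(residues)
    for i, res in enumerate(residues):
        phi = psi = None
        try:
            if i > 0:
                phi = _dihedral(
                    residues[i - 1].coords["C"], res.coords["N"],
                    res.coords["CA"], res.coords["C"],
                )
            if i < n - 1:
                psi = _dihedral(
                    res.coords["N"], res.coords["CA"],
                    res.coords["C"], residues[i + 1].coords["N"],
                )
        except KeyError:
            pass
        if phi is None or psi is None:
            out.append("coil")
        elif -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
            out.append("helix")
        elif -180.0 <= phi <= -90.0 and (psi >= 90.0 or psi <= -150.0):
            out.append("strand")
        else:
            out.append("coil")
    return out


def _hamming_window_find(haystack: str, needle: str, max_mismatch: int) -> int | None:
    best = None
    for i in range(len(haystack) - len(needle) + 1):
        mm = sum(a != b for a, b in zip(haystack[i : i + len(needle)], needle))
        if mm <= max_mismatch:
            if best is None:
                best = i
    return best


def resolve_uhp_in_model(
    uhp_a: str,
    uhp_b: str,
    display_protein: str,
    plddt: np.ndarray | None = None,
    max_mismatch: int = 2,
) -> UHPMapping:
    """Map one UHP side onto the display isoform modelled by the structure.

    The display isoform carries at most one of the two sides.  If it
    contains exactly one, that side is mapped.  If it contains both
    (overlapping annotation), the side with the lower disordered-residue
    fraction is kept — the other side is only disordered because it does
    not belong in the principal isoform.  If it contains neither (exact
    match first, then <= 2 mismatches), the event is excluded with a
    reason code."""
    def locate(seq: str) -> int | None:
        idx = display_protein.find(seq)
        if idx >= 0:
            return idx
        return _hamming_window_find(display_protein, seq, max_mismatch)

    pos_a = locate(uhp_a) if uhp_a else None
    pos_b = locate(uhp_b) if uhp_b else None
    if pos_a is None and pos_b is None:
        return UHPMapping(None, None, None, reason="uhp_not_in_display")
    if pos_a is not None and pos_b is not None:
        if plddt is None:
            keep = "A"
        else:
            dis = call_disorder(plddt)
            frac_a = dis[pos_a : pos_a + len(uhp_a)].mean()
            frac_b = dis[pos_b : pos_b + len(uhp_b)].mean()
            keep = "A" if frac_a <= frac_b else "B"
    else:
        keep = "A" if pos_a is not None else "B"
    pos, seq = (pos_a, uhp_a) if keep == "A" else (pos_b, uhp_b)
    return UHPMapping(keep, pos + 1, pos + len(seq))


def exposure_contingency(annotations: list[ResidueAnnotation]) -> ExposureContingency:
    """Exposed/buried vs in-UHP/out-of-UHP chi-squared contrast.

    Disordered residues are removed before counting; their coordinates (and
    hence their computed accessibility) are not physically meaningful."""
    kept = [a for a in annotations if not a.disordered]
    table = np.zeros((2, 2), dtype=int)
    for a in kept:
        row = 0 if a.exposed else 1
        col = 0 if a.uhp_side in ("A", "B") else 1
        table[row, col] += 1
    chi2, p = chi2_2x2(table)
    return ExposureContingency(table=table, chi2=chi2, p=p)


def rsa_distributions(annotations: list[ResidueAnnotation]) -> dict:
    """Per-class RSA value lists, stratified by secondary structure, for
    non-disordered residues inside and outside UHP regions."""
    out: dict[str, list[float]] = {}
    for a in annotations:
        if a.disordered:
            continue
        region = "uhp" if a.uhp_side in ("A", "B") else "background"
        out.setdefault(f"{region}:{a.ss3}", []).append(a.rsa)
    return out
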
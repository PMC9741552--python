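"""Peptide-level evidence for tissue-specific expression of UHP sides.

The module's contract begins at a peptide evidence table (peptide sequence,
posterior error probability, experiment id, tissue) distilled from
search-engine output.  Records are filtered (PEP <= 0.001, fully tryptic
with at most one missed cleavage, gene-unique, detected in >= 2 distinct
experiments), peptides are assigned to the UHP side whose isoforms they
discriminate, and per-(event, side, tissue) peptide experiment counts
(PECs) feed Fisher's exact tests of tissue specificity.  A PEC is the
number of distinct experiments in which a discriminating peptide was
detected, summed over the side's peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .stats import fisher_two_sided

__all__ = [
    "PEP_CUTOFF",
    "MIN_PEC",
    "PeptideSpan",
    "tryptic_digest",
    "filter_evidence",
    "discriminating_peptides",
    "compute_pec",
    "TissueSpecificityResult",
    "tissue_specificity",
]

PEP_CUTOFF = 0.001
MIN_PEC = 3
MIN_PEPTIDE_LEN = 7


@dataclass(frozen=True)
class PeptideSpan:
    sequence: str
    start: int  # 0-based within the parent protein
    end: int  # exclusive
    missed: int


def _cleavage_sites(protein: str) -> list[int]:
    """0-based positions after which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def tryptic_digest(
    protein: str, max_missed: int = 1, min_len: int = MIN_PEPTIDE_LEN
) -> list[PeptideSpan]:
    """Fully tryptic peptides with 0..max_missed missed cleavages.

    Cleavage after K or R except before P; peptide boundaries are the
    protein termini and cleavage sites."""
    if not protein:
        raise ValueError("empty protein")
    sites = _cleavage_sites(protein)
    bounds = [0] + [s + 1 for s in sites] + [len(protein)]
    out = []
    for i in range(len(bounds) - 1):
        for miss in range(max_missed + 1):
            j = i + 1 + miss
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            if end - start >= min_len:
                out.append(PeptideSpan(protein[start:end], start, end, miss))
    return out


def _norm(seq: str, equate_il: bool) -> str:
    return seq.replace("I", "L") if equate_il else seq


def _is_tryptic_in(peptide: str, protein: str, max_missed: int) -> bool:
    """True iff the peptide occurs in the protein as a fully tryptic
    fragment with at most max_missed missed cleavages."""
    sites = set(_cleavage_sites(protein))
    start = protein.find(peptide)
    while start >= 0:
        end = start + len(peptide)
        left_ok = start == 0 or (start - 1) in sites
        right_ok = end == len(protein) or (end - 1) in sites
        internal = sum(1 for s in sites if start <= s < end - 1)
        if left_ok and right_ok and internal <= max_missed:
            return True
        start = protein.find(peptide, start + 1)
    return False


def genes_containing(peptide: str, proteome: dict, equate_il: bool = False) -> set:
    """Gene ids whose isoforms contain the peptide as a substring."""
    pep = _norm(peptide, equate_il)
    return {
        g
        for g, isoforms in proteome.items()
        if any(pep in _norm(iso, equate_il) for iso in isoforms)
    }


def filter_evidence(
    records: pd.DataFrame,
    proteome: dict,
    pep_cutoff: float = PEP_CUTOFF,
    max_missed: int = 1,
    min_experiments: int = 2,
    equate_il: bool = False,
) -> pd.DataFrame:
    """Apply the peptide-evidence filters; order-independent by design.

    Keeps records whose peptide (1) has PEP <= cutoff, (2) is a fully
    tryptic fragment (<= max_missed missed cleavages) of an isoform of its
    single mapped gene, (3) maps to exactly one gene in the proteome, and
    (4) is detected in >= min_experiments distinct experiments after the
    other filters."""
    req = {"peptide", "pep_score", "experiment_id", "tissue"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"evidence table lacks columns {sorted(missing)}")
    df = records[records["pep_score"] <= pep_cutoff].copy()
    keep_pep = {}
    for pep in df["peptide"].unique():
        genes = genes_containing(pep, proteome, equate_il)
        if len(genes) != 1:
            keep_pep[pep] = False
            continue
        (gene,) = genes
        keep_pep[pep] = any(
            _is_tryptic_in(_norm(pep, equate_il), _norm(iso, equate_il), max_missed)
            for iso in proteome[gene]
        )
    mask = df["peptide"].map(keep_pep).fillna(False).astype(bool)
    df = df[mask]
    n_exp = df.groupby("peptide")["experiment_id"].nunique()
    good = set(n_exp[n_exp >= min_experiments].index)
    return df[df["peptide"].isin(good)].reset_index(drop=True)


def discriminating_peptides(
    side_a_isoforms: list[str],
    side_b_isoforms: list[str],
    uhp_a: str,
    uhp_b: str,
    gene_id: str,
    proteome: dict,
    max_missed: int = 1,
    min_len: int = MIN_PEPTIDE_LEN,
    equate_il: bool = False,
) -> dict:
    """Peptides that uniquely discriminate one UHP side of an event.

    A peptide discriminates side A iff it is a tryptic peptide of at least
    one side-A isoform, overlaps the side-A UHP region by >= 1 residue
    there (junction-spanning peptides count), occurs in no side-B isoform,
    and maps to no other gene.  Symmetric for B.  Peptides present on both
    sides are 'shared' and never counted."""
    def side_peps(isoforms, uhp):
        peps = {}
        for iso in isoforms:
            u0 = iso.find(uhp)
            if u0 < 0:
                continue
            u1 = u0 + len(uhp)
            for span in tryptic_digest(iso, max_missed, min_len):
                if span.start < u1 and span.end > u0:  # overlaps the UHP
                    peps[span.sequence] = span
        return peps

    cand_a = side_peps(side_a_isoforms, uhp_a)
    cand_b = side_peps(side_b_isoforms, uhp_b)

    def in_any(pep, isoforms):
        p = _norm(pep, equate_il)
        return any(p in _norm(iso, equate_il) for iso in isoforms)

    out = {"A": set(), "B": set(), "shared": set()}
    for pep in cand_a:
        if in_any(pep, side_b_isoforms):
            out["shared"].add(pep)
        elif genes_containing(pep, proteome, equate_il) <= {gene_id}:
            out["A"].add(pep)
    for pep in cand_b:
        if in_any(pep, side_a_isoforms):
            out["shared"].add(pep)
        elif genes_containing(pep, proteome, equate_il) <= {gene_id}:
            out["B"].add(pep)
    return out


def compute_pec(
    records: pd.DataFrame,
    assignment: dict,
) -> pd.DataFrame:
    """Peptide experiment counts per (event, side, tissue).

    ``assignment`` maps peptide sequence -> (event_id, side).  Distinctness
    is per (peptide, experiment): repeated spectra of one peptide within an
    experiment count once; the same experiment detected through two
    different peptides counts once per peptide."""
    rows = []
    df = records.drop_duplicates(subset=["peptide", "experiment_id"])
    for r in df.itertuples():
        hit = assignment.get(r.peptide)
        if hit is None:
            continue
        event_id, side = hit
        rows.append((event_id, side, r.tissue))
    out = pd.DataFrame(rows, columns=["event_id", "side", "tissue"])
    if out.empty:
        return pd.DataFrame(columns=["event_id", "side", "tissue", "pec"])
    return (
        out.groupby(["event_id", "side", "tissue"])
        .size()
        .rename("pec")
        .reset_index()
    )


@dataclass
class TissueSpecificityResult:
    event_id: str
    tissue_or_group: str
    is_group: bool
    table: tuple  # ((A_in, A_out), (B_in, B_out))
    odds_ratio: float
    p: float
    adjusted_p: float
    specific_side: str  # 'A', 'B' or 'none'
    evaluable: bool


def tissue_specificity(
    pec_table: pd.DataFrame,
    groups: dict | None = None,
    alpha: float = 0.05,
) -> list[TissueSpecificityResult]:
    """Fisher's exact tissue-specificity tests per event.

    For each event and each tissue (and each tissue group, PECs pooled over
    member tissues), the 2x2 table contrasts side-A PECs in the tissue vs
    elsewhere against side-B PECs.  Events where either side has a total
    PEC below 3 are reported non-evaluable without p-values.  The specific
    flag uses the raw two-sided p (as in the source analysis); Benjamini-
    Hochberg adjusted p-values across all evaluable tests are attached for
    transparency."""
    groups = groups or {}
    results: list[TissueSpecificityResult] = []
    if pec_table.empty:
        return results
    for tissue in pec_table["tissue"].unique():
        if groups and tissue not in groups:
            raise KeyError(f"tissue {tissue!r} absent from the tissue-group map")
    for event_id, ev in pec_table.groupby("event_id"):
        tot = ev.groupby("side")["pec"].sum()
        tot_a, tot_b = int(tot.get("A", 0)), int(tot.get("B", 0))
        if tot_a < MIN_PEC or tot_b < MIN_PEC:
            results.append(
                TissueSpecificityResult(
                    event_id, "", False, ((0, 0), (0, 0)), float("nan"),
                    float("nan"), float("nan"), "none", False,
                )
            )
            continue
        by = ev.set_index(["side", "tissue"])["pec"]

        def pec_in(side, tissues):
            return int(sum(by.get((side, t), 0) for t in tissues))

        units = [(t, False, [t]) for t in sorted(ev["tissue"].unique())]
        if groups:
            members: dict[str, list] = {}
            for t, g in groups.items():
                members.setdefault(g, []).append(t)
            units += [(g, True, ts) for g, ts in sorted(members.items())]
        for name, is_group, tissues in units:
            a_in = pec_in("A", tissues)
            b_in = pec_in("B", tissues)
            table = ((a_in, tot_a - a_in), (b_in, tot_b - b_in))
            odds, p = fisher_two_sided(table)
            if p < alpha:
                # direction: the side over-represented in this tissue
                side = "A" if a_in * tot_b > b_in * tot_a else "B"
            else:
                side = "none"
            results.append(
                TissueSpecificityResult(
                    event_id, name, is_group, table, odds, p, float("nan"),
                    side, True,
                )
            )
    ps = [r.p for r in results if r.evaluable]
    if ps:
        adj = multipletests(ps, method="fdr_bh")[1]
        it = iter(adj)
        for r in results:
            if r.evaluable:
                r.adjusted_p = float(next(it))
    return results


def specific_events(results: list[TissueSpecificityResult]) -> set:
    """Events with at least one significant tissue or group."""
    return {r.event_id for r in results if r.evaluable and r.specific_side != "none"}
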
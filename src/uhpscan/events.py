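"""Detection of tandem duplicated exon substitution events.

A tandem duplicated exon substitution event is a pair of adjacent,
homologous CDS in one gene that are spliced mutually exclusively: distinct
coding transcripts carry one or the other, so the resulting protein
isoforms differ only in the encoded segment (the two "unique homologous
polypeptide" — UHP — regions).

The detector applies three curation predicates to every candidate pair of
distinct CDS:

1. consecutive — the two CDS are adjacent in the gene's genomically ordered
   set of distinct CDS, with no third distinct CDS strictly between them;
2. mutually exclusive — more coding transcripts carry exactly one of the
   pair than carry both (strict majority);
3. homologous — the two encoded peptides are each at least ``min_uhp_len``
   residues and align with an empirical shuffle-test significance at or
   below ``homology_alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .annotation import TranscriptModel
from .stats import multinomial_gof

logger = logging.getLogger(__name__)

__all__ = [
    "TandemEvent",
    "PositionExpectation",
    "HomologyResult",
    "enumerate_candidate_pairs",
    "mutual_exclusivity_check",
    "homology_test",
    "classify_position",
    "expected_position_counts",
    "detect_events",
]

POSITION_CLASSES = ("N-terminal", "internal", "C-terminal", "full-protein")

# minimum internal-CDS length (nt) counted in the random position model;
# shorter internal CDS are too small to encode a detectable UHP region
MIN_INTERNAL_CDS_NT = 21


@dataclass
class HomologyResult:
    score: float
    identity: float
    empirical_p: float
    reason: str | None = None  # set when the pair was rejected without testing

    @property
    def tested(self) -> bool:
        return self.reason is None


@dataclass
class TandemEvent:
    event_id: str
    gene_id: str
    cds_a: tuple[int, int]
    cds_b: tuple[int, int]
    transcripts_with_a_only: frozenset
    transcripts_with_b_only: frozenset
    transcripts_with_both: frozenset
    position_class: str
    uhp_a: str
    uhp_b: str
    homology: HomologyResult


@dataclass
class PositionExpectation:
    observed: dict
    expected: dict
    enrichment_p: float


def _local_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def distinct_cds(transcripts: list[TranscriptModel]) -> list[tuple[int, int]]:
    """The gene's distinct CDS loci: unique (start, end) intervals sorted by
    genomic coordinate.  Overlapping-but-unequal intervals are distinct."""
    return sorted({iv for t in transcripts for iv in t.cds_intervals})


def enumerate_candidate_pairs(
    transcripts: list[TranscriptModel],
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All pairs of distinct, non-overlapping CDS that are consecutive: no
    third distinct CDS lies strictly inside the gap between them."""
    loci = distinct_cds(transcripts)
    pairs = []
    for i, a in enumerate(loci):
        for b in loci[i + 1 :]:
            if b[0] <= a[1]:
                continue  # overlapping loci cannot form a pair
            gap_blocked = any(
                c[0] > a[1] and c[1] < b[0] for c in loci if c not in (a, b)
            )
            if not gap_blocked:
                pairs.append((a, b))
    return pairs


def mutual_exclusivity_check(
    pair, transcripts: list[TranscriptModel]
) -> tuple[int, int, int, bool]:
    """Count coding transcripts with only cds_a, only cds_b, or both.

    Passes when (a_only + b_only) > both — the pair is annotated in
    distinct coding transcripts more often than together (strict
    majority; ties fail)."""
    a, b = pair
    a_only = b_only = both = 0
    seen = False
    for t in transcripts:
        has_a = a in t.cds_intervals
        has_b = b in t.cds_intervals
        if has_a or has_b:
            seen = True
        if has_a and has_b:
            both += 1
        elif has_a:
            a_only += 1
        elif has_b:
            b_only += 1
    if not seen:
        raise ValueError(f"pair {pair} absent from all transcripts of the gene")
    return a_only, b_only, both, (a_only + b_only) > both


def homology_test(
    uhp_a: str,
    uhp_b: str,
    n_shuffles: int = 99,
    seed: int = 0,
    min_uhp_len: int = 7,
) -> HomologyResult:
    """Shuffle-test homology between the two UHP peptides.

    The observed statistic is the best local alignment score (BLOSUM62,
    affine gaps 11/1).  The null distribution is obtained by re-aligning
    uhp_a against seeded residue shuffles of uhp_b;
    empirical_p = (1 + #{shuffled >= observed}) / (n_shuffles + 1).
    Pairs below ``min_uhp_len`` are rejected with a reason code rather than
    raising."""
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be at least 99")
    if len(uhp_a) < min_uhp_len or len(uhp_b) < min_uhp_len:
        return HomologyResult(0.0, 0.0, 1.0, reason="uhp_below_min_length")
    al = _local_aligner()
    alns = al.align(uhp_a, uhp_b)
    score = float(alns.score)
    best = alns[0]
    cols = list(zip(best[0], best[1]))
    aligned = [(x, y) for x, y in cols if x != "-" and y != "-"]
    ident = (
        100.0 * sum(x == y for x, y in aligned) / len(aligned) if aligned else 0.0
    )
    rng = np.random.default_rng(seed)
    b_arr = np.frombuffer(uhp_b.encode(), dtype="S1")
    ge = 0
    for _ in range(n_shuffles):
        shuf = rng.permutation(b_arr).tobytes().decode()
        if al.score(uhp_a, shuf) >= score:
            ge += 1
    p = (1 + ge) / (n_shuffles + 1)
    return HomologyResult(score, ident, p)


def uhp_sequence(
    transcript: TranscriptModel, cds: tuple[int, int]
) -> str:
    """Peptide encoded by one CDS within its transcript's reading frame."""
    offset = 0
    for iv in transcript.cds_intervals:
        if iv == cds:
            break
        offset += iv[1] - iv[0] + 1
    else:
        raise ValueError(f"CDS {cds} not in transcript {transcript.transcript_id}")
    offset -= transcript.phases[0]
    length = cds[1] - cds[0] + 1
    start_res = max(0, offset) // 3
    end_res = (offset + length - 1) // 3
    return transcript.protein[start_res : end_res + 1]


def classify_position(pair, transcripts: list[TranscriptModel]) -> str:
    """Position class of the substituted region within the protein.

    A pair is N-terminal if either CDS is the 5'-most CDS of any transcript
    carrying it, C-terminal if either is 3'-most, full-protein if both hold,
    internal otherwise.  Terminal status in any one transcript dominates
    internal status in others."""
    is_first = is_last = False
    for t in transcripts:
        for cds in pair:
            if cds in t.cds_intervals:
                if t.first_cds() == cds:
                    is_first = True
                if t.last_cds() == cds:
                    is_last = True
    if is_first and is_last:
        return "full-protein"
    if is_first:
        return "N-terminal"
    if is_last:
        return "C-terminal"
    return "internal"


def expected_position_counts(
    n_internal_cds: int,
    n_5prime_cds: int,
    n_3prime_cds: int,
    n_events: int,
    observed: dict | None = None,
) -> PositionExpectation:
    """Expected event counts per position class if duplication were random
    across CDS loci, in proportion to how many CDS of each class exist.

    ``n_internal_cds`` should count only internal CDS of length >= 21 nt.
    When observed counts are supplied, a goodness-of-fit p-value is
    computed (exact multinomial for <= 300 events, chi-squared otherwise).
    """
    counts = {
        "internal": n_internal_cds,
        "N-terminal": n_5prime_cds,
        "C-terminal": n_3prime_cds,
    }
    total = sum(counts.values())
    if total <= 0 or min(counts.values()) < 0:
        raise ValueError("class counts must be positive overall")
    expected = {k: n_events * v / total for k, v in counts.items()}
    p = float("nan")
    if observed is not None:
        classes = list(counts)
        obs = [observed.get(k, 0) for k in classes]
        if sum(obs) != n_events:
            raise ValueError("observed counts must sum to n_events")
        probs = [counts[k] / total for k in classes]
        p = multinomial_gof(obs, probs)
    return PositionExpectation(observed=dict(observed or {}), expected=expected, enrichment_p=p)


def detect_events(
    genes: dict[str, list[TranscriptModel]],
    min_uhp_len: int = 7,
    homology_alpha: float = 0.01,
    n_shuffles: int = 99,
    seed: int = 0,
) -> list[TandemEvent]:
    """Run the full curation over every gene; returns accepted events.

    Randomness (the homology shuffle test) is derived deterministically
    from ``seed`` and the event's genomic coordinates, so results do not
    depend on gene iteration order."""
    events = []
    for gene_id in sorted(genes):
        transcripts = genes[gene_id]
        strand = transcripts[0].strand
        for cds_a, cds_b in enumerate_candidate_pairs(transcripts):
            if strand == "-":
                # candidate pairs come in genomic order; cds_a is 5' of cds_b
                # in transcription order
                cds_a, cds_b = cds_b, cds_a
            a_only, b_only, both, passes = mutual_exclusivity_check(
                (cds_a, cds_b), transcripts
            )
            if not passes:
                continue
            tx_a = next(t for t in transcripts if cds_a in t.cds_intervals)
            tx_b = next(t for t in transcripts if cds_b in t.cds_intervals)
            uhp_a = uhp_sequence(tx_a, cds_a)
            uhp_b = uhp_sequence(tx_b, cds_b)
            pair_seed = (seed * 1000003 + hash((cds_a, cds_b)) % 65521) % (2**31)
            hom = homology_test(
                uhp_a, uhp_b, n_shuffles=n_shuffles, seed=pair_seed,
                min_uhp_len=min_uhp_len,
            )
            if not hom.tested or hom.empirical_p > homology_alpha:
                continue
            a_set = frozenset(
                t.transcript_id for t in transcripts
                if cds_a in t.cds_intervals and cds_b not in t.cds_intervals
            )
            b_set = frozenset(
                t.transcript_id for t in transcripts
                if cds_b in t.cds_intervals and cds_a not in t.cds_intervals
            )
            both_set = frozenset(
                t.transcript_id for t in transcripts
                if cds_a in t.cds_intervals and cds_b in t.cds_intervals
            )
            events.append(
                TandemEvent(
                    event_id=f"{gene_id}:{cds_a[0]}-{cds_a[1]}|{cds_b[0]}-{cds_b[1]}",
                    gene_id=gene_id,
                    cds_a=cds_a,
                    cds_b=cds_b,
                    transcripts_with_a_only=a_set,
                    transcripts_with_b_only=b_set,
                    transcripts_with_both=both_set,
                    position_class=classify_position((cds_a, cds_b), transcripts),
                    uhp_a=uhp_a,
                    uhp_b=uhp_b,
                    homology=hom,
                )
            )
    return events
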
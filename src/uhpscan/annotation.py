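"""Gene annotation parsing and coding-sequence translation.

Transcript models are read from GTF or GFF3 with gffutils and spliced /
translated strand-aware.  All coordinates are 1-based inclusive genomic
positions, as in the input formats; ordering of ``cds_intervals`` follows
transcription (5'->3'), so on the minus strand intervals appear in
decreasing genomic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = ["TranscriptModel", "AnnotationError", "parse_annotation", "translate_cds"]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class TranscriptModel:
    """Ordered CDS structure of one coding transcript.

    cds_intervals are (start, end) 1-based inclusive genomic coordinates in
    transcription order; phases give the frame offset (0/1/2) of each CDS.
    """

    transcript_id: str
    gene_id: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    phases: list[int] = field(default_factory=list)
    seqid: str = ""
    protein: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r} for {self.transcript_id}")
        starts = [s for s, _ in self.cds_intervals]
        ends = [e for _, e in self.cds_intervals]
        if any(s > e for s, e in self.cds_intervals):
            raise AnnotationError(f"inverted CDS interval in {self.transcript_id}")
        genomic = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise AnnotationError(f"overlapping CDS in {self.transcript_id}")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if self.cds_intervals != expect:
            raise AnnotationError(
                f"CDS order inconsistent with strand in {self.transcript_id}"
            )
        del starts, ends

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def first_cds(self) -> tuple[int, int]:
        """5'-most CDS in transcription order."""
        return self.cds_intervals[0]

    def last_cds(self) -> tuple[int, int]:
        return self.cds_intervals[-1]


def translate_cds(spliced: str, phase: int = 0) -> str:
    """Translate a spliced CDS nucleotide sequence (already in coding
    orientation).  ``phase`` bases of an incomplete leading codon are
    skipped; a trailing incomplete codon and a terminal stop are dropped.
    An internal stop raises AnnotationError (the caller excludes the
    transcript)."""
    s = spliced[phase:].upper()
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    prot = str(Seq(s).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise AnnotationError("internal stop codon")
    return prot


def _validate_lines(gtf_path: str) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: non-numeric coordinates "
                    f"{fields[3]!r}..{fields[4]!r}"
                )


def _open_db(gtf_path: str) -> gffutils.FeatureDB:
    _validate_lines(gtf_path)
    try:
        return gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the offending line in its message
        raise AnnotationError(f"failed to parse annotation {gtf_path}: {exc}") from exc


def parse_annotation(gtf_path: str, fasta_path: str) -> dict[str, list[TranscriptModel]]:
    """Read a GTF/GFF3 plus genome FASTA into TranscriptModels grouped by gene.

    Every CDS-bearing transcript yields one TranscriptModel with its
    translated protein attached.  Transcripts whose CDS length (after phase
    correction) is not divisible by 3, or that contain an internal stop,
    are excluded with a log entry.
    """
    db = _open_db(gtf_path)
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    by_gene: dict[str, list[TranscriptModel]] = {}
    cds_by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, strand, seqid)
    for cds in db.features_of_type("CDS"):
        tx_ids = cds.attributes.get("transcript_id") or cds.attributes.get("Parent")
        if not tx_ids:
            raise AnnotationError(f"CDS without transcript_id/Parent at line: {cds}")
        gene_ids = cds.attributes.get("gene_id") or [tx_ids[0]]
        for tx in tx_ids:
            cds_by_tx.setdefault(tx, []).append(cds)
            meta.setdefault(tx, (gene_ids[0], cds.strand, cds.seqid))

    for tx, parts in cds_by_tx.items():
        gene_id, strand, seqid = meta[tx]
        parts.sort(key=lambda c: c.start, reverse=(strand == "-"))
        intervals = [(c.start, c.end) for c in parts]
        phases = [int(c.frame) if c.frame not in (None, ".") else 0 for c in parts]
        try:
            model = TranscriptModel(tx, gene_id, strand, intervals, phases, seqid)
        except AnnotationError as exc:
            logger.warning("excluding transcript %s: %s", tx, exc)
            continue
        chunks = []
        for s, e in intervals:
            seq = str(genome[seqid][s - 1 : e])
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            chunks.append(seq)
        spliced = "".join(chunks)
        if (len(spliced) - phases[0]) % 3 != 0:
            logger.warning(
                "excluding transcript %s: CDS length %d (phase %d) not divisible by 3",
                tx, len(spliced), phases[0],
            )
            continue
        try:
            model.protein = translate_cds(spliced, phases[0])
        except AnnotationError as exc:
            logger.warning("excluding transcript %s: %s", tx, exc)
            continue
        if len(model.protein) < 1:
            logger.warning("excluding transcript %s: empty translation", tx)
            continue
        by_gene.setdefault(gene_id, []).append(model)
    return by_gene
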
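"""Core domain types shared across the package.

Coordinate conventions
----------------------
All internal intervals are **0-based, half-open** ``[start, end)`` — the BED
convention. SNPs are stored as **1-based** points (the convention of GWAS
Catalog / dbSNP tables) and converted to 0-based exactly once, at overlap
time, via the single rule::

    snp overlaps interval  <=>  start <= pos - 1 < end

External 1-based formats (GTF, SNP tables) are converted at the I/O boundary
and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "RecordError",
    "GenomicInterval",
    "Snp",
    "DiffPeak",
    "TranscriptModel",
    "DegRecord",
    "SpliceEvent",
    "QtlRecord",
]

STRANDS = {"+", "-", "."}
SPLICE_EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")
QTL_TYPES = ("eQTL", "sQTL")
DIRECTIONS = ("increased", "decreased", "none")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is invalid."""


class RecordError(ValidationError):
    """A malformed record in an input file; carries the offending line."""

    def __init__(self, message: str, line: Optional[int] = None, path=None):
        self.line = line
        self.path = path
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open span [start, end), 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos0: int) -> bool:
        """Containment of a 0-based point."""
        return self.start <= pos0 < self.end

    def contains_snp(self, snp: "Snp") -> bool:
        """The one documented SNP-in-interval rule: start <= pos-1 < end."""
        return self.chrom == snp.chrom and self.start <= snp.pos - 1 < self.end


@dataclass(frozen=True)
class Snp:
    """A point variant (1-based position) with lead/LD-proxy provenance.

    Leads carry ``r2 = 1.0`` and are their own ``lead_rsid``; proxies carry
    the linkage r-squared to their attributed lead.
    """

    rsid: str
    chrom: str
    pos: int
    is_lead: bool = True
    lead_rsid: Optional[str] = None
    r2: float = 1.0

    def __post_init__(self):
        if self.lead_rsid is None:
            object.__setattr__(self, "lead_rsid", self.rsid if self.is_lead else None)
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"{self.rsid}: r2 must be in [0, 1], got {self.r2}")
        if self.is_lead != (self.lead_rsid == self.rsid):
            raise ValidationError(
                f"{self.rsid}: lead_rsid == rsid iff is_lead "
                f"(is_lead={self.is_lead}, lead_rsid={self.lead_rsid})"
            )

    @property
    def pos0(self) -> int:
        """0-based position, for overlap arithmetic."""
        return self.pos - 1


@dataclass(frozen=True)
class DiffPeak:
    """An m6A peak with differential statistics (tumor vs normal).

    ``direction`` is ``none`` until classified; ``increased``/``decreased``
    require a matching sign of ``log2fc``.
    """

    interval: GenomicInterval
    log2fc: float
    pvalue: float
    padj: Optional[float] = None
    direction: str = "none"
    peak_id: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"pvalue must be in [0, 1], got {self.pvalue}")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValidationError(f"padj must be in [0, 1], got {self.padj}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if self.direction == "increased" and not self.log2fc > 0:
            raise ValidationError("direction=increased requires log2fc > 0")
        if self.direction == "decreased" and not self.log2fc < 0:
            raise ValidationError("direction=decreased requires log2fc < 0")

    def with_direction(self, direction: str, padj: Optional[float] = None) -> "DiffPeak":
        return replace(self, direction=direction, padj=self.padj if padj is None else padj)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript, in genomic coordinates.

    Exons are sorted, non-overlapping, 0-based half-open. ``cds_start`` /
    ``cds_end`` are genomic bounds of the coding span (absent for noncoding
    transcripts). Transcript ("mRNA") coordinates run 5'->3' along the
    mature transcript, i.e. reversed relative to the genome on the minus
    strand.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValidationError(f"{self.transcript_id}: exon on wrong chromosome")
            if ex.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not self.cds_end > self.cds_start:
                raise ValidationError(f"{self.transcript_id}: empty CDS span")
            if not (self._in_exon_union(self.cds_start) and self._in_exon_union(self.cds_end - 1)):
                raise ValidationError(
                    f"{self.transcript_id}: CDS bounds outside exon union"
                )

    def _in_exon_union(self, pos0: int) -> bool:
        return any(ex.contains_point(pos0) for ex in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def cds_length(self) -> Optional[int]:
        if not self.is_coding:
            return None
        lo, hi = self.cds_transcript_span()
        return hi - lo

    @property
    def tss(self) -> int:
        """0-based genomic position of the transcription start site."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    @property
    def tes(self) -> int:
        """0-based genomic position of the transcription end site."""
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start

    def to_transcript(self, gpos: int) -> int:
        """Map a 0-based genomic position inside an exon to a transcript coordinate."""
        off = 0
        plus = None
        for ex in self.exons:
            if ex.contains_point(gpos):
                plus = off + (gpos - ex.start)
                break
            off += len(ex)
        if plus is None:
            raise ValueError(f"{gpos} not in exon union of {self.transcript_id}")
        return plus if self.strand == "+" else self.exonic_length - 1 - plus

    def to_genomic(self, tpos: int) -> int:
        """Map a transcript coordinate back to a 0-based genomic position."""
        if not (0 <= tpos < self.exonic_length):
            raise ValueError(f"transcript coordinate {tpos} out of range")
        plus = tpos if self.strand == "+" else self.exonic_length - 1 - tpos
        off = 0
        for ex in self.exons:
            if plus < off + len(ex):
                return ex.start + (plus - off)
            off += len(ex)
        raise AssertionError("unreachable")

    def cds_transcript_span(self):
        """(lo, hi) transcript coordinates of the CDS, half-open, 5'->3'."""
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is noncoding")
        a = self.to_transcript(self.cds_start)
        b = self.to_transcript(self.cds_end - 1)
        lo, hi = (a, b) if a <= b else (b, a)
        return lo, hi + 1


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression result (DESeq2-style)."""

    gene_id: str
    log2fc: float
    pvalue: Optional[float] = None
    padj: Optional[float] = None

    def __post_init__(self):
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.gene_id}: {name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event (rMATS-style)."""

    gene_id: str
    event_type: str
    inc_level_diff: float
    fdr: float

    def __post_init__(self):
        if self.event_type not in SPLICE_EVENT_TYPES:
            raise ValidationError(
                f"event_type must be one of {SPLICE_EVENT_TYPES}, got {self.event_type!r}"
            )
        if abs(self.inc_level_diff) > 1.0:
            raise ValidationError(f"|inc_level_diff| must be <= 1, got {self.inc_level_diff}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"fdr must be in [0, 1], got {self.fdr}")


@dataclass(frozen=True)
class QtlRecord:
    """A variant-to-gene QTL annotation (eQTL or sQTL)."""

    rsid: str
    target_gene: str
    qtl_type: str

    def __post_init__(self):
        if self.qtl_type not in QTL_TYPES:
            raise ValidationError(f"qtl_type must be one of {QTL_TYPES}, got {self.qtl_type!r}")
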
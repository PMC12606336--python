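"""Differential m6A peak classification, metagene profiling, DRACH scanning.

The metagene axis is the standard three-segment transcript coordinate:
[0, 1) is the 5'UTR, [1, 2) the CDS, [2, 3) the 3'UTR, each segment scaled
to unit length within its transcript. m6A peaks of coding transcripts
characteristically concentrate near the stop codon, i.e. around 2.0 on this
axis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .stats import benjamini_hochberg
from .types import ConfigurationError, DiffPeak, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

# DRACH consensus in DNA space (U -> T): D = A/G/T, R = A/G, H = A/C/T
DRACH_PATTERN = "[AGT][AG]AC[ACT]"
DRACH_RE = re.compile(DRACH_PATTERN)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_dmps(
    peaks: Sequence[DiffPeak],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> Tuple[List[DiffPeak], List[DiffPeak]]:
    """Split peaks into (increased, decreased) differential m6A peaks.

    Significance is BH-adjusted p < ``alpha`` (strict) by default; setting
    ``use_adjusted=False`` applies the threshold to raw p-values instead.
    Missing adjusted p-values are recomputed by BH over all input peaks.
    Significant peaks with log2fc exactly 0 stay unclassified (logged).
    Returned peaks carry their direction label; the two lists are disjoint
    and together with the unclassified remainder partition the input.
    """
    peaks = list(peaks)
    if use_adjusted and any(p.padj is None for p in peaks):
        adj = benjamini_hochberg([p.pvalue for p in peaks])
        peaks = [
            p if p.padj is not None else p.with_direction(p.direction, padj=float(a))
            for p, a in zip(peaks, adj)
        ]
        logger.info("padj recomputed by BH for %d peaks", len(peaks))
    increased, decreased = [], []
    for p in peaks:
        stat = p.padj if use_adjusted else p.pvalue
        if stat is not None and stat < alpha:
            if p.log2fc > 0:
                increased.append(p.with_direction("increased"))
            elif p.log2fc < 0:
                decreased.append(p.with_direction("decreased"))
            else:
                logger.info("significant peak %s has log2fc = 0; left unclassified", p.peak_id)
    return increased, decreased


def label_dmps(
    peaks: Sequence[DiffPeak], alpha: float = 0.05, use_adjusted: bool = True
) -> List[DiffPeak]:
    """All input peaks with direction labels applied (order preserved)."""
    inc, dec = classify_dmps(peaks, alpha=alpha, use_adjusted=use_adjusted)
    by_id = {id(p.interval): p for p in inc + dec}
    out = []
    for p in peaks:
        out.append(by_id.get(id(p.interval), p))
    return out


@dataclass
class MetageneProfile:
    """Peak density along the normalized 5'UTR / CDS / 3'UTR axis [0, 3)."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_mapped: int
    n_unmapped: int
    positions: Optional[np.ndarray] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def segment_mass(self, lo: float, hi: float) -> float:
        """Integrated density over [lo, hi) of the metagene axis."""
        widths = np.diff(self.bin_edges)
        centers = self.bin_centers
        sel = (centers >= lo) & (centers < hi)
        return float(np.sum(self.density[sel] * widths[sel]))

    def write_tsv(self, path) -> None:
        from . import __version__

        with open(path, "w") as fh:
            fh.write(
                f"# m6avar v{__version__} | metagene profile; axis [0,3): "
                f"5'UTR [0,1), CDS [1,2), 3'UTR [2,3); "
                f"n_mapped={self.n_mapped} n_unmapped={self.n_unmapped}\n"
            )
            fh.write("bin_center\tdensity\n")
            for c, d in zip(self.bin_centers, self.density):
                fh.write(f"{c:.6g}\t{d:.10g}\n")


class TranscriptIndex:
    """Interval index over exons for midpoint-to-transcript assignment."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts = list(transcripts)
        self._trees: Dict[str, IntervalTree] = {}
        for i, t in enumerate(self.transcripts):
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            for ex in t.exons:
                tree.addi(ex.start, ex.end, i)

    def transcripts_at(self, chrom: str, pos0: int) -> List[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.transcripts[iv.data] for iv in tree.at(pos0)]


def _pick_transcript(cands: List[TranscriptModel]) -> Optional[TranscriptModel]:
    coding = [t for t in cands if t.is_coding]
    if not coding:
        return None
    # longest CDS, then longest transcript, then lexicographic id
    return min(coding, key=lambda t: (-t.cds_length, -t.exonic_length, t.transcript_id))


def metagene_position(pos0: int, t: TranscriptModel) -> Optional[float]:
    """Normalized [0, 3) coordinate of a genomic point on a coding transcript.

    Returns None if the transcript lacks the segment the point falls in
    (e.g. a zero-length UTR).
    """
    tp = t.to_transcript(pos0)
    lo, hi = t.cds_transcript_span()
    L = t.exonic_length
    if tp < lo:
        return tp / lo
    if tp < hi:
        return 1.0 + (tp - lo) / (hi - lo)
    if L == hi:
        return None
    return 2.0 + (tp - hi) / (L - hi)


def metagene_profile(
    peaks: Sequence[DiffPeak],
    transcripts: Sequence[TranscriptModel],
    n_bins: int = 90,
    index: Optional[TranscriptIndex] = None,
) -> MetageneProfile:
    """Map each peak's midpoint onto the metagene axis and bin the density.

    A peak is represented by its interval midpoint; the midpoint is assigned
    to the coding transcript whose exon union contains it (longest CDS on
    ties). Peaks hitting no transcript, only introns, or only noncoding
    transcripts are counted as unmapped. The density integrates to 1 over
    [0, 3) whenever any peak maps.
    """
    if n_bins < 3:
        raise ConfigurationError(f"n_bins must be >= 3, got {n_bins}")
    idx = index if index is not None else TranscriptIndex(transcripts)
    positions = []
    n_unmapped = 0
    for p in peaks:
        iv = p.interval
        mid = (iv.start + iv.end) // 2
        t = _pick_transcript(idx.transcripts_at(iv.chrom, mid))
        x = metagene_position(mid, t) if t is not None else None
        if x is None:
            n_unmapped += 1
        else:
            positions.append(x)
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    if positions:
        density, _ = np.histogram(positions, bins=edges, density=True)
    else:
        density = np.zeros(n_bins)
    return MetageneProfile(
        bin_edges=edges,
        density=density,
        n_mapped=len(positions),
        n_unmapped=n_unmapped,
        positions=np.asarray(positions),
    )


def peak_sequence(peak: DiffPeak, fasta) -> str:
    """Strand-aware peak sequence from an indexed FASTA (pyfaidx.Fasta)."""
    iv = peak.interval
    if iv.chrom not in fasta:
        raise ValueError(f"chromosome {iv.chrom} absent from genome FASTA")
    contig_len = len(fasta[iv.chrom])
    if iv.end > contig_len:
        raise ValueError(
            f"peak [{iv.start}, {iv.end}) beyond end of {iv.chrom} (length {contig_len})"
        )
    seq = str(fasta[iv.chrom][iv.start : iv.end]).upper()
    return reverse_complement(seq) if iv.strand == "-" else seq


def has_drach(seq: str) -> bool:
    return DRACH_RE.search(seq.upper()) is not None


def drach_fraction(peaks: Sequence[DiffPeak], genome_fasta) -> float:
    """Fraction of peaks whose strand-aware sequence contains a DRACH match.

    ``genome_fasta`` is a path to an (indexable) FASTA or an open
    pyfaidx.Fasta.
    """
    import pyfaidx

    peaks = list(peaks)
    if not peaks:
        return 0.0
    fasta = genome_fasta if isinstance(genome_fasta, pyfaidx.Fasta) else pyfaidx.Fasta(str(genome_fasta))
    n_hit = sum(1 for p in peaks if has_drach(peak_sequence(p, fasta)))
    return n_hit / len(peaks)
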
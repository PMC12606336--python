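"""Genomic-context annotation of SNPs and SNP-in-peak overlap.

Categories follow HOMER-style conventions: promoter (TSS -1000/+100 bp,
strand-aware), TTS (transcription end +/- 1000 bp), exonic, intronic,
intergenic, assigned with the fixed precedence
promoter > TTS > exonic > intronic > intergenic over all transcripts
touching the SNP. Windows and precedence are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .types import (
    ConfigurationError,
    DiffPeak,
    GenomicInterval,
    Snp,
    TranscriptModel,
    ValidationError,
)
from .variant_sets import VariantSet

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "TTS", "exonic", "intronic", "intergenic")
DEFAULT_PROMOTER_UP = 1000
DEFAULT_PROMOTER_DOWN = 100
DEFAULT_TTS_FLANK = 1000


@dataclass(frozen=True)
class AnnotatedSnp:
    snp: Snp
    category: str
    host_gene: Optional[str] = None
    subcategory: Optional[str] = None  # 5UTR/CDS/3UTR when exonic is resolved

    def __post_init__(self):
        if (self.category == "intergenic") != (self.host_gene is None):
            raise ValidationError("host_gene absent iff category is intergenic")


class SnpAnnotator:
    """Index transcripts once, annotate many SNPs.

    Parameters
    ----------
    promoter_up, promoter_down : int
        Strand-aware promoter window: ``up`` bases upstream of the TSS to
        ``down`` bases downstream.
    tts_flank : int
        Symmetric window around the transcription end site.
    precedence : sequence of category names, highest priority first.
    """

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        promoter_up: int = DEFAULT_PROMOTER_UP,
        promoter_down: int = DEFAULT_PROMOTER_DOWN,
        tts_flank: int = DEFAULT_TTS_FLANK,
        precedence: Sequence[str] = ("promoter", "TTS", "exonic", "intronic"),
    ):
        unknown = set(precedence) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories in precedence: {unknown}")
        self.precedence = tuple(precedence)
        self.transcripts = list(transcripts)
        self._trees: Dict[str, Dict[str, IntervalTree]] = {}
        for i, t in enumerate(self.transcripts):
            trees = self._trees.setdefault(
                t.chrom, {c: IntervalTree() for c in ("promoter", "TTS", "exonic", "intronic")}
            )
            if t.strand == "+":
                plo, phi = t.tss - promoter_up, t.tss + promoter_down + 1
            else:
                plo, phi = t.tss - promoter_down, t.tss + promoter_up + 1
            plo = max(plo, 0)
            if plo < phi:
                trees["promoter"].addi(plo, phi, i)
            tlo, thi = max(t.tes - tts_flank, 0), t.tes + tts_flank + 1
            trees["TTS"].addi(tlo, thi, i)
            for ex in t.exons:
                trees["exonic"].addi(ex.start, ex.end, i)
            span = t.span
            trees["intronic"].addi(span.start, span.end, i)  # minus exons, checked later

    def annotate(self, snp: Snp, resolve_utr: bool = False) -> AnnotatedSnp:
        pos0 = snp.pos0
        trees = self._trees.get(snp.chrom)
        if trees is None:
            return AnnotatedSnp(snp=snp, category="intergenic")
        for cat in self.precedence:
            hits = trees[cat].at(pos0)
            if cat == "intronic":
                # inside the transcript span but not in any exon of that transcript
                hits = {
                    h for h in hits
                    if not any(ex.contains_point(pos0) for ex in self.transcripts[h.data].exons)
                }
            if hits:
                winners = sorted(self.transcripts[h.data].gene_id for h in hits)
                host = winners[0]
                sub = None
                if cat == "exonic" and resolve_utr:
                    sub = self._utr_subcategory(pos0, [self.transcripts[h.data] for h in hits])
                return AnnotatedSnp(snp=snp, category=cat, host_gene=host, subcategory=sub)
        return AnnotatedSnp(snp=snp, category="intergenic")

    @staticmethod
    def _utr_subcategory(pos0: int, cands: List[TranscriptModel]) -> Optional[str]:
        from .peak_analysis import _pick_transcript, metagene_position

        t = _pick_transcript([c for c in cands if any(ex.contains_point(pos0) for ex in c.exons)])
        if t is None:
            return None
        x = metagene_position(pos0, t)
        if x is None:
            return None
        return ("5UTR", "CDS", "3UTR")[int(x)]


def annotate_snp(
    snp: Snp,
    transcripts: Sequence[TranscriptModel],
    promoter_window: Tuple[int, int] = (DEFAULT_PROMOTER_UP, DEFAULT_PROMOTER_DOWN),
    tts_window: int = DEFAULT_TTS_FLANK,
) -> AnnotatedSnp:
    """One-shot convenience wrapper; build a SnpAnnotator for repeated use."""
    ann = SnpAnnotator(
        transcripts,
        promoter_up=promoter_window[0],
        promoter_down=promoter_window[1],
        tts_flank=tts_window,
    )
    return ann.annotate(snp)


def overlap_snps_with_peaks(
    vset, dmps: Sequence[DiffPeak]
) -> Tuple[List[Tuple[Snp, DiffPeak]], List[Snp]]:
    """All (SNP, peak) containment pairs plus the deduplicated SNP list.

    ``dmps`` should already be direction-filtered by the caller (typically
    increased peaks only). Containment uses the single documented rule
    start <= pos-1 < end. Pairs are ordered by (rsid, peak coordinates).
    """
    snps = list(vset)
    tree_by_chrom: Dict[str, IntervalTree] = {}
    for i, p in enumerate(dmps):
        iv = p.interval
        tree_by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    pairs: List[Tuple[Snp, DiffPeak]] = []
    dedup: List[Snp] = []
    for s in sorted(snps, key=lambda s: s.rsid):
        tree = tree_by_chrom.get(s.chrom)
        if tree is None:
            continue
        hits = sorted(tree.at(s.pos0), key=lambda h: (h.begin, h.end, h.data))
        if hits:
            dedup.append(s)
            for h in hits:
                pairs.append((s, dmps[h.data]))
    return pairs, dedup


def write_overlap_table(pairs: Sequence[Tuple[Snp, DiffPeak]], path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(
            f"# m6avar v{__version__} | SNP-in-peak containment pairs; "
            "columns: rsid chrom pos peak_chrom peak_start peak_end peak_direction peak_id\n"
        )
        fh.write("rsid\tchrom\tpos\tpeak_chrom\tpeak_start\tpeak_end\tpeak_direction\tpeak_id\n")
        for s, p in pairs:
            iv = p.interval
            fh.write(
                f"{s.rsid}\t{s.chrom}\t{s.pos}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{p.direction}\t{p.peak_id}\n"
            )
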
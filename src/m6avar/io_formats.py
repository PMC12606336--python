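"""Readers and writers for every external table the pipeline touches.

All on-disk interval formats keep their native conventions (GTF and SNP
positions are 1-based; BED-like peak tables are 0-based half-open) and are
converted to the internal 0-based half-open convention exactly once, here.
Outputs are tab-separated with a leading ``#`` comment line naming the tool
version and column semantics; readers skip comment lines.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .stats import benjamini_hochberg
from .types import (
    ConfigurationError,
    DegRecord,
    DiffPeak,
    GenomicInterval,
    QtlRecord,
    RecordError,
    Snp,
    SpliceEvent,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

PEAK_DIALECTS = ("flat-tsv", "bed12", "auto")
_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
    "log2fc", "pvalue", "padj",
]


class LdRecord(NamedTuple):
    """One row of an LD-proxy table (HaploReg/haploR-style)."""

    lead_rsid: str
    proxy_rsid: str
    r2: float
    chrom: str
    pos: int


def _comment(text: str) -> str:
    return f"# m6avar v{__version__} | {text}\n"


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Canonicalize chromosome names ('chr'-prefixed by default).

    ``style='chr'`` adds the prefix if missing; ``style='plain'`` strips it.
    """
    name = str(name)
    if style == "chr":
        return name if name.startswith("chr") else f"chr{name}"
    if style == "plain":
        return name[3:] if name.startswith("chr") else name
    raise ConfigurationError(f"unknown chromosome naming style {style!r}")


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RecordError(f"missing required columns {missing}", path=path)


# ---------------------------------------------------------------------------
# differential m6A peak tables (exomePeak-style)
# ---------------------------------------------------------------------------

def _detect_peak_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if "chrom" in fields and "log2fc" in fields:
                return "flat-tsv"
            if len(fields) >= 14:
                return "bed12"
            raise ConfigurationError(
                f"{path}: cannot auto-detect peak-table dialect from header {fields[:6]}"
            )
    raise RecordError("empty peak table", path=path)


def read_peak_table(path, dialect: str = "auto") -> List[DiffPeak]:
    """Read an exomePeak-style differential-peak table.

    Two dialects are accepted: ``flat-tsv`` (named columns chrom, start, end,
    strand, log2fc, pvalue, optional padj/name) and ``bed12`` (headerless
    BED12 plus trailing log2fc, pvalue, optional padj columns). Coordinates
    are already 0-based half-open in both. Missing padj values are recomputed
    by Benjamini-Hochberg over all rows of the file. Direction is ``none``;
    classification happens downstream.
    """
    if dialect not in PEAK_DIALECTS:
        raise ConfigurationError(f"unknown peak dialect {dialect!r}; expected {PEAK_DIALECTS}")
    if dialect == "auto":
        dialect = _detect_peak_dialect(path)
    if dialect == "flat-tsv":
        df = _read_tsv(path)
        _require_columns(df, ["chrom", "start", "end", "strand", "log2fc", "pvalue"], path)
        if "name" not in df.columns:
            df = df.assign(name=[f"peak_{i + 1}" for i in range(len(df))])
    else:
        df = _read_tsv(path, header=None)
        if df.shape[1] < 14:
            raise RecordError(f"bed12 peak table needs >= 14 columns, found {df.shape[1]}", path=path)
        df = df.iloc[:, : min(df.shape[1], 15)]
        df.columns = _BED12_COLS[: df.shape[1]]
    if "padj" not in df.columns or df["padj"].isna().all():
        if df["pvalue"].isna().any():
            raise RecordError("cannot recompute padj: missing pvalue entries", path=path)
        df["padj"] = benjamini_hochberg(df["pvalue"].to_numpy()) if len(df) else []
        logger.info("%s: padj absent; recomputed by BH over %d rows", path, len(df))

    peaks: List[DiffPeak] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        if pd.isna(row.pvalue):
            raise RecordError("missing pvalue", line=idx, path=path)
        try:
            iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand))
            peaks.append(
                DiffPeak(
                    interval=iv,
                    log2fc=float(row.log2fc),
                    pvalue=float(row.pvalue),
                    padj=None if pd.isna(row.padj) else float(row.padj),
                    peak_id=str(row.name),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise RecordError(str(exc), line=idx, path=path) from exc
    return peaks


def write_peak_table(peaks: Iterable[DiffPeak], path, dialect: str = "flat-tsv") -> None:
    peaks = list(peaks)
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "flat-tsv":
            fh.write(_comment(
                "differential m6A peaks; 0-based half-open; "
                "columns: chrom start end strand log2fc pvalue padj direction name"
            ))
            fh.write("chrom\tstart\tend\tstrand\tlog2fc\tpvalue\tpadj\tdirection\tname\n")
            for i, p in enumerate(peaks, start=1):
                iv = p.interval
                padj = "" if p.padj is None else f"{p.padj:.10g}"
                name = p.peak_id or f"peak_{i}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{p.log2fc:.10g}\t{p.pvalue:.10g}\t{padj}\t{p.direction}\t{name}\n"
                )
        elif dialect == "bed12":
            fh.write(_comment("BED12-like differential m6A peaks + log2fc pvalue padj"))
            for i, p in enumerate(peaks, start=1):
                iv = p.interval
                name = p.peak_id or f"peak_{i}"
                padj = "" if p.padj is None else f"{p.padj:.10g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t"
                    f"{iv.start}\t{iv.end}\t0\t1\t{len(iv)},\t0,\t"
                    f"{p.log2fc:.10g}\t{p.pvalue:.10g}\t{padj}\n"
                )
        else:
            raise ConfigurationError(f"unknown peak dialect {dialect!r}")


# ---------------------------------------------------------------------------
# GTF transcript annotation (GENCODE dialect)
# ---------------------------------------------------------------------------

def read_gtf(path) -> List[TranscriptModel]:
    """Read transcript models from a GTF file (1-based inclusive features).

    Exons and CDS features are grouped by their ``transcript_id`` attribute;
    exon coordinates are converted to 0-based half-open. Transcripts without
    exons are dropped with a warning; unsorted exons are sorted silently.
    """
    import gffutils.iterators

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    exons: dict = {}
    cds_bounds: dict = {}
    meta: dict = {}
    for n, feat in enumerate(gffutils.iterators.DataIterator(str(path)), start=1):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        attrs = feat.attributes
        if "transcript_id" not in attrs:
            raise RecordError("feature lacks transcript_id attribute", line=n, path=path)
        tid = attrs["transcript_id"][0]
        meta.setdefault(tid, {
            "gene_id": attrs.get("gene_id", [tid])[0],
            "gene_name": attrs.get("gene_name", attrs.get("gene_id", [tid]))[0],
            "chrom": feat.seqid,
            "strand": feat.strand,
        })
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        else:
            lo, hi = cds_bounds.get(tid, (feat.start - 1, feat.end))
            cds_bounds[tid] = (min(lo, feat.start - 1), max(hi, feat.end))

    models: List[TranscriptModel] = []
    for tid, m in meta.items():
        if tid not in exons:
            logger.warning("%s: transcript %s has no exons; dropped", path, tid)
            continue
        ivs = sorted(exons[tid])
        if ivs != exons[tid]:
            logger.info("%s: transcript %s exons unsorted; sorted", path, tid)
        cds = cds_bounds.get(tid, (None, None))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(GenomicInterval(m["chrom"], s, e, m["strand"]) for s, e in ivs),
                cds_start=cds[0],
                cds_end=cds[1],
            )
        )
    models.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as GENCODE-style GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(_comment("GTF transcript annotation (GENCODE dialect)"))
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}";'
            )
            sp = t.span
            fh.write(
                f"{t.chrom}\tm6avar\ttranscript\t{sp.start + 1}\t{sp.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for ex in t.exons:
                fh.write(
                    f"{t.chrom}\tm6avar\texon\t{ex.start + 1}\t{ex.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                for ex in t.exons:
                    lo = max(ex.start, t.cds_start)
                    hi = min(ex.end, t.cds_end)
                    if lo < hi:
                        fh.write(
                            f"{t.chrom}\tm6avar\tCDS\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# SNP / LD tables
# ---------------------------------------------------------------------------

def read_snp_table(path) -> List[Snp]:
    """Read a GWAS-Catalog-style lead-SNP table (1-based positions).

    Deduplicates on rsid (first occurrence wins, logged); duplicate rsids
    with conflicting positions are a hard error.
    """
    df = _read_tsv(path, dtype={"rsid": str, "chrom": str})
    _require_columns(df, ["rsid", "chrom", "pos"], path)
    seen: dict = {}
    out: List[Snp] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rsid = str(row.rsid)
        pos = int(row.pos)
        if rsid in seen:
            if seen[rsid] != (str(row.chrom), pos):
                raise RecordError(
                    f"duplicate rsid {rsid} with conflicting position", line=idx, path=path
                )
            logger.info("%s: duplicate rsid %s; first occurrence kept", path, rsid)
            continue
        seen[rsid] = (str(row.chrom), pos)
        is_lead = bool(getattr(row, "is_lead", True))
        r2 = float(getattr(row, "r2", 1.0))
        lead_rsid = str(getattr(row, "lead_rsid", rsid)) if not is_lead else rsid
        try:
            out.append(Snp(rsid=rsid, chrom=str(row.chrom), pos=pos,
                           is_lead=is_lead, lead_rsid=lead_rsid, r2=r2))
        except ValidationError as exc:
            raise RecordError(str(exc), line=idx, path=path) from exc
    return out


def write_snp_table(snps: Iterable[Snp], path, trait: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        tr = f" trait={trait};" if trait else ""
        fh.write(_comment(f"SNPs, 1-based positions;{tr} columns: rsid chrom pos is_lead lead_rsid r2"))
        fh.write("rsid\tchrom\tpos\tis_lead\tlead_rsid\tr2\n")
        for s in snps:
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.is_lead}\t{s.lead_rsid}\t{s.r2:.6g}\n")


def read_ld_table(path) -> List[LdRecord]:
    """Read a haploR-style LD proxy table: lead_rsid, proxy_rsid, r2, chrom, pos."""
    df = _read_tsv(path, dtype={"lead_rsid": str, "proxy_rsid": str, "chrom": str})
    _require_columns(df, ["lead_rsid", "proxy_rsid", "r2", "chrom", "pos"], path)
    out: List[LdRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r2 = float(row.r2)
        if not (0.0 <= r2 <= 1.0):
            raise RecordError(f"r2 outside [0, 1]: {r2}", line=idx, path=path)
        pos = int(row.pos)
        if pos < 1:
            raise RecordError(f"position must be >= 1: {pos}", line=idx, path=path)
        out.append(LdRecord(str(row.lead_rsid), str(row.proxy_rsid), r2, str(row.chrom), pos))
    return out


def write_ld_table(records: Iterable[LdRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment("LD proxies; columns: lead_rsid proxy_rsid r2 chrom pos (1-based)"))
        fh.write("lead_rsid\tproxy_rsid\tr2\tchrom\tpos\n")
        for r in records:
            fh.write(f"{r.lead_rsid}\t{r.proxy_rsid}\t{r.r2:.6g}\t{r.chrom}\t{r.pos}\n")


# ---------------------------------------------------------------------------
# DEG / splicing / QTL tables
# ---------------------------------------------------------------------------

def read_deg_table(path) -> List[DegRecord]:
    """Read a DESeq2-result-style table: gene_id, log2FoldChange, pvalue, padj."""
    df = _read_tsv(path, dtype={"gene_id": str})
    _require_columns(df, ["gene_id", "log2FoldChange", "pvalue", "padj"], path)
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                DegRecord(
                    gene_id=str(row.gene_id),
                    log2fc=float(row.log2FoldChange),
                    pvalue=None if pd.isna(row.pvalue) else float(row.pvalue),
                    padj=None if pd.isna(row.padj) else float(row.padj),
                )
            )
        except ValidationError as exc:
            raise RecordError(str(exc), line=idx, path=path) from exc
    return out


def write_deg_table(records: Iterable[DegRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment("DESeq2-style DEG results; columns: gene_id log2FoldChange pvalue padj"))
        fh.write("gene_id\tlog2FoldChange\tpvalue\tpadj\n")
        for r in records:
            pv = "" if r.pvalue is None else f"{r.pvalue:.10g}"
            pa = "" if r.padj is None else f"{r.padj:.10g}"
            fh.write(f"{r.gene_id}\t{r.log2fc:.10g}\t{pv}\t{pa}\n")


def read_splice_table(path, event_type: Optional[str] = None) -> List[SpliceEvent]:
    """Read an rMATS-style event table (GeneID, IncLevelDifference, FDR).

    The event type is implied by the file name stem (SE.tsv, RI.tsv, ...)
    unless given explicitly.
    """
    path = Path(path)
    if event_type is None:
        event_type = path.stem.split(".")[0].upper()
    df = _read_tsv(path, dtype={"GeneID": str})
    _require_columns(df, ["GeneID", "IncLevelDifference", "FDR"], path)
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                SpliceEvent(
                    gene_id=str(row.GeneID),
                    event_type=event_type,
                    inc_level_diff=float(row.IncLevelDifference),
                    fdr=float(row.FDR),
                )
            )
        except ValidationError as exc:
            raise RecordError(str(exc), line=idx, path=path) from exc
    return out


def write_splice_table(events: Iterable[SpliceEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment("rMATS-style events; columns: GeneID IncLevelDifference FDR"))
        fh.write("GeneID\tIncLevelDifference\tFDR\n")
        for e in events:
            fh.write(f"{e.gene_id}\t{e.inc_level_diff:.6g}\t{e.fdr:.10g}\n")


def read_qtl_table(path) -> List[QtlRecord]:
    """Read a snpXplorer-style QTL annotation table: rsid, target_gene, qtl_type."""
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ["rsid", "target_gene", "qtl_type"], path)
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(QtlRecord(str(row.rsid), str(row.target_gene), str(row.qtl_type)))
        except ValidationError as exc:
            raise RecordError(str(exc), line=idx, path=path) from exc
    return out


def write_qtl_table(records: Iterable[QtlRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment("QTL annotations; columns: rsid target_gene qtl_type"))
        fh.write("rsid\ttarget_gene\tqtl_type\n")
        for r in records:
            fh.write(f"{r.rsid}\t{r.target_gene}\t{r.qtl_type}\n")


# ---------------------------------------------------------------------------
# chromosome sizes / FASTA
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict:
    """Read a two-column UCSC chrom.sizes file into an ordered dict."""
    sizes = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise RecordError("expected two columns (chrom, size)", line=n, path=path)
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_fasta(genome: dict, path, width: int = 70) -> None:
    """Write {chrom: sequence} to FASTA with fixed line width."""
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
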
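"""Synthetic study generator with planted, recoverable structure.

Emulates every input table the pipeline consumes — toy genome FASTA, GTF
transcript models, a differential m6A peak table, per-trait lead-SNP and LD
tables, DEG / splicing / QTL tables — with a truth record listing exactly
what was planted: which peaks are true DMPs and in which direction, which
trait SNPs were placed inside increased DMPs, which peaks carry a DRACH
site, and which genes were planted as QTL-linked DEG/DSG candidates.

Randomness policy: a single master seed derives one named substream per
component (genome, transcripts, peaks, drach, snps, ld, deg, splice, qtl),
so changing a parameter that only one component reads leaves the others'
output byte-identical.

Planting model for SNP enrichment: with increased-DMP bases D on a genome
of L bases and enrichment multiplier e, each lead SNP falls inside an
increased DMP with probability q = min(1, e * D / L) (uniform over DMP
bases), otherwise uniformly over non-DMP bases. At e = 1 this is exactly a
uniform draw over the genome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .io_formats import (
    LdRecord,
    write_chrom_sizes,
    write_deg_table,
    write_fasta,
    write_gtf,
    write_ld_table,
    write_peak_table,
    write_qtl_table,
    write_snp_table,
    write_splice_table,
)
from .peak_analysis import DRACH_RE, reverse_complement
from .stats import benjamini_hochberg
from .types import (
    ConfigurationError,
    DegRecord,
    DiffPeak,
    GenomicInterval,
    QtlRecord,
    Snp,
    SpliceEvent,
    TranscriptModel,
    ValidationError,
)
from .variant_sets import VariantSet, expand_ld

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STREAMS = ("genome", "transcripts", "peaks", "drach", "snps", "ld", "deg", "splice", "qtl")
PEAK_PLACEMENTS = ("exonic", "5utr", "cds", "3utr")


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Sizes are deliberately toy-scale (a few hundred kb per chromosome, a few
    hundred transcripts and peaks) so that hundreds of replicate studies run
    in seconds while every downstream statistic still has resolution.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 500_000
    n_transcripts: int = 500
    n_peaks: int = 900
    frac_dmp_increased: float = 0.30
    frac_dmp_decreased: float = 0.15
    n_lead_snps: int = 350
    ld_block_size_mean: float = 4.0
    planted_enrichment: float = 1.0
    chrom_skew: Optional[Dict[str, float]] = None
    drach_plant_prob: float = 0.7
    n_traits: int = 2
    planted_trait: int = 0
    peak_placement: str = "exonic"
    n_candidate_genes: int = 4
    ld_max_dist: int = 50_000
    r2_threshold: float = 0.8

    def __post_init__(self):
        if self.frac_dmp_increased < 0 or self.frac_dmp_decreased < 0:
            raise ConfigurationError("DMP fractions must be >= 0")
        if self.frac_dmp_increased + self.frac_dmp_decreased > 1:
            raise ConfigurationError("DMP fractions must sum to <= 1")
        if self.planted_enrichment < 1:
            raise ConfigurationError("planted_enrichment must be >= 1")
        if self.peak_placement not in PEAK_PLACEMENTS:
            raise ConfigurationError(f"peak_placement must be one of {PEAK_PLACEMENTS}")
        for name in ("n_chroms", "chrom_length", "n_transcripts", "n_peaks",
                     "n_lead_snps", "n_traits"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_traits < 1:
            raise ConfigurationError("n_traits must be >= 1")
        if not (0 <= self.planted_trait < self.n_traits):
            raise ConfigurationError("planted_trait out of range")
        if not (0.0 <= self.drach_plant_prob <= 1.0):
            raise ConfigurationError("drach_plant_prob must be in [0, 1]")

    @property
    def trait_names(self) -> List[str]:
        return [f"trait_{i + 1}" for i in range(self.n_traits)]

    @property
    def planted_trait_name(self) -> str:
        return self.trait_names[self.planted_trait]


@dataclass
class SimTruth:
    """What was planted; every count is recoverable from the emitted files."""

    peak_direction: Dict[str, str]
    drach_planted: Dict[str, bool]
    snps_planted_in_dmp: Dict[str, List[str]]
    overlap_rsids: Dict[str, List[str]]
    candidate_genes: List[dict]
    deg_only_genes: Dict[str, str]


@dataclass
class StudyBundle:
    """In-memory simulated study; ``write`` emits the on-disk file set."""

    config: SimConfig
    chrom_sizes: Dict[str, int]
    genome: Dict[str, str]
    transcripts: List[TranscriptModel]
    peaks: List[DiffPeak]
    leads: Dict[str, List[Snp]]
    ld_records: Dict[str, List[LdRecord]]
    degs: List[DegRecord]
    splice_events: List[SpliceEvent]
    qtls: List[QtlRecord]
    truth: SimTruth

    def variant_set(self, trait: Optional[str] = None, r2_min: Optional[float] = None) -> VariantSet:
        trait = trait or self.config.planted_trait_name
        r2_min = self.config.r2_threshold if r2_min is None else r2_min
        return expand_ld(self.leads[trait], self.ld_records[trait], r2_min=r2_min, trait=trait)

    def true_regions(self, direction: str) -> List[GenomicInterval]:
        return [
            p.interval for p in self.peaks
            if self.truth.peak_direction[p.peak_id] == direction
        ]

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        paths["chrom_sizes"] = outdir / "genome.sizes"
        write_chrom_sizes(self.chrom_sizes, paths["chrom_sizes"])
        paths["gtf"] = outdir / "annotation.gtf"
        write_gtf(self.transcripts, paths["gtf"])
        paths["peaks"] = outdir / "peaks.tsv"
        write_peak_table(self.peaks, paths["peaks"])
        for trait in self.config.trait_names:
            paths[f"snps_{trait}"] = outdir / f"snps_{trait}.tsv"
            write_snp_table(self.leads[trait], paths[f"snps_{trait}"], trait=trait)
            paths[f"ld_{trait}"] = outdir / f"ld_{trait}.tsv"
            write_ld_table(self.ld_records[trait], paths[f"ld_{trait}"])
        paths["deg"] = outdir / "deg.tsv"
        write_deg_table(self.degs, paths["deg"])
        splice_dir = outdir / "splice"
        splice_dir.mkdir(exist_ok=True)
        for etype in ("SE", "RI", "A5SS", "A3SS", "MXE"):
            paths[f"splice_{etype}"] = splice_dir / f"{etype}.tsv"
            write_splice_table(
                [e for e in self.splice_events if e.event_type == etype],
                paths[f"splice_{etype}"],
            )
        paths["qtl"] = outdir / "qtl.tsv"
        write_qtl_table(self.qtls, paths["qtl"])
        paths["truth"] = outdir / "truth.tsv"
        self._write_truth(paths["truth"])
        paths["manifest"] = outdir / "sim_manifest.json"
        with open(paths["manifest"], "w") as fh:
            cfg = asdict(self.config)
            counts = {
                "n_transcripts": len(self.transcripts),
                "n_peaks": len(self.peaks),
                "n_leads": {t: len(v) for t, v in self.leads.items()},
                "n_ld_rows": {t: len(v) for t, v in self.ld_records.items()},
                "n_deg_rows": len(self.degs),
                "n_splice_events": len(self.splice_events),
                "n_qtl_rows": len(self.qtls),
            }
            json.dump({"config": cfg, "counts": counts}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    def _write_truth(self, path) -> None:
        from . import __version__

        with open(path, "w") as fh:
            fh.write(f"# m6avar v{__version__} | truth record; columns: kind key value\n")
            fh.write("kind\tkey\tvalue\n")
            for pid in sorted(self.truth.peak_direction):
                fh.write(f"peak_direction\t{pid}\t{self.truth.peak_direction[pid]}\n")
            for pid in sorted(self.truth.drach_planted):
                fh.write(f"drach_planted\t{pid}\t{self.truth.drach_planted[pid]}\n")
            for trait, rsids in sorted(self.truth.snps_planted_in_dmp.items()):
                fh.write(f"snps_planted_in_dmp\t{trait}\t{','.join(rsids)}\n")
            for trait, rsids in sorted(self.truth.overlap_rsids.items()):
                fh.write(f"overlap_rsids\t{trait}\t{','.join(rsids)}\n")
            for cand in self.truth.candidate_genes:
                fh.write(f"candidate_gene\t{cand['gene_id']}\t{json.dumps(cand, sort_keys=True)}\n")
            for g, d in sorted(self.truth.deg_only_genes.items()):
                fh.write(f"deg_only_gene\t{g}\t{d}\n")


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _substreams(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _make_genome(cfg: SimConfig, rng) -> Dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=cfg.chrom_length)]
        for i in range(cfg.n_chroms)
    }


def _make_transcripts(cfg: SimConfig, rng) -> List[TranscriptModel]:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cursors = {c: int(rng.integers(200, 600)) for c in chroms}
    models: List[TranscriptModel] = []
    exhausted = set()
    ci = 0
    while len(models) < cfg.n_transcripts:
        if len(exhausted) == len(chroms):
            raise ConfigurationError(
                f"genome too small: placed {len(models)} of {cfg.n_transcripts} transcripts"
            )
        chrom = chroms[ci % len(chroms)]
        ci += 1
        if chrom in exhausted:
            continue
        n_exons = int(rng.integers(1, 5))
        exon_lens = rng.integers(200, 700, size=n_exons)
        intron_lens = rng.integers(80, 400, size=max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom]
        if start + span > cfg.chrom_length - 200:
            exhausted.add(chrom)
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cursors[chrom] = pos + int(rng.integers(300, 900))
        k = len(models) + 1
        ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
        # UTR/CDS split in transcript (mRNA) coordinates: 5'UTR ~15%, 3'UTR ~35%
        E = int(exon_lens.sum())
        u5 = max(1, int(round(0.15 * E)))
        u3 = max(1, int(round(0.35 * E)))
        model = TranscriptModel(
            transcript_id=f"T{k:04d}", gene_id=f"G{k:04d}", gene_name=f"GENE{k:04d}",
            chrom=chrom, strand=strand, exons=ivs,
        )
        g_a = model.to_genomic(u5)
        g_b = model.to_genomic(E - u3 - 1)
        lo, hi = (g_a, g_b) if g_a <= g_b else (g_b, g_a)
        models.append(
            TranscriptModel(
                transcript_id=model.transcript_id, gene_id=model.gene_id,
                gene_name=model.gene_name, chrom=chrom, strand=strand,
                exons=ivs, cds_start=lo, cds_end=hi + 1,
            )
        )
    return models


def transcript_segment_pieces(t: TranscriptModel, which: str) -> List[GenomicInterval]:
    """Genomic pieces of one transcript segment (exonic, 5utr, cds, 3utr)."""
    if which == "exonic":
        return list(t.exons)
    if not t.is_coding:
        return []
    lo, hi = t.cds_transcript_span()
    L = t.exonic_length
    rng_t = {"5utr": (0, lo), "cds": (lo, hi), "3utr": (hi, L)}[which]
    a, b = rng_t
    if a >= b:
        return []
    # map the transcript-coordinate range to genomic pieces exon by exon
    g = sorted(t.to_genomic(x) for x in (a, b - 1))
    glo, ghi = g[0], g[1] + 1
    out = []
    for ex in t.exons:
        s, e = max(ex.start, glo), min(ex.end, ghi)
        if s < e:
            out.append(GenomicInterval(t.chrom, s, e, t.strand))
    return out


def _make_peaks(cfg: SimConfig, rng, transcripts) -> Tuple[List[DiffPeak], Dict[str, str]]:
    pieces: List[GenomicInterval] = []
    for t in transcripts:
        pieces.extend(transcript_segment_pieces(t, cfg.peak_placement))
    if not pieces and cfg.n_peaks > 0:
        raise ConfigurationError(f"no genomic space for peak_placement={cfg.peak_placement}")
    weights = np.asarray([len(p) for p in pieces], dtype=float)
    weights /= weights.sum()
    occupied: Dict[str, IntervalTree] = {}
    intervals: List[GenomicInterval] = []
    for _ in range(cfg.n_peaks):
        placed = False
        for _attempt in range(200):
            piece = pieces[int(rng.choice(len(pieces), p=weights))]
            length = int(np.clip(round(rng.lognormal(np.log(200.0), 0.5)), 50, 2000))
            length = min(length, len(piece))
            if length < 30:
                continue
            start = piece.start + int(rng.integers(0, len(piece) - length + 1))
            tree = occupied.setdefault(piece.chrom, IntervalTree())
            if tree.overlap(start - 10, start + length + 10):
                continue
            tree.addi(start, start + length)
            intervals.append(GenomicInterval(piece.chrom, start, start + length, piece.strand))
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                f"could not place {cfg.n_peaks} non-overlapping peaks "
                f"(placed {len(intervals)}); reduce n_peaks or enlarge the genome"
            )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))

    n = len(intervals)
    n_inc = int(round(cfg.frac_dmp_increased * n))
    n_dec = int(round(cfg.frac_dmp_decreased * n))
    order = rng.permutation(n)
    direction = np.array(["none"] * n, dtype=object)
    direction[order[:n_inc]] = "increased"
    direction[order[n_inc : n_inc + n_dec]] = "decreased"
    log2fc = rng.normal(0.0, 0.3, size=n)
    pvals = rng.uniform(0.2, 1.0, size=n)
    is_dmp = direction != "none"
    log2fc[direction == "increased"] = rng.uniform(0.8, 3.0, size=n_inc)
    log2fc[direction == "decreased"] = -rng.uniform(0.8, 3.0, size=n_dec)
    pvals[is_dmp] = 10.0 ** rng.uniform(-8, -6, size=int(is_dmp.sum()))
    padj = benjamini_hochberg(pvals)

    peaks, truth = [], {}
    for i, iv in enumerate(intervals):
        pid = f"peak_{i + 1:04d}"
        peaks.append(DiffPeak(interval=iv, log2fc=float(log2fc[i]),
                              pvalue=float(pvals[i]), padj=float(padj[i]), peak_id=pid))
        truth[pid] = str(direction[i])
    return peaks, truth


def _scrub_drach(seq: str) -> str:
    """Destroy every DRACH match by mutating its methylatable A to C."""
    s = list(seq)
    while True:
        m = DRACH_RE.search("".join(s))
        if m is None:
            return "".join(s)
        s[m.start() + 2] = "C"


def _apply_drach(cfg: SimConfig, rng, genome, peaks) -> Dict[str, bool]:
    planted: Dict[str, bool] = {}
    for p in peaks:
        iv = p.interval
        arr = genome[iv.chrom]
        seq = arr[iv.start : iv.end].tobytes().decode()
        oriented = reverse_complement(seq) if iv.strand == "-" else seq
        oriented = _scrub_drach(oriented)
        plant = bool(rng.random() < cfg.drach_plant_prob)
        if plant and len(oriented) >= 5:
            k = int(rng.integers(0, len(oriented) - 4))
            oriented = oriented[:k] + "GGACT" + oriented[k + 5 :]
        planted[p.peak_id] = plant and len(oriented) >= 5
        back = reverse_complement(oriented) if iv.strand == "-" else oriented
        arr[iv.start : iv.end] = np.frombuffer(back.encode(), dtype=np.uint8)
    return planted


class _RegionIndex:
    """Merged region membership + uniform sampling over covered bases."""

    def __init__(self, regions: Sequence[GenomicInterval]):
        by_chrom: Dict[str, list] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        self.merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        flat = []
        for c, ivs in by_chrom.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.asarray([s for s, _ in merged], dtype=np.int64)
            ends = np.asarray([e for _, e in merged], dtype=np.int64)
            self.merged[c] = (starts, ends)
            for s, e in merged:
                flat.append((c, s, e))
        self.flat = flat
        self.lengths = np.asarray([e - s for _, s, e in flat], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(self.lengths)])
        self.total = int(self.cum[-1])

    def contains(self, chrom: str, pos0: int) -> bool:
        g = self.merged.get(chrom)
        if g is None:
            return False
        starts, ends = g
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def nth_base(self, j: int) -> Tuple[str, int]:
        i = int(np.searchsorted(self.cum, j, side="right")) - 1
        chrom, s, _ = self.flat[i]
        return chrom, s + (j - int(self.cum[i]))


def _make_snps(cfg: SimConfig, rng, inc_index: _RegionIndex,
               chrom_sizes: Dict[str, int]) -> Tuple[Dict[str, List[Snp]], Dict[str, List[str]], "object"]:
    L = sum(chrom_sizes.values())
    D = inc_index.total
    chroms = list(chrom_sizes)
    sizes = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    if cfg.chrom_skew is not None:
        w = np.asarray([cfg.chrom_skew.get(c, 1.0) for c in chroms], dtype=float)
        bg_weights = (w * sizes) / (w * sizes).sum()
    else:
        bg_weights = sizes / sizes.sum()
    leads: Dict[str, List[Snp]] = {}
    planted: Dict[str, List[str]] = {}
    counter = 0
    for ti, trait in enumerate(cfg.trait_names):
        e = cfg.planted_enrichment if ti == cfg.planted_trait else 1.0
        if e > 1 and D == 0:
            raise ConfigurationError("planted_enrichment > 1 but there are no increased-DMP bases")
        q = min(1.0, e * D / L) if L else 0.0
        leads[trait] = []
        planted[trait] = []
        for _ in range(cfg.n_lead_snps):
            counter += 1
            rsid = f"rs{100000 + counter}"
            if rng.random() < q:
                chrom, pos0 = inc_index.nth_base(int(rng.integers(0, D)))
                planted[trait].append(rsid)
            else:
                while True:
                    chrom = chroms[int(rng.choice(len(chroms), p=bg_weights))]
                    pos0 = int(rng.integers(0, chrom_sizes[chrom]))
                    if not inc_index.contains(chrom, pos0):
                        break
            leads[trait].append(Snp(rsid=rsid, chrom=chrom, pos=pos0 + 1))
    return leads, planted, counter


def _make_ld(cfg: SimConfig, rng, leads: Dict[str, List[Snp]],
             chrom_sizes: Dict[str, int], counter: int) -> Dict[str, List[LdRecord]]:
    out: Dict[str, List[LdRecord]] = {}
    for trait in cfg.trait_names:
        rows: List[LdRecord] = []
        for lead in leads[trait]:
            k = int(rng.poisson(cfg.ld_block_size_mean))
            for _ in range(k):
                counter += 1
                off = 0
                while off == 0:
                    off = int(rng.integers(-cfg.ld_max_dist, cfg.ld_max_dist + 1))
                pos = int(np.clip(lead.pos + off, 1, chrom_sizes[lead.chrom]))
                r2 = float(rng.uniform(0.5, 1.0))
                rows.append(LdRecord(lead.rsid, f"rs{100000 + counter}", r2, lead.chrom, pos))
        out[trait] = rows
    return out


def _plant_downstream(cfg: SimConfig, rng_deg, rng_splice, rng_qtl,
                      transcripts, overlap_rsids: List[str], all_rsids: List[str]):
    genes = [t.gene_id for t in transcripts]
    n_cand = min(cfg.n_candidate_genes, len(overlap_rsids), len(genes))
    if n_cand < cfg.n_candidate_genes:
        logger.info(
            "reduced planted candidate genes from %d to %d (limited by %d overlap SNPs)",
            cfg.n_candidate_genes, n_cand, len(overlap_rsids),
        )
    cand_genes = [genes[i] for i in sorted(rng_qtl.choice(len(genes), size=n_cand, replace=False))]
    cand_rsids = [overlap_rsids[i] for i in sorted(rng_qtl.choice(len(overlap_rsids), size=n_cand, replace=False))] if n_cand else []

    qtls: List[QtlRecord] = []
    candidates: List[dict] = []
    for i, (g, rsid) in enumerate(zip(cand_genes, cand_rsids)):
        qtypes = [["eQTL"], ["sQTL"], ["eQTL", "sQTL"]][i % 3]
        for qt in qtypes:
            qtls.append(QtlRecord(rsid=rsid, target_gene=g, qtl_type=qt))
        candidates.append({"gene_id": g, "qtl_types": qtypes, "rsids": [rsid]})
    # decoy QTL rows: rsids outside the overlap set, random target genes
    decoy_pool = [r for r in all_rsids if r not in set(overlap_rsids)]
    n_decoys = min(10, len(decoy_pool))
    for i in sorted(rng_qtl.choice(len(decoy_pool), size=n_decoys, replace=False)):
        g = genes[int(rng_qtl.integers(0, len(genes)))]
        qtls.append(QtlRecord(rsid=decoy_pool[i], target_gene=g,
                              qtl_type="eQTL" if rng_qtl.random() < 0.5 else "sQTL"))

    # DEG table: planted candidates are significant; a few extra DEG-only genes
    cand_set = {c["gene_id"] for c in candidates}
    non_cand = [g for g in genes if g not in cand_set]
    n_extra = min(20, len(non_cand))
    extra = {non_cand[i] for i in rng_deg.choice(len(non_cand), size=n_extra, replace=False)}
    lfc = {}
    pv = {}
    deg_only = {}
    for g in genes:
        if g in cand_set or g in extra:
            sign = 1.0 if rng_deg.random() < 0.5 else -1.0
            lfc[g] = sign * float(rng_deg.uniform(1.0, 2.5))
            pv[g] = 10.0 ** float(rng_deg.uniform(-10, -4))
        else:
            lfc[g] = float(rng_deg.normal(0.0, 0.2))
            pv[g] = float(rng_deg.uniform(0.3, 1.0))
    padj = benjamini_hochberg([pv[g] for g in genes])
    degs = [DegRecord(gene_id=g, log2fc=lfc[g], pvalue=pv[g], padj=float(a))
            for g, a in zip(genes, padj)]
    for g in extra:
        deg_only[g] = "up" if lfc[g] > 0 else "down"
    for c in candidates:
        c["deg_direction"] = "up" if lfc[c["gene_id"]] > 0 else "down"

    # splicing: significant events for every other candidate, plus decoy events
    events: List[SpliceEvent] = []
    etypes = ("SE", "RI", "A5SS", "A3SS", "MXE")
    for i, c in enumerate(candidates):
        c["splice_events"] = []
        if i % 2 == 0:
            et = etypes[int(rng_splice.integers(0, len(etypes)))]
            events.append(SpliceEvent(
                gene_id=c["gene_id"], event_type=et,
                inc_level_diff=float(rng_splice.uniform(0.1, 0.6)) * (1 if rng_splice.random() < 0.5 else -1),
                fdr=10.0 ** float(rng_splice.uniform(-6, -3)),
            ))
            c["splice_events"].append(et)
    for _ in range(30):
        g = genes[int(rng_splice.integers(0, len(genes)))]
        if g in cand_set:
            continue
        events.append(SpliceEvent(
            gene_id=g, event_type=etypes[int(rng_splice.integers(0, len(etypes)))],
            inc_level_diff=float(rng_splice.uniform(-0.3, 0.3)),
            fdr=float(rng_splice.uniform(0.2, 1.0)),
        ))
    return qtls, candidates, degs, deg_only, events


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate one complete in-memory study; deterministic for a fixed seed."""
    rngs = _substreams(config.seed)
    genome_arrays = _make_genome(config, rngs["genome"])
    chrom_sizes = {c: len(a) for c, a in genome_arrays.items()}
    transcripts = _make_transcripts(config, rngs["transcripts"])
    peaks, peak_truth = _make_peaks(config, rngs["peaks"], transcripts)
    drach_truth = _apply_drach(config, rngs["drach"], genome_arrays, peaks)

    inc_regions = [p.interval for p in peaks if peak_truth[p.peak_id] == "increased"]
    inc_index = _RegionIndex(inc_regions)
    leads, planted, counter = _make_snps(config, rngs["snps"], inc_index, chrom_sizes)
    ld_records = _make_ld(config, rngs["ld"], leads, chrom_sizes, counter)

    # realized overlap (leads + passing proxies inside increased DMPs)
    overlap: Dict[str, List[str]] = {}
    all_rsids: List[str] = []
    for trait in config.trait_names:
        vset = expand_ld(leads[trait], ld_records[trait],
                         r2_min=config.r2_threshold, trait=trait)
        overlap[trait] = sorted(
            s.rsid for s in vset if inc_index.contains(s.chrom, s.pos0)
        )
        all_rsids.extend(s.rsid for s in vset)

    qtls, candidates, degs, deg_only, events = _plant_downstream(
        config, rngs["deg"], rngs["splice"], rngs["qtl"], transcripts,
        overlap[config.planted_trait_name], all_rsids,
    )

    truth = SimTruth(
        peak_direction=peak_truth,
        drach_planted=drach_truth,
        snps_planted_in_dmp=planted,
        overlap_rsids=overlap,
        candidate_genes=candidates,
        deg_only_genes=deg_only,
    )
    genome = {c: a.tobytes().decode() for c, a in genome_arrays.items()}
    return StudyBundle(
        config=config, chrom_sizes=chrom_sizes, genome=genome,
        transcripts=transcripts, peaks=peaks, leads=leads, ld_records=ld_records,
        degs=degs, splice_events=events, qtls=qtls, truth=truth,
    )


def simulate_null_snp_sets(
    snps: Sequence[Snp],
    m: int,
    n_sets: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> List[List[Snp]]:
    """Draw ``n_sets`` uniform without-replacement subsets of size ``m``.

    Subsets are independent across list entries given the RNG stream; each
    preserves the original SNP order.
    """
    snps = list(snps)
    if m > len(snps):
        raise ValidationError(f"cannot draw subset of {m} from {len(snps)} SNPs")
    if m < 0:
        raise ValidationError("m must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for _ in range(n_sets):
        idx = np.sort(rng.choice(len(snps), size=m, replace=False))
        out.append([snps[i] for i in idx])
    return out
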
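"""Candidate-gene triage: m6A-overlapping SNPs x QTLs x DEGs x splicing.

SNPs found inside differential m6A peaks are passed through an eQTL/sQTL
annotation table; their target genes are then cross-referenced against
differential-expression calls (padj < 0.05 and |log2FC| > 0.58, both strict
per the thresholds applied upstream by DESeq2-style analyses) and
differential-splicing events (FDR < 0.05, strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .types import DegRecord, QtlRecord, Snp, SpliceEvent

logger = logging.getLogger(__name__)

DEFAULT_DEG_ALPHA = 0.05
DEFAULT_DEG_LFC_MIN = 0.58
DEFAULT_SPLICE_FDR_MAX = 0.05


@dataclass
class CandidateGene:
    """A gene linked to >= 1 m6A-overlapping SNP through a QTL annotation."""

    gene_id: str
    qtl_types: Set[str]
    supporting_snps: List[str]
    deg_status: str = "ns"  # up | down | ns
    splice_events: List[Tuple[str, float, float]] = field(default_factory=list)
    # (event_type, fdr, inc_level_diff)


def filter_degs(
    degs: Sequence[DegRecord],
    alpha: float = DEFAULT_DEG_ALPHA,
    lfc_min: float = DEFAULT_DEG_LFC_MIN,
) -> Tuple[List[str], List[str]]:
    """Up/down DEG gene lists: padj < alpha (strict) and |log2FC| > lfc_min (strict).

    Records without an adjusted p-value are excluded (logged).
    """
    up, down = [], []
    n_missing = 0
    for r in degs:
        if r.padj is None:
            n_missing += 1
            continue
        if r.padj < alpha and r.log2fc > lfc_min:
            up.append(r.gene_id)
        elif r.padj < alpha and r.log2fc < -lfc_min:
            down.append(r.gene_id)
    if n_missing:
        logger.info("%d DEG records without padj excluded", n_missing)
    return up, down


def filter_splice_events(
    events: Sequence[SpliceEvent],
    fdr_max: float = DEFAULT_SPLICE_FDR_MAX,
) -> Dict[Tuple[str, str], List[SpliceEvent]]:
    """Significant events (FDR < fdr_max, strict), grouped by (gene, event_type)."""
    out: Dict[Tuple[str, str], List[SpliceEvent]] = {}
    for e in events:
        if e.fdr < fdr_max:
            out.setdefault((e.gene_id, e.event_type), []).append(e)
    return out


def build_candidates(
    overlap_snps: Sequence[Snp],
    qtl_table: Sequence[QtlRecord],
    deg_up: Sequence[str],
    deg_down: Sequence[str],
    splice_events: Dict[Tuple[str, str], List[SpliceEvent]],
) -> List[CandidateGene]:
    """Join QTL-linked target genes of overlapping SNPs with DEG/DSG status.

    QTL rows whose rsid is not among the overlapping SNPs are ignored
    (logged). One CandidateGene per target gene; output sorted by
    (number of QTL types desc, number of supporting SNPs desc, gene_id).
    """
    overlap_rsids = {s.rsid for s in overlap_snps}
    up, down = set(deg_up), set(deg_down)
    genes: Dict[str, CandidateGene] = {}
    n_skipped = 0
    for q in qtl_table:
        if q.rsid not in overlap_rsids:
            n_skipped += 1
            continue
        cand = genes.get(q.target_gene)
        if cand is None:
            cand = genes[q.target_gene] = CandidateGene(
                gene_id=q.target_gene, qtl_types=set(), supporting_snps=[]
            )
        cand.qtl_types.add(q.qtl_type)
        if q.rsid not in cand.supporting_snps:
            cand.supporting_snps.append(q.rsid)
    if n_skipped:
        logger.info("%d QTL rows for non-overlapping rsids ignored", n_skipped)

    for g, cand in genes.items():
        cand.deg_status = "up" if g in up else "down" if g in down else "ns"
        cand.supporting_snps.sort()
        for (gene_id, etype), evs in sorted(splice_events.items()):
            if gene_id == g:
                for e in sorted(evs, key=lambda e: (e.fdr, -abs(e.inc_level_diff))):
                    cand.splice_events.append((etype, e.fdr, e.inc_level_diff))

    return sorted(
        genes.values(),
        key=lambda c: (-len(c.qtl_types), -len(c.supporting_snps), c.gene_id),
    )


def write_candidate_table(candidates: Sequence[CandidateGene], path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(
            f"# m6avar v{__version__} | candidate genes; columns: gene_id qtl_types "
            "n_supporting_snps supporting_snps deg_status splice_events\n"
        )
        fh.write("gene_id\tqtl_types\tn_supporting_snps\tsupporting_snps\tdeg_status\tsplice_events\n")
        for c in candidates:
            ev = ";".join(f"{t}:fdr={f:.3g}:dpsi={d:.3g}" for t, f, d in c.splice_events)
            fh.write(
                f"{c.gene_id}\t{','.join(sorted(c.qtl_types))}\t{len(c.supporting_snps)}\t"
                f"{','.join(c.supporting_snps)}\t{c.deg_status}\t{ev}\n"
            )
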
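"""Trait-labelled variant sets: GWAS lead SNPs plus LD expansion.

A variant set is the unit of enrichment testing: all lead SNPs reported for
a trait together with their LD proxies at r-squared >= a threshold
(inclusive, default 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import pandas as pd

from .io_formats import LdRecord
from .types import Snp, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.8


@dataclass
class VariantSet:
    """A trait-labelled collection of SNPs (leads and passing LD proxies)."""

    trait: str
    snps: List[Snp] = field(default_factory=list)

    def __post_init__(self):
        rsids = [s.rsid for s in self.snps]
        if len(rsids) != len(set(rsids)):
            raise ValidationError(f"{self.trait}: duplicate rsids within variant set")

    @property
    def n_lead(self) -> int:
        return sum(1 for s in self.snps if s.is_lead)

    @property
    def n_total(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __len__(self):
        return len(self.snps)


def expand_ld(
    leads: Sequence[Snp],
    ld_table: Iterable[LdRecord],
    r2_min: float = DEFAULT_R2_MIN,
    trait: str = "trait",
) -> VariantSet:
    """Expand lead SNPs with LD proxies at r2 >= ``r2_min`` (inclusive).

    Proxies reachable from two leads are kept once, attributed to the
    higher-r2 lead (ties broken by lexicographic lead rsid). LD rows whose
    lead is not in ``leads`` are logged and skipped. A proxy whose rsid
    collides with an existing SNP at a different position is a hard error.
    """
    if not leads:
        raise ValidationError("empty lead SNP list")
    if not (0.0 <= r2_min <= 1.0):
        raise ValidationError(f"r2_min must be in [0, 1], got {r2_min}")

    positions = {}
    out: dict = {}
    for lead in leads:
        if not lead.is_lead:
            raise ValidationError(f"{lead.rsid}: non-lead SNP passed as lead")
        if lead.rsid in positions and positions[lead.rsid] != (lead.chrom, lead.pos):
            raise ValidationError(f"duplicate lead rsid {lead.rsid} with conflicting position")
        positions[lead.rsid] = (lead.chrom, lead.pos)
        out[lead.rsid] = lead

    lead_rsids = set(out)
    best: dict = {}  # proxy_rsid -> LdRecord with winning attribution
    for rec in ld_table:
        if rec.lead_rsid not in lead_rsids:
            logger.info("LD row for unknown lead %s skipped", rec.lead_rsid)
            continue
        if rec.r2 < r2_min:
            continue
        if rec.proxy_rsid in lead_rsids:
            continue  # already present as a lead (r2 = 1 by definition)
        prev = best.get(rec.proxy_rsid)
        if prev is not None and (prev.chrom, prev.pos) != (rec.chrom, rec.pos):
            raise ValidationError(f"proxy {rec.proxy_rsid} appears at conflicting positions")
        if prev is None or _wins(rec, prev):
            best[rec.proxy_rsid] = rec

    for rsid, rec in best.items():
        if rsid in positions and positions[rsid] != (rec.chrom, rec.pos):
            raise ValidationError(f"proxy {rsid} conflicts with existing SNP position")
        out[rsid] = Snp(
            rsid=rsid, chrom=rec.chrom, pos=rec.pos,
            is_lead=False, lead_rsid=rec.lead_rsid, r2=rec.r2,
        )

    snps = sorted(out.values(), key=lambda s: (not s.is_lead, s.rsid))
    return VariantSet(trait=trait, snps=snps)


def _wins(rec: LdRecord, prev: LdRecord) -> bool:
    # higher r2 wins; ties broken by lexicographically smaller lead rsid
    if rec.r2 != prev.r2:
        return rec.r2 > prev.r2
    return rec.lead_rsid < prev.lead_rsid


def summarize_sets(sets: Sequence[VariantSet]) -> pd.DataFrame:
    """One row per trait: (trait, n_lead, n_total)."""
    return pd.DataFrame(
        [{"trait": s.trait, "n_lead": s.n_lead, "n_total": s.n_total} for s in sets],
        columns=["trait", "n_lead", "n_total"],
    )
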
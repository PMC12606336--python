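"""Variant Set Enrichment Analysis with a random-region permutation null.

The observed statistic is the number of SNPs of a trait's variant set that
fall inside a region set (typically the increased or decreased differential
m6A peaks). The null redraws the regions: each permutation places the same
number of regions, each keeping its original length and chromosome, at a
uniform random start, and recounts. Enrichment is summarized as a
permutation z-score and a fold change, with an add-one permutation p-value
and BH adjustment across all trait x direction tests of a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .stats import benjamini_hochberg, permutation_pvalue
from .types import ConfigurationError, GenomicInterval, Snp
from .variant_sets import VariantSet

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
_ES_CAP = np.finfo(float).max


@dataclass
class EnrichmentResult:
    """Result of one VSEA test (one trait x direction)."""

    trait: str
    direction: str
    observed: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    enrichment_score: float
    fold: float
    p_perm: float
    n_perm: int
    p_adj: Optional[float] = None
    degenerate: bool = False
    es_capped: bool = False


class _SnpPoints:
    """0-based SNP positions grouped by chromosome for vectorized counting."""

    def __init__(self, snps: Iterable[Snp]):
        by_chrom: Dict[str, list] = {}
        self.n = 0
        for s in snps:
            by_chrom.setdefault(s.chrom, []).append(s.pos0)
            self.n += 1
        self.by_chrom = {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}


def _group_regions(regions: Sequence[GenomicInterval]):
    by_chrom: Dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    return {
        c: (np.sort(np.asarray([s for s, _ in v], dtype=np.int64)),
            np.sort(np.asarray([e for _, e in v], dtype=np.int64)))
        for c, v in by_chrom.items()
    }


def _count_points(points: _SnpPoints, grouped) -> int:
    """Number of SNPs covered by >= 1 region (per-SNP, not per-pair)."""
    total = 0
    for chrom, pos in points.by_chrom.items():
        g = grouped.get(chrom)
        if g is None:
            continue
        starts, ends = g
        depth = np.searchsorted(starts, pos, side="right") - np.searchsorted(ends, pos, side="right")
        total += int(np.count_nonzero(depth > 0))
    return total


def count_overlaps(snps, regions: Sequence[GenomicInterval]) -> int:
    """Count SNPs falling in >= 1 region under the rule start <= pos-1 < end.

    ``snps`` may be a VariantSet or any iterable of Snp. A SNP inside two
    regions counts once.
    """
    return _count_points(_SnpPoints(snps), _group_regions(regions))


def sample_null_regions(
    template: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> List[GenomicInterval]:
    """Redraw each template region uniformly on its own chromosome.

    Region i keeps its length and chromosome; its start is uniform on
    [0, chrom_len - len] inclusive. Output regions may overlap each other.
    """
    out = []
    for r in template:
        clen = chrom_sizes.get(r.chrom)
        if clen is None:
            raise ConfigurationError(f"chromosome {r.chrom} missing from chrom_sizes")
        room = clen - len(r)
        if room < 0:
            raise ConfigurationError(
                f"template region of length {len(r)} exceeds {r.chrom} (length {clen})"
            )
        start = int(rng.integers(0, room + 1))
        out.append(GenomicInterval(r.chrom, start, start + len(r), r.strand))
    return out


def _null_sampler(template, chrom_sizes):
    """Vectorized per-permutation resampler over a fixed template."""
    chroms = [r.chrom for r in template]
    lengths = np.asarray([len(r) for r in template], dtype=np.int64)
    rooms = []
    for r in template:
        clen = chrom_sizes.get(r.chrom)
        if clen is None:
            raise ConfigurationError(f"chromosome {r.chrom} missing from chrom_sizes")
        if clen < len(r):
            raise ConfigurationError(
                f"template region of length {len(r)} exceeds {r.chrom} (length {clen})"
            )
        rooms.append(clen - len(r))
    rooms = np.asarray(rooms, dtype=np.int64)

    def draw(rng: np.random.Generator):
        starts = rng.integers(0, rooms + 1)
        by_chrom: Dict[str, list] = {}
        for c, s, l in zip(chroms, starts, lengths):
            by_chrom.setdefault(c, []).append((int(s), int(s + l)))
        return {
            c: (np.sort(np.asarray([s for s, _ in v], dtype=np.int64)),
                np.sort(np.asarray([e for _, e in v], dtype=np.int64)))
            for c, v in by_chrom.items()
        }

    return draw


def vsea_test(
    snps: VariantSet,
    dmps: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    direction: str = "increased",
    threads: int = 1,
) -> EnrichmentResult:
    """One VSEA test: observed SNP-in-region count against a random-region null.

    Each of the ``n_perm`` permutations uses its own RNG substream spawned
    from ``rng``, so results are identical regardless of how permutations
    are scheduled across ``threads``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    trait = snps.trait if isinstance(snps, VariantSet) else "set"
    points = _SnpPoints(snps)

    if len(dmps) == 0:
        logger.warning("%s/%s: empty region set; degenerate VSEA result", trait, direction)
        return EnrichmentResult(
            trait=trait, direction=direction, observed=0,
            null_counts=np.zeros(n_perm, dtype=np.int64),
            null_mean=0.0, null_sd=0.0, enrichment_score=0.0, fold=1.0,
            p_perm=1.0, n_perm=n_perm, degenerate=True,
        )

    observed = _count_points(points, _group_regions(dmps))
    # canonical template order: the null stream must not depend on how the
    # caller happened to order the regions
    template = sorted(dmps, key=lambda r: (r.chrom, r.start, r.end))
    draw = _null_sampler(template, chrom_sizes)
    child_rngs = rng.spawn(n_perm)

    def run_iter(k: int) -> int:
        return _count_points(points, draw(child_rngs[k]))

    if threads > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as ex:
            null_counts = np.fromiter(ex.map(run_iter, range(n_perm)), dtype=np.int64, count=n_perm)
    else:
        null_counts = np.fromiter((run_iter(k) for k in range(n_perm)), dtype=np.int64, count=n_perm)

    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=0))
    es_capped = False
    if null_sd > 0:
        es = (observed - null_mean) / null_sd
    elif observed == null_mean:
        es = 0.0
    else:
        es = _ES_CAP if observed > null_mean else -_ES_CAP
        es_capped = True
    p_perm = permutation_pvalue(int(np.count_nonzero(null_counts >= observed)), n_perm)
    return EnrichmentResult(
        trait=trait, direction=direction, observed=int(observed),
        null_counts=null_counts, null_mean=null_mean, null_sd=null_sd,
        enrichment_score=float(es), fold=(observed + 1) / (null_mean + 1),
        p_perm=p_perm, n_perm=n_perm, es_capped=es_capped,
    )


def vsea_batch(
    sets: Sequence[VariantSet],
    dmp_sets: Mapping[str, Tuple[Sequence[GenomicInterval], Sequence[GenomicInterval]]],
    chrom_sizes: Mapping[str, int],
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    threads: int = 1,
) -> List[EnrichmentResult]:
    """VSEA for every trait x direction, BH-adjusted jointly, sorted by p_adj.

    ``dmp_sets`` maps each trait to its (increased, decreased) region lists.
    """
    rng = np.random.default_rng() if rng is None else rng
    results: List[EnrichmentResult] = []
    for vset in sets:
        inc, dec = dmp_sets[vset.trait]
        for direction, regions in (("increased", inc), ("decreased", dec)):
            sub = rng.spawn(1)[0]
            results.append(
                vsea_test(vset, regions, chrom_sizes, n_perm=n_perm, rng=sub,
                          direction=direction, threads=threads)
            )
    if results:
        adj = benjamini_hochberg([r.p_perm for r in results])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    results.sort(key=lambda r: (r.p_adj, r.trait, r.direction))
    return results


def write_vsea_table(results: Sequence[EnrichmentResult], path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(
            f"# m6avar v{__version__} | VSEA results; enrichment_score = permutation "
            "z-score (observed - null_mean)/null_sd; fold = (observed+1)/(null_mean+1); "
            "p_perm = add-one permutation p; p_adj = BH across all rows\n"
        )
        fh.write(
            "trait\tdirection\tobserved\tnull_mean\tnull_sd\tenrichment_score\t"
            "fold\tp_perm\tp_adj\tn_perm\tdegenerate\n"
        )
        for r in results:
            fh.write(
                f"{r.trait}\t{r.direction}\t{r.observed}\t{r.null_mean:.6g}\t"
                f"{r.null_sd:.6g}\t{r.enrichment_score:.6g}\t{r.fold:.6g}\t"
                f"{r.p_perm:.10g}\t{'' if r.p_adj is None else format(r.p_adj, '.10g')}\t"
                f"{r.n_perm}\t{r.degenerate}\n"
            )
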
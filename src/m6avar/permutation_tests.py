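"""SNP-subset resampling tests for chromosomal and genomic-category enrichment.

Given a subset of SNPs (e.g. those overlapping increased m6A peaks) drawn
from a full trait set, each test asks whether a category label (chromosome,
or genomic annotation category) is over-represented in the subset relative
to random same-size subsets of the full set. Because the null draws the
subset uniformly without replacement, the per-category null count is exactly
multivariate hypergeometric; draws are generated directly from that
distribution, and the closed-form hypergeometric upper tail serves as the
exact oracle the permutation p converges to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .stats import benjamini_hochberg, hypergeom_tail, permutation_pvalue
from .types import ConfigurationError, Snp, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 100_000

__all__ = [
    "CategoryTestResult",
    "subset_permutation_test",
    "annotation_enrichment",
    "hypergeom_tail",
]


@dataclass
class CategoryTestResult:
    """Enrichment of one category (chromosome or annotation class)."""

    category: str
    observed: int
    expected: float
    p_perm: float
    p_adj: Optional[float]
    n_iter: int
    n_subset: int
    n_full: int
    n_full_category: int


def subset_permutation_test(
    subset_labels: Mapping[str, str],
    full_labels: Mapping[str, str],
    n_iter: int = DEFAULT_N_ITER,
    rng: Optional[np.random.Generator] = None,
    alternative: str = "greater",
) -> List[CategoryTestResult]:
    """Per-category enrichment of a SNP subset against same-size random subsets.

    Parameters
    ----------
    subset_labels, full_labels : mapping rsid -> category label
        The subset must be contained in the full set (checked by rsid).
    n_iter : number of null subsets drawn (uniformly, without replacement).
    alternative : 'greater' tests enrichment (one-sided >=), 'less' depletion.

    Null per-category counts are multivariate-hypergeometric; they are drawn
    directly from that distribution, which is identical in law to drawing
    the SNP subset and tabulating labels. BH adjustment spans all categories
    present in the full set.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    if alternative not in ("greater", "less"):
        raise ConfigurationError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if len(subset_labels) == 0:
        raise ValidationError("empty subset: nothing to test")
    missing = set(subset_labels) - set(full_labels)
    if missing:
        raise ValidationError(
            f"subset is not contained in the full set; {len(missing)} rsids missing "
            f"(e.g. {sorted(missing)[:3]})"
        )
    rng = np.random.default_rng() if rng is None else rng

    categories = sorted({str(v) for v in full_labels.values()})
    cat_index = {c: i for i, c in enumerate(categories)}
    colors = np.zeros(len(categories), dtype=np.int64)
    for lab in full_labels.values():
        colors[cat_index[str(lab)]] += 1
    observed = np.zeros(len(categories), dtype=np.int64)
    for lab in subset_labels.values():
        observed[cat_index[str(lab)]] += 1

    m = len(subset_labels)
    N = len(full_labels)
    draws = rng.multivariate_hypergeometric(colors, m, size=n_iter)

    results: List[CategoryTestResult] = []
    for c, i in cat_index.items():
        if alternative == "greater":
            b = int(np.count_nonzero(draws[:, i] >= observed[i]))
        else:
            b = int(np.count_nonzero(draws[:, i] <= observed[i]))
        results.append(
            CategoryTestResult(
                category=c,
                observed=int(observed[i]),
                expected=m * colors[i] / N,
                p_perm=permutation_pvalue(b, n_iter),
                p_adj=None,
                n_iter=n_iter,
                n_subset=m,
                n_full=N,
                n_full_category=int(colors[i]),
            )
        )
    adj = benjamini_hochberg([r.p_perm for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def chromosome_enrichment(
    subset_snps: Sequence[Snp],
    full_snps: Sequence[Snp],
    n_iter: int = DEFAULT_N_ITER,
    rng: Optional[np.random.Generator] = None,
    alternative: str = "greater",
) -> List[CategoryTestResult]:
    """Chromosomal-distribution permutation test (labels = chromosome names)."""
    return subset_permutation_test(
        {s.rsid: s.chrom for s in subset_snps},
        {s.rsid: s.chrom for s in full_snps},
        n_iter=n_iter, rng=rng, alternative=alternative,
    )


def annotation_enrichment(
    subset_snps: Sequence[Snp],
    full_snps: Sequence[Snp],
    transcripts: Sequence[TranscriptModel],
    n_iter: int = DEFAULT_N_ITER,
    rng: Optional[np.random.Generator] = None,
    alternative: str = "greater",
    annotator=None,
    **annotator_kwargs,
) -> List[CategoryTestResult]:
    """Genomic-category permutation test over annotation labels.

    Every SNP of the full set is annotated (promoter / TTS / exonic /
    intronic / intergenic, via the annotation module), then the same
    resampling machinery as the chromosome test runs over those labels.
    """
    from .annotation import SnpAnnotator

    ann = annotator if annotator is not None else SnpAnnotator(transcripts, **annotator_kwargs)
    full_labels = {s.rsid: ann.annotate(s).category for s in full_snps}
    subset_labels = {s.rsid: full_labels.get(s.rsid) for s in subset_snps}
    if any(v is None for v in subset_labels.values()):
        raise ValidationError("subset contains rsids absent from the full set")
    return subset_permutation_test(
        subset_labels, full_labels, n_iter=n_iter, rng=rng, alternative=alternative
    )


def write_category_table(results: Sequence[CategoryTestResult], path, mode: str) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(
            f"# m6avar v{__version__} | {mode} permutation test; observed vs "
            "same-size random subsets of the full SNP set; one-sided p, BH-adjusted\n"
        )
        fh.write("category\tobserved\texpected\tp_perm\tp_adj\tn_iter\tn_subset\tn_full\n")
        for r in sorted(results, key=lambda r: (r.p_adj, r.category)):
            fh.write(
                f"{r.category}\t{r.observed}\t{r.expected:.6g}\t{r.p_perm:.10g}\t"
                f"{r.p_adj:.10g}\t{r.n_iter}\t{r.n_subset}\t{r.n_full}\n"
            )
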
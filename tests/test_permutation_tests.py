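"""Subset-resampling tests against the exact hypergeometric oracle."""

import numpy as np
import pytest

from m6avar.permutation_tests import (
    annotation_enrichment,
    chromosome_enrichment,
    hypergeom_tail,
    subset_permutation_test,
)
from m6avar.types import ConfigurationError, Snp, ValidationError


def _labels(counts):
    """{'A': 3, 'B': 2} -> rsid->label mapping with deterministic rsids."""
    out = {}
    i = 0
    for lab, n in counts.items():
        for _ in range(n):
            out[f"rs{i}"] = lab
            i += 1
    return out


class TestSubsetPermutationTest:
    def test_subset_equals_full_gives_p_one(self, rng):
        full = _labels({"chr1": 10, "chr2": 5, "chr3": 8})
        results = subset_permutation_test(full, full, n_iter=500, rng=rng)
        assert all(r.p_perm == 1.0 for r in results)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValidationError):
            subset_permutation_test({}, _labels({"chr1": 5}), n_iter=10, rng=rng)

    def test_subset_not_contained_rejected(self, rng):
        full = _labels({"chr1": 5})
        with pytest.raises(ValidationError):
            subset_permutation_test({"rs999": "chr1"}, full, n_iter=10, rng=rng)

    def test_agrees_with_hypergeometric_oracle(self, rng):
        # moderate concentration: p in a range where Monte-Carlo error is meaningful
        N, K = 200, 40
        full = _labels({"A": K, "B": N - K})
        subset = {f"rs{i}": "A" for i in range(12)}
        subset.update({f"rs{K + i}": "B" for i in range(8)})
        n_iter = 20_000
        res = {r.category: r for r in subset_permutation_test(subset, full, n_iter=n_iter, rng=rng)}
        p_exact = hypergeom_tail(N, K, 20, 12)
        se = np.sqrt(p_exact * (1 - p_exact) / n_iter)
        assert abs(res["A"].p_perm - p_exact) <= 3 * se + 2 / n_iter
        assert res["A"].expected == pytest.approx(20 * K / N)

    def test_extreme_concentration_hits_floor(self, rng):
        # all-promoter subset where promoters are 5% of the full set
        full = _labels({"promoter": 50, "other": 950})
        subset = {f"rs{i}": "promoter" for i in range(20)}
        res = {r.category: r for r in subset_permutation_test(subset, full, n_iter=10_000, rng=rng)}
        assert res["promoter"].p_perm <= 1e-3

    def test_depletion_mode(self, rng):
        full = _labels({"A": 100, "B": 100})
        subset = {f"rs{i + 100}": "B" for i in range(20)}  # zero A's
        res = {r.category: r for r in
               subset_permutation_test(subset, full, n_iter=5000, rng=rng, alternative="less")}
        assert res["A"].p_perm < 0.01

    def test_bh_monotonicity_and_determinism(self):
        full = _labels({"a": 30, "b": 25, "c": 40, "d": 10})
        subset = dict(list(full.items())[:20])
        r1 = subset_permutation_test(subset, full, n_iter=2000, rng=np.random.default_rng(5))
        r2 = subset_permutation_test(subset, full, n_iter=2000, rng=np.random.default_rng(5))
        assert [r.p_perm for r in r1] == [r.p_perm for r in r2]
        by_p = sorted(r1, key=lambda r: r.p_perm)
        assert [r.p_adj for r in by_p] == sorted(r.p_adj for r in by_p)

    def test_invalid_n_iter(self, rng):
        with pytest.raises(ConfigurationError):
            subset_permutation_test(_labels({"a": 1}), _labels({"a": 1}), n_iter=0, rng=rng)


class TestSnpLevelWrappers:
    def test_chromosome_enrichment_on_study(self, small_study, rng):
        vset = small_study.variant_set()
        subset = vset.snps[:25]
        results = chromosome_enrichment(subset, vset.snps, n_iter=2000, rng=rng)
        assert {r.category for r in results} <= {f"chr{i + 1}" for i in range(small_study.config.n_chroms)}
        assert all(0 < r.p_perm <= 1 for r in results)
        assert all(r.observed <= len(subset) for r in results)

    def test_annotation_enrichment_calibrated_on_random_subsets(self, small_study):
        """Uniform random subsets should not produce concentrated small p-values."""
        vset = small_study.variant_set()
        master = np.random.default_rng(2024)
        exceed = {}
        n_rep = 200
        for _ in range(n_rep):
            idx = master.choice(len(vset.snps), size=30, replace=False)
            subset = [vset.snps[i] for i in idx]
            res = annotation_enrichment(subset, vset.snps, small_study.transcripts,
                                        n_iter=1000, rng=master)
            for r in res:
                exceed.setdefault(r.category, []).append(r.p_perm < 0.05)
        for cat, flags in exceed.items():
            assert np.mean(flags) <= 0.08, f"{cat}: {np.mean(flags):.3f}"

    def test_annotation_categories_from_study(self, small_study, rng):
        vset = small_study.variant_set()
        res = annotation_enrichment(vset.snps[:40], vset.snps, small_study.transcripts,
                                    n_iter=500, rng=rng)
        allowed = {"promoter", "TTS", "exonic", "intronic", "intergenic"}
        assert {r.category for r in res} <= allowed
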
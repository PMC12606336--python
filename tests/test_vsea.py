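"""VSEA: overlap counting, null-region sampling, permutation machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from m6avar.types import ConfigurationError, GenomicInterval, Snp
from m6avar.variant_sets import VariantSet
from m6avar.vsea import count_overlaps, sample_null_regions, vsea_batch, vsea_test


def _snp(pos, chrom="chr1", i=[0]):
    i[0] += 1
    return Snp(rsid=f"rs{i[0]}", chrom=chrom, pos=pos)


def _brute_force(snps, regions):
    hit = set()
    for s in snps:
        for r in regions:
            if r.chrom == s.chrom and r.start <= s.pos - 1 < r.end:
                hit.add(s.rsid)
    return len(hit)


class TestCountOverlaps:
    def test_coordinate_rule_boundaries(self):
        # the one documented rule: snp overlaps region <=> start <= pos-1 < end
        assert count_overlaps([_snp(100)], [GenomicInterval("chr1", 99, 150)]) == 1
        assert count_overlaps([_snp(100)], [GenomicInterval("chr1", 50, 99)]) == 0
        # a 1-based SNP at 100 occupies 0-based 99, one short of [100, 150)
        assert count_overlaps([_snp(100)], [GenomicInterval("chr1", 100, 150)]) == 0
        assert count_overlaps([_snp(101)], [GenomicInterval("chr1", 100, 150)]) == 1
        # half-open right edge: pos-1 == end is outside
        assert count_overlaps([_snp(151)], [GenomicInterval("chr1", 100, 150)]) == 0
        assert count_overlaps([_snp(150)], [GenomicInterval("chr1", 100, 150)]) == 1

    def test_snp_in_two_regions_counts_once(self):
        regions = [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 50, 300)]
        assert count_overlaps([_snp(100)], regions) == 1

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n, m = int(rng.integers(1, 60)), int(rng.integers(1, 40))
            snps = [
                Snp(rsid=f"r{j}", chrom=f"chr{rng.integers(1, 4)}",
                    pos=int(rng.integers(1, 500)))
                for j in range(n)
            ]
            regions = []
            for _ in range(m):
                s = int(rng.integers(0, 480))
                regions.append(GenomicInterval(f"chr{rng.integers(1, 4)}", s,
                                               s + int(rng.integers(1, 60))))
            assert count_overlaps(snps, regions) == _brute_force(snps, regions)


class TestSampleNullRegions:
    def test_forced_placement_when_region_fills_chromosome(self, rng):
        template = [GenomicInterval("chr1", 0, 500)]
        out = sample_null_regions(template, {"chr1": 500}, rng)
        assert out == template

    def test_lengths_and_chromosomes_conserved(self, rng):
        template = [
            GenomicInterval("chr1", 10, 200), GenomicInterval("chr2", 0, 77),
            GenomicInterval("chr1", 900, 1000),
        ]
        sizes = {"chr1": 5000, "chr2": 5000}
        for _ in range(200):
            out = sample_null_regions(template, sizes, rng)
            assert len(out) == len(template)
            for a, b in zip(template, out):
                assert len(a) == len(b) and a.chrom == b.chrom
                assert 0 <= b.start and b.end <= sizes[b.chrom]

    def test_template_longer_than_chromosome_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_null_regions([GenomicInterval("chr1", 0, 600)], {"chr1": 500}, rng)

    def test_uniform_placement_chi_square(self, rng):
        # start positions of 10,000 redraws of one length-5 region on a
        # 50 bp chromosome should be uniform over the 46 legal starts
        template = [GenomicInterval("chr1", 0, 5)]
        counts = np.zeros(46)
        for _ in range(10_000):
            (r,) = sample_null_regions(template, {"chr1": 50}, rng)
            counts[r.start] += 1
        stat, p = sps.chisquare(counts)
        assert p > 0.001


class TestVseaTest:
    def test_zero_snps_gives_p_one(self, rng):
        vset = VariantSet(trait="t", snps=[])
        res = vsea_test(vset, [GenomicInterval("chr1", 0, 100)], {"chr1": 10_000},
                        n_perm=1000, rng=rng)
        assert res.observed == 0
        assert res.p_perm == 1.0

    def test_add_one_minimum_p(self, rng):
        # SNPs clustered in two distant blocks covered by the real regions;
        # a random redraw essentially never covers both blocks
        snps = [_snp(p) for p in range(1, 51)] + [_snp(p, chrom="chr2") for p in range(1, 51)]
        vset = VariantSet(trait="t", snps=snps)
        regions = [GenomicInterval("chr1", 0, 60), GenomicInterval("chr2", 0, 60)]
        sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
        res = vsea_test(vset, regions, sizes, n_perm=1000, rng=rng)
        assert res.observed == 100
        assert res.p_perm == pytest.approx(1 / 1001)
        assert res.enrichment_score > 10

    def test_empty_region_set_is_degenerate(self, rng):
        vset = VariantSet(trait="t", snps=[_snp(5)])
        res = vsea_test(vset, [], {"chr1": 1000}, n_perm=100, rng=rng)
        assert res.degenerate and res.p_perm == 1.0 and res.observed == 0

    def test_determinism_and_thread_independence(self, small_study):
        vset = small_study.variant_set()
        regions = small_study.true_regions("increased")
        runs = [
            vsea_test(vset, regions, small_study.chrom_sizes, n_perm=200,
                      rng=np.random.default_rng(42), threads=threads)
            for threads in (1, 1, 2)
        ]
        np.testing.assert_array_equal(runs[0].null_counts, runs[1].null_counts)
        np.testing.assert_array_equal(runs[0].null_counts, runs[2].null_counts)

    def test_input_order_invariance(self, rng, small_study):
        vset = small_study.variant_set()
        regions = small_study.true_regions("increased")
        shuffled = VariantSet(trait=vset.trait,
                              snps=[vset.snps[i] for i in rng.permutation(len(vset.snps))])
        r1 = vsea_test(vset, regions, small_study.chrom_sizes, n_perm=100,
                       rng=np.random.default_rng(7))
        r2 = vsea_test(shuffled, list(reversed(regions)), small_study.chrom_sizes,
                       n_perm=100, rng=np.random.default_rng(7))
        assert r1.observed == r2.observed
        assert r1.p_perm == r2.p_perm


class TestVseaBatch:
    def test_single_test_bh_identity(self, small_study):
        vset = small_study.variant_set()
        dmp_sets = {vset.trait: (small_study.true_regions("increased"), [])}
        results = vsea_batch([vset], dmp_sets, small_study.chrom_sizes, n_perm=100,
                             rng=np.random.default_rng(3))
        inc = next(r for r in results if r.direction == "increased")
        # two tests total (decreased is degenerate with p = 1); BH keeps the
        # smaller p unchanged when it is below the tie
        assert inc.p_adj == pytest.approx(min(2 * inc.p_perm, 1.0) if inc.p_perm < 1 else 1.0)

    def test_bh_ties_equal(self, rng):
        from m6avar.stats import benjamini_hochberg

        p = [0.2] * 18
        assert np.allclose(benjamini_hochberg(p), p)

    def test_planted_enrichment_ranks_first(self):
        from m6avar.synthetic_data import SimConfig, simulate_study

        bundle = simulate_study(SimConfig(seed=31, planted_enrichment=5.0))
        sets = [bundle.variant_set(t) for t in bundle.config.trait_names]
        dmp_sets = {
            s.trait: (bundle.true_regions("increased"), bundle.true_regions("decreased"))
            for s in sets
        }
        results = vsea_batch(sets, dmp_sets, bundle.chrom_sizes, n_perm=500,
                             rng=np.random.default_rng(9))
        top = results[0]
        assert (top.trait, top.direction) == (bundle.config.planted_trait_name, "increased")
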
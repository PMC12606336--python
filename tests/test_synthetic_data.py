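"""Generator determinism, seed isolation, truth conservation, planting laws."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

from m6avar.synthetic_data import (
    SimConfig,
    simulate_null_snp_sets,
    simulate_study,
    transcript_segment_pieces,
)
from m6avar.types import ConfigurationError, Snp, ValidationError

SMALL = dict(n_chroms=2, chrom_length=120_000, n_transcripts=70,
             n_peaks=180, n_lead_snps=60)


def _files(d):
    return sorted(p for p in Path(d).rglob("*") if p.is_file())


class TestDeterminismAndIsolation:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg).write(d1)
        simulate_study(cfg).write(d2)
        f1, f2 = _files(d1), _files(d2)
        assert [p.name for p in f1] == [p.name for p in f2]
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes(), a.name

    def test_planted_enrichment_does_not_touch_genome_or_gtf(self):
        base = simulate_study(SimConfig(seed=9, **SMALL))
        enriched = simulate_study(SimConfig(seed=9, planted_enrichment=5.0, **SMALL))
        assert base.genome == enriched.genome
        assert base.transcripts == enriched.transcripts
        assert [p.interval for p in base.peaks] == [p.interval for p in enriched.peaks]


class TestTruthConservation:
    def test_truth_counts_recoverable_from_files(self, tmp_path, small_study):
        from m6avar.io_formats import read_peak_table, read_snp_table
        from m6avar.peak_analysis import classify_dmps

        d = tmp_path / "study"
        paths = small_study.write(d)
        peaks = read_peak_table(paths["peaks"])
        inc, dec = classify_dmps(peaks)
        truth = small_study.truth.peak_direction
        assert len(inc) == sum(v == "increased" for v in truth.values())
        assert len(dec) == sum(v == "decreased" for v in truth.values())
        for trait in small_study.config.trait_names:
            snps = read_snp_table(paths[f"snps_{trait}"])
            assert len(snps) == small_study.config.n_lead_snps
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["counts"]["n_peaks"] == len(peaks)

    def test_planted_lead_snps_really_sit_in_increased_dmps(self, small_study):
        inc = small_study.true_regions("increased")
        for trait, rsids in small_study.truth.snps_planted_in_dmp.items():
            planted = set(rsids)
            for snp in small_study.leads[trait]:
                inside = any(iv.contains_snp(snp) for iv in inc)
                assert inside == (snp.rsid in planted)


class TestPlantingLaws:
    def test_uniform_placement_at_enrichment_one(self):
        """Binomial oracle: lead in-DMP rate matches DMP bases / genome length."""
        total_hits = 0
        mean_hits = 0.0
        var_hits = 0.0
        for seed in range(50):
            b = simulate_study(SimConfig(seed=300 + seed, n_chroms=2,
                                         chrom_length=100_000, n_transcripts=60,
                                         n_peaks=150, n_lead_snps=40, n_traits=1))
            inc = b.true_regions("increased")
            D = sum(len(iv) for iv in inc)
            L = sum(b.chrom_sizes.values())
            q = D / L
            n = b.config.n_lead_snps
            total_hits += sum(
                any(iv.contains_snp(s) for iv in inc) for s in b.leads["trait_1"]
            )
            mean_hits += n * q
            var_hits += n * q * (1 - q)
        z = (total_hits - mean_hits) / np.sqrt(var_hits)
        assert abs(z) < 2.576  # 99% normal bounds

    def test_forced_drach_planting(self, small_config):
        from dataclasses import replace

        bundle = simulate_study(replace(small_config, drach_plant_prob=1.0))
        assert all(bundle.truth.drach_planted.values())

    def test_infeasible_enrichment_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_study(SimConfig(seed=1, n_chroms=1, chrom_length=60_000,
                                     n_transcripts=10, n_peaks=20,
                                     frac_dmp_increased=0.0, frac_dmp_decreased=0.0,
                                     n_lead_snps=5, planted_enrichment=2.0))

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimConfig(frac_dmp_increased=0.7, frac_dmp_decreased=0.5)
        with pytest.raises(ConfigurationError):
            SimConfig(planted_enrichment=0.5)
        with pytest.raises(ConfigurationError):
            SimConfig(peak_placement="intron")

    def test_segment_pieces_partition_exons(self, small_study):
        for t in small_study.transcripts[:20]:
            total = sum(
                sum(len(iv) for iv in transcript_segment_pieces(t, w))
                for w in ("5utr", "cds", "3utr")
            )
            assert total == t.exonic_length


class TestNullSnpSets:
    SNPS = [Snp(rsid=f"rs{i}", chrom=f"chr{1 + i % 3}", pos=100 + i) for i in range(30)]

    def test_full_and_empty_draws(self, rng):
        (full,) = simulate_null_snp_sets(self.SNPS, m=30, rng=rng)
        assert full == self.SNPS
        (empty,) = simulate_null_snp_sets(self.SNPS, m=0, rng=rng)
        assert empty == []

    def test_oversized_draw_rejected(self, rng):
        with pytest.raises(ValidationError):
            simulate_null_snp_sets(self.SNPS, m=31, rng=rng)

    def test_per_chromosome_counts_match_hypergeometric(self, rng):
        """chr1 holds 10 of 30 SNPs; draws of 12 should average 12*10/30 = 4."""
        n_draws = 20_000
        subsets = simulate_null_snp_sets(self.SNPS, m=12, n_sets=n_draws, rng=rng)
        counts = np.array([sum(s.chrom == "chr1" for s in sub) for sub in subsets])
        hg = sps.hypergeom(30, 10, 12)
        se = hg.std() / np.sqrt(n_draws)
        assert abs(counts.mean() - hg.mean()) < 3 * se
        # tail probability agreement
        p_emp = np.mean(counts >= 6)
        p_exact = hg.sf(5)
        assert abs(p_emp - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / n_draws)
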
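"""DMP classification thresholds, metagene mapping, DRACH scanning."""

import re

import numpy as np
import pytest

from m6avar.io_formats import write_fasta
from m6avar.peak_analysis import (
    DRACH_RE,
    classify_dmps,
    drach_fraction,
    has_drach,
    label_dmps,
    metagene_position,
    metagene_profile,
    reverse_complement,
)
from m6avar.stats import benjamini_hochberg
from m6avar.synthetic_data import SimConfig, simulate_study
from m6avar.types import ConfigurationError, DiffPeak, GenomicInterval, TranscriptModel


def _peak(start, end, log2fc, pvalue, padj=None, chrom="chr1", strand="+"):
    return DiffPeak(
        interval=GenomicInterval(chrom, start, end, strand),
        log2fc=log2fc, pvalue=pvalue, padj=padj,
    )


class TestClassifyDmps:
    def test_threshold_and_sign_rules(self):
        peaks = [
            _peak(0, 100, +1.2, 0.001, padj=0.01),   # increased
            _peak(0, 100, -3.0, 0.001, padj=0.2),    # not significant
            _peak(0, 100, +0.5, 0.001, padj=0.05),   # boundary: strict <
            _peak(0, 100, -1.0, 0.001, padj=0.049),  # decreased
            _peak(0, 100, 0.0, 0.001, padj=0.001),   # zero fold-change
        ]
        inc, dec = classify_dmps(peaks, alpha=0.05)
        assert [p.interval for p in inc] == [peaks[0].interval]
        assert [p.interval for p in dec] == [peaks[3].interval]
        assert all(p.direction == "increased" for p in inc)
        assert all(p.direction == "decreased" for p in dec)

    def test_partition_property(self, small_study):
        labeled = label_dmps(small_study.peaks)
        counts = {d: sum(p.direction == d for p in labeled) for d in ("increased", "decreased", "none")}
        assert sum(counts.values()) == len(small_study.peaks)
        inc, dec = classify_dmps(small_study.peaks)
        assert counts["increased"] == len(inc) and counts["decreased"] == len(dec)

    def test_padj_recomputed_when_absent(self):
        pvals = [0.001, 0.02, 0.8, 0.5]
        peaks = [_peak(0, 100, 1.0, pv) for pv in pvals]
        inc, _ = classify_dmps(peaks)
        expected = benjamini_hochberg(pvals)
        sig = [a for a in expected if a < 0.05]
        assert sorted(p.padj for p in inc) == pytest.approx(sorted(sig))

    def test_raw_p_mode(self):
        peaks = [_peak(0, 100, 1.0, 0.03, padj=0.3)]
        assert classify_dmps(peaks, use_adjusted=True) == ([], [])
        inc, _ = classify_dmps(peaks, use_adjusted=False)
        assert len(inc) == 1

    def test_recovers_generator_truth(self, small_study):
        inc, dec = classify_dmps(small_study.peaks)
        truth = small_study.truth.peak_direction
        assert {p.peak_id for p in inc} == {k for k, v in truth.items() if v == "increased"}
        assert {p.peak_id for p in dec} == {k for k, v in truth.items() if v == "decreased"}


class TestMetagene:
    def _single_exon_tx(self, strand="+"):
        # exon [0, 1000); CDS [200, 800) -> 5'UTR 200, CDS 600, 3'UTR 200
        return TranscriptModel(
            transcript_id="T1", gene_id="G1", gene_name="G1", chrom="chr1",
            strand=strand, exons=(GenomicInterval("chr1", 0, 1000, strand),),
            cds_start=200, cds_end=800,
        )

    def test_cds_center_maps_to_1_5(self):
        t = self._single_exon_tx()
        assert metagene_position(500, t) == pytest.approx(1.5)
        profile = metagene_profile([_peak(450, 550, 1.0, 0.5, padj=0.5)], [t])
        assert profile.n_mapped == 1
        assert profile.positions[0] == pytest.approx(1.5)

    def test_minus_strand_reverses_segments(self):
        t = self._single_exon_tx(strand="-")
        # genomic 100 is near the genomic start => 3' end of a minus-strand transcript
        x = metagene_position(100, t)
        assert 2.0 <= x < 3.0
        assert metagene_position(900, t) < 1.0

    def test_zero_mappable_peaks(self):
        t = self._single_exon_tx()
        profile = metagene_profile([_peak(5000, 5100, 1.0, 0.5, padj=0.5)], [t])
        assert profile.n_mapped == 0 and profile.n_unmapped == 1
        assert np.all(profile.density == 0)

    def test_n_bins_validation(self):
        with pytest.raises(ConfigurationError):
            metagene_profile([], [], n_bins=2)

    def test_density_integrates_to_one(self, small_study):
        for n_bins in (30, 90):
            prof = metagene_profile(small_study.peaks, small_study.transcripts, n_bins=n_bins)
            assert prof.n_mapped > 0
            widths = np.diff(prof.bin_edges)
            assert np.sum(prof.density * widths) == pytest.approx(1.0)

    def test_three_prime_utr_planting_recovered(self):
        bundle = simulate_study(SimConfig(
            seed=77, n_chroms=2, chrom_length=120_000, n_transcripts=70,
            n_peaks=100, n_lead_snps=10, peak_placement="3utr",
        ))
        prof = metagene_profile(bundle.peaks, bundle.transcripts)
        assert prof.segment_mass(2.0, 3.0) >= 0.99


class TestDrach:
    def test_motif_examples(self):
        assert has_drach("GGACT")
        assert not has_drach("CCCCCCC")

    def test_fraction_matches_naive_regex_oracle(self, tmp_path, small_study):
        fasta = tmp_path / "genome.fa"
        write_fasta(small_study.genome, fasta)
        peaks = small_study.peaks[:200]
        got = drach_fraction(peaks, fasta)
        # independent route: plain string slicing + Biopython reverse complement
        from Bio.Seq import Seq

        hits = 0
        for p in peaks:
            iv = p.interval
            seq = small_study.genome[iv.chrom][iv.start:iv.end]
            if iv.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            hits += bool(re.search("[AGT][AG]AC[ACT]", seq))
        assert got == pytest.approx(hits / len(peaks))

    def test_forced_planting_gives_fraction_one(self, tmp_path):
        bundle = simulate_study(SimConfig(
            seed=5, n_chroms=2, chrom_length=100_000, n_transcripts=50,
            n_peaks=80, n_lead_snps=10, drach_plant_prob=1.0,
        ))
        fasta = tmp_path / "g.fa"
        write_fasta(bundle.genome, fasta)
        assert drach_fraction(bundle.peaks, fasta) == 1.0

    def test_peak_beyond_contig_end_rejected(self, tmp_path):
        fasta = tmp_path / "tiny.fa"
        write_fasta({"chr1": "ACGT" * 25}, fasta)
        with pytest.raises(ValueError):
            drach_fraction([_peak(50, 200, 1.0, 0.5, padj=0.5)], fasta)

    def test_reverse_complement(self):
        assert reverse_complement("GGACT") == "AGTCC"
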
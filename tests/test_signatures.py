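"""Size/strand profiles, 5' coverage, U1/A10 bias, ping-pong z and RNAi calls."""
import numpy as np
import pytest
from oracles import allpairs_pair_weight
from scipy import stats as sps

from viromesig.mapper import AlignmentRecord
from viromesig.signatures import (RnaiThresholds, classify_rnai,
                                  coverage_5prime, nucleotide_bias,
                                  pingpong_signature, profile_pair,
                                  size_distribution)
from viromesig.simulate import (GenomeSpec, SmallRnaSimConfig, make_genome,
                                simulate_small_rna_library, truth_alignments)


def _sim(genome, seed=1, **kw):
    defaults = dict(n_reads=4000, frac_sirna=0.4, frac_pirna=0.4,
                    frac_noise=0.2)
    defaults.update(kw)
    reads, labels = simulate_small_rna_library(
        genome, SmallRnaSimConfig(seed=seed, **defaults))
    return reads, labels, truth_alignments(labels)


def _aln(read_id, seg, strand, start, end):
    return AlignmentRecord(read_id=read_id, segment_id=seg, strand=strand,
                           start=start, end=end, mismatches=0, identity=1.0,
                           aligned_fraction=1.0)


class TestSizeDistribution:
    def test_sirna_mode_peaks_at_21_both_strands(self, genome_4k):
        _r, _l, aln = _sim(genome_4k, frac_sirna=1.0, frac_pirna=0, frac_noise=0,
                           n_reads=8000)
        prof = size_distribution(aln)
        assert prof.counts["+"].idxmax() == 21
        assert prof.counts["-"].idxmax() == 21

    def test_pirna_mode_peaks_at_27(self, genome_4k):
        _r, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=1.0, frac_noise=0,
                           n_reads=8000)
        prof = size_distribution(aln)
        peak = prof.counts.sum(axis=1).idxmax()
        assert peak == 27

    def test_empty_profile_and_conservation(self, genome_4k):
        assert size_distribution([]).total == 0
        _r, _l, aln = _sim(genome_4k, n_reads=3000)
        assert size_distribution(aln).total == len(aln)


class TestCoverage5Prime:
    def test_sense_5prime_is_interval_start(self):
        cov = coverage_5prime([_aln("r", "s", "+", 100, 121)], "s", 200)
        assert cov.plus[100] == 1 and cov.plus.sum() == 1

    def test_antisense_5prime_is_rightmost_coordinate(self):
        cov = coverage_5prime([_aln("r", "s", "-", 100, 121)], "s", 200)
        assert cov.minus[120] == 1 and cov.minus.sum() == 1

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            coverage_5prime([_aln("r", "s", "+", 190, 211)], "s", 200)

    def test_uniform_reads_pass_chisquare(self, genome_4k):
        _r, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=0, frac_noise=1.0,
                           n_reads=20000)
        seg = genome_4k[0].id
        cov = coverage_5prime(aln, seg, 4000)
        # bin the 5' starts; noise positions are uniform over valid starts
        counts = (cov.plus + cov.minus)[:3960]
        binned = counts.reshape(40, -1).sum(axis=1)
        assert sps.chisquare(binned).pvalue > 0.001

    def test_totals_match_strand_counts(self, genome_4k):
        _r, labels, aln = _sim(genome_4k, n_reads=3000)
        seg = genome_4k[0].id
        cov = coverage_5prime(aln, seg, 4000)
        assert cov.strand_total("+") == (labels.strand == "+").sum()
        assert cov.strand_total("-") == (labels.strand == "-").sum()


class TestNucleotideBias:
    def test_forced_u1(self, genome_4k):
        reads, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=1.0,
                              frac_noise=0, pingpong_prob=0.0, u1_bias=1.0,
                              n_reads=2000)
        bias = nucleotide_bias(aln, {r.id: str(r.seq) for r in reads})
        assert bias.frequency("antisense", "T", 1) == 1.0

    def test_forced_a10(self, genome_4k):
        reads, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=1.0,
                              frac_noise=0, pingpong_prob=0.0, a10_bias=1.0,
                              n_reads=2000)
        bias = nucleotide_bias(aln, {r.id: str(r.seq) for r in reads})
        assert bias.frequency("sense", "A", 10) == 1.0

    def test_unbiased_frequencies_near_quarter(self, genome_4k):
        reads, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=1.0,
                              frac_noise=0, pingpong_prob=0.0, u1_bias=0.0,
                              a10_bias=0.0, n_reads=12000)
        bias = nucleotide_bias(aln, {r.id: str(r.seq) for r in reads})
        for orientation, n in (("sense", bias.n_sense),
                               ("antisense", bias.n_antisense)):
            se = np.sqrt(0.25 * 0.75 / n)
            frame = bias.sense if orientation == "sense" else bias.antisense
            assert (np.abs(frame.to_numpy() - 0.25) <= 3 * se + 0.02).all()

    def test_empty_window_flagged_undefined(self):
        bias = nucleotide_bias([], {})
        assert not bias.defined("sense") and not bias.defined("antisense")


class TestPingpongSignature:
    def test_zscores_mean_zero(self, genome_4k):
        _r, _l, aln = _sim(genome_4k, n_reads=5000)
        pp = pingpong_signature(aln)
        assert pp.defined and abs(pp.zscore.mean()) < 1e-9

    def test_pair_weights_match_allpairs_oracle(self, genome_2seg):
        _r, _l, aln = _sim(genome_2seg, frac_sirna=0, frac_pirna=1.0,
                           frac_noise=0, pingpong_prob=0.5, n_reads=1500)
        pp = pingpong_signature(aln)
        oracle = allpairs_pair_weight(aln)
        np.testing.assert_allclose(pp.pair_weight, oracle)

    def test_pingpong_enrichment_at_10(self, genome_4k):
        _r, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=1.0, frac_noise=0,
                           pingpong_prob=0.6, n_reads=10000, seed=5)
        pp = pingpong_signature(aln)
        assert pp.argmax_overlap == 10 and pp.z(10) >= 3.0

    def test_single_strand_flagged_undefined(self):
        aln = [_aln(f"r{i}", "s", "+", 10 * i, 10 * i + 27) for i in range(5)]
        pp = pingpong_signature(aln)
        assert not pp.defined and np.isnan(pp.pair_weight).all()

    def test_reference_revcomp_symmetry(self, genome_4k):
        # mirroring coordinates and flipping strands is the exact symmetry:
        # z-scores invariant, orientation fraction f -> 1 - f
        _r, _l, aln = _sim(genome_4k, frac_sirna=0, frac_pirna=1.0, frac_noise=0,
                           pingpong_prob=0.5, n_reads=4000, seed=6)
        L = 4000
        flip = {"+": "-", "-": "+"}
        mirrored = [_aln(a.read_id, a.segment_id, flip[a.strand],
                         L - a.end, L - a.start) for a in aln]
        pp, ppm = pingpong_signature(aln), pingpong_signature(mirrored)
        np.testing.assert_allclose(pp.zscore, ppm.zscore, atol=1e-9)
        prof, profm = size_distribution(aln), size_distribution(mirrored)
        f = prof.window_counts()["+"] / prof.window_counts().sum()
        fm = profm.window_counts()["+"] / profm.window_counts().sum()
        assert f == pytest.approx(1 - fm)


class TestClassifyRnai:
    def _call(self, genome, **kw):
        reads, _l, aln = _sim(genome, **kw)
        *_n, call = profile_pair(aln, {r.id: str(r.seq) for r in reads})
        return call

    def test_not_detected_below_minimum(self, genome_4k):
        call = self._call(genome_4k, n_reads=50)
        assert call.status == "NOT_DETECTED"

    def test_pure_sirna_regime(self, genome_4k):
        call = self._call(genome_4k, frac_sirna=0.8, frac_pirna=0,
                          frac_noise=0.2, n_reads=4000)
        assert call.status == "ACTIVE_SIRNA"

    def test_eve_regime(self, genome_4k):
        call = self._call(genome_4k, frac_sirna=0, frac_pirna=0.9,
                          frac_noise=0.1, eve_mode=True, n_reads=4000)
        assert call.status == "EVE_LIKE"

    def test_pingpong_regime(self, genome_4k):
        call = self._call(genome_4k, frac_sirna=0, frac_pirna=0.8,
                          frac_noise=0.2, pingpong_prob=0.6, n_reads=4000)
        assert call.status == "PIRNA_PINGPONG"

    def test_combined_regime(self, genome_4k):
        call = self._call(genome_4k, frac_sirna=0.4, frac_pirna=0.4,
                          frac_noise=0.2, pingpong_prob=0.6, n_reads=6000)
        assert call.status == "ACTIVE_SIRNA_PLUS_PIRNA"
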
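"""Synthetic genome / small-RNA library / presence panel generators."""
import io as _io

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO
from viromesig.simulate import (GenomeSpec, PanelSimConfig, SmallRnaSimConfig,
                                VirusModel, make_genome,
                                simulate_presence_panel,
                                simulate_small_rna_library)


class TestMakeGenome:
    def test_deterministic_and_correct_lengths(self):
        spec = GenomeSpec(segment_lengths=(4000,), gc_fraction=0.5, seed=1)
        a, b = make_genome(spec), make_genome(spec)
        assert len(a[0].seq) == 4000
        assert str(a[0].seq) == str(b[0].seq)
        assert set(str(a[0].seq)) <= set("ACGT")

    def test_binegevirus_sized_segments(self):
        # the bi-segmented negev-like genome layout: ~7600 + ~4600 nt
        recs = make_genome(GenomeSpec(segment_lengths=(7600, 4600),
                                      gc_fraction=0.45, seed=2))
        assert [len(r.seq) for r in recs] == [7600, 4600]
        for rec in recs:
            gc = sum(str(rec.seq).count(b) for b in "GC") / len(rec.seq)
            assert abs(gc - 0.45) < 0.03

    def test_gc_zero_gives_at_only(self):
        recs = make_genome(GenomeSpec(segment_lengths=(1000,) * 3,
                                      gc_fraction=0.0, seed=3))
        for rec in recs:
            assert set(str(rec.seq)) <= set("AT")

    @pytest.mark.parametrize("kwargs", [
        dict(segment_lengths=()),
        dict(segment_lengths=(-5,)),
        dict(segment_lengths=(50,)),
        dict(segment_lengths=(1000,), gc_fraction=1.5),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomeSpec(**kwargs)


class TestSmallRnaConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SmallRnaSimConfig(n_reads=10, frac_sirna=0.5, frac_pirna=0.5,
                              frac_noise=0.2)

    def test_eve_mode_moves_sirna_mass_to_pirna(self):
        cfg = SmallRnaSimConfig(n_reads=10, frac_sirna=0.4, frac_pirna=0.4,
                                frac_noise=0.2, eve_mode=True).effective()
        assert cfg.frac_sirna == 0.0
        assert cfg.frac_pirna == pytest.approx(0.8)


class TestSmallRnaLibrary:
    def test_sirna_only_peaks_at_21(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=10000, frac_sirna=1.0, frac_pirna=0.0,
                                frac_noise=0.0, seed=7)
        _reads, labels = simulate_small_rna_library(genome_4k, cfg)
        assert labels.length.mode()[0] == 21

    def test_read_lengths_in_range(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=2000, seed=8)
        reads, labels = simulate_small_rna_library(genome_4k, cfg)
        lens = np.array([len(r.seq) for r in reads])
        assert lens.min() >= 18 and lens.max() <= 32
        assert (labels.length.to_numpy() == lens).all()

    def test_class_fractions_within_3_se(self, genome_4k):
        n = 12000
        cfg = SmallRnaSimConfig(n_reads=n, frac_sirna=0.5, frac_pirna=0.3,
                                frac_noise=0.2, seed=9)
        _reads, labels = simulate_small_rna_library(genome_4k, cfg)
        observed = {
            "sirna": (labels.source_class == "sirna").mean(),
            "pirna": labels.source_class.isin(
                ["primary-pirna", "secondary-pirna"]).mean(),
            "noise": (labels.source_class == "noise").mean(),
        }
        for key, p in (("sirna", 0.5), ("pirna", 0.3), ("noise", 0.2)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed[key] - p) <= 3 * se

    def test_pingpong_partners_have_exact_10nt_overlap(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=4000, frac_sirna=0.0, frac_pirna=1.0,
                                frac_noise=0.0, pingpong_prob=0.8, seed=10)
        _reads, labels = simulate_small_rna_library(genome_4k, cfg)
        paired = labels[labels.partner_id != ""]
        assert len(paired) > 0
        partner_pos5 = labels.set_index("read_id").pos5
        for row in paired.itertuples(index=False):
            # sense 5' sits exactly 10 nt into the partner's 5' end
            assert row.pos5 == partner_pos5[row.partner_id] - 9

    def test_eve_mode_single_orientation_no_sirna(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=5000, frac_sirna=0.3, frac_pirna=0.5,
                                frac_noise=0.2, eve_mode=True, seed=11)
        _reads, labels = simulate_small_rna_library(genome_4k, cfg)
        viral = labels[labels.source_class.str.contains("pirna")]
        assert set(viral.strand) == {"-"}
        assert (labels.source_class == "sirna").sum() == 0
        # 20-22 nt reads only from the noise class
        short = labels[(labels.length >= 20) & (labels.length <= 22)]
        assert set(short.source_class) <= {"noise"}

    def test_forced_u1_bias(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=2000, frac_sirna=0.0, frac_pirna=1.0,
                                frac_noise=0.0, pingpong_prob=0.0, u1_bias=1.0,
                                seed=12)
        reads, labels = simulate_small_rna_library(genome_4k, cfg)
        seqs = {r.id: str(r.seq) for r in reads}
        anti = labels[labels.strand == "-"]
        assert len(anti) > 0
        assert all(seqs[rid][0] == "T" for rid in anti.read_id)

    def test_forced_a10_bias(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=2000, frac_sirna=0.0, frac_pirna=1.0,
                                frac_noise=0.0, pingpong_prob=0.0, a10_bias=1.0,
                                seed=13)
        reads, labels = simulate_small_rna_library(genome_4k, cfg)
        seqs = {r.id: str(r.seq) for r in reads}
        sense = labels[labels.strand == "+"]
        assert len(sense) > 0
        assert all(seqs[rid][9] == "A" for rid in sense.read_id)

    def test_seed_determinism_byte_identical_fastq(self, genome_4k):
        cfg = SmallRnaSimConfig(n_reads=500, seed=14)
        out = []
        for _ in range(2):
            reads, _labels = simulate_small_rna_library(genome_4k, cfg)
            buf = _io.StringIO()
            SeqIO.write(reads, buf, "fastq")
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_empty_library_needs_flag(self, genome_4k):
        with pytest.raises(ValueError):
            simulate_small_rna_library(genome_4k,
                                       SmallRnaSimConfig(n_reads=0, seed=1))
        reads, labels = simulate_small_rna_library(
            genome_4k, SmallRnaSimConfig(n_reads=0, seed=1), allow_empty=True)
        assert reads == [] and labels.empty

    def test_short_segment_rejected(self):
        recs = make_genome(GenomeSpec(segment_lengths=(100,), seed=1))
        recs[0] = recs[0][:30]
        with pytest.raises(ValueError):
            simulate_small_rna_library(recs, SmallRnaSimConfig(n_reads=10, seed=1))


class TestPresencePanel:
    def test_perfect_cosegregation(self):
        vm = VirusModel("v", ("s1", "s2"), prevalence=0.5)
        cfg = PanelSimConfig(n_libraries=20, virus_models=(vm,),
                             segment_dropout=0.0, contamination_rate=0.0, seed=1)
        presence, rpkm, truth = simulate_presence_panel(cfg)
        assert (presence.loc["s1"] == presence.loc["s2"]).all()
        assert (presence.loc["s1"] == truth.loc["v"]).all()
        assert ((rpkm.to_numpy() > 0) == presence.to_numpy()).all()

    def test_satellite_tracks_core_when_dependence_is_one(self):
        vm = VirusModel("v", ("core", "sat"), satellite_ids=("sat",),
                        prevalence=0.6)
        cfg = PanelSimConfig(n_libraries=30, virus_models=(vm,),
                             satellite_dependence=1.0, contamination_rate=0.0,
                             seed=2)
        presence, _, truth = simulate_presence_panel(cfg)
        assert (presence.loc["sat"] == truth.loc["v"]).all()

    def test_full_contamination_fills_matrix(self):
        vm = VirusModel("v", ("s1", "s2"), prevalence=0.0)
        cfg = PanelSimConfig(n_libraries=10, virus_models=(vm,),
                             contamination_rate=1.0, seed=3)
        presence, _, _ = simulate_presence_panel(cfg)
        assert presence.to_numpy().all()

    def test_reproducible_under_seed(self):
        vm = VirusModel("v", ("s1",), prevalence=0.4)
        cfg = PanelSimConfig(n_libraries=15, virus_models=(vm,),
                             segment_dropout=0.1, seed=4)
        a = simulate_presence_panel(cfg)[0]
        b = simulate_presence_panel(cfg)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_empty_virus_list_rejected(self):
        with pytest.raises(ValueError):
            PanelSimConfig(n_libraries=5, virus_models=())
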
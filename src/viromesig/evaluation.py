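"""Seeded evaluation experiments over the synthetic study conditions.

These routines define the package's reference experiments: regime-recovery
of the RNAi classifier, ping-pong null calibration, co-occurrence
permutation calibration and power.  Each draws its parameters from the
generative regimes the simulator models (non-boundary draws), runs the
corresponding analysis end to end, and reports a summary statistic.
Problem sizes are the package's reference defaults; every experiment is
deterministic under its seed.
"""
from __future__ import annotations

import numpy as np

from ._util import child_seed
from .cooccur import IncriminationRule, incriminate, permutation_test
from .signatures import RnaiThresholds, pingpong_signature, profile_pair
from .simulate import (GenomeSpec, PanelSimConfig, SmallRnaSimConfig,
                       VirusModel, make_genome, simulate_presence_panel,
                       simulate_small_rna_library, truth_alignments)

REGIMES = ("sirna", "pingpong", "both", "eve")
REGIME_STATUS = {"sirna": "ACTIVE_SIRNA", "pingpong": "PIRNA_PINGPONG",
                 "both": "ACTIVE_SIRNA_PLUS_PIRNA", "eve": "EVE_LIKE"}


def draw_regime_config(regime: str, rng: np.random.Generator,
                       n_reads: int = 3000, seed: int = 0) -> SmallRnaSimConfig:
    """Sample a non-boundary parameter draw from one generative regime."""
    u = rng.uniform
    if regime == "sirna":
        fs = u(0.6, 0.85)
        return SmallRnaSimConfig(n_reads=n_reads, frac_sirna=fs, frac_pirna=0.0,
                                 frac_noise=1 - fs,
                                 sirna_strand_balance=u(0.4, 0.6), seed=seed)
    if regime == "pingpong":
        fp = u(0.6, 0.85)
        return SmallRnaSimConfig(n_reads=n_reads, frac_sirna=0.0, frac_pirna=fp,
                                 frac_noise=1 - fp, pingpong_prob=u(0.4, 0.8),
                                 u1_bias=u(0.8, 0.95), a10_bias=u(0.8, 0.95),
                                 seed=seed)
    if regime == "both":
        fs, fp = u(0.3, 0.45), u(0.3, 0.45)
        return SmallRnaSimConfig(n_reads=n_reads, frac_sirna=fs, frac_pirna=fp,
                                 frac_noise=1 - fs - fp,
                                 pingpong_prob=u(0.4, 0.8),
                                 u1_bias=u(0.8, 0.95), a10_bias=u(0.8, 0.95),
                                 seed=seed)
    if regime == "eve":
        fp = u(0.85, 0.95)
        return SmallRnaSimConfig(n_reads=n_reads, frac_sirna=0.0, frac_pirna=fp,
                                 frac_noise=1 - fp, eve_mode=True,
                                 u1_bias=u(0.8, 0.95), seed=seed)
    raise ValueError(f"unknown regime '{regime}'")


def regime_recovery(n_pairs: int = 200, seed: int = 0,
                    n_reads: int = 3000, genome_length: int = 4000
                    ) -> tuple[int, int]:
    """Classify n_pairs simulated virus-library pairs; count regime recoveries."""
    rng = np.random.default_rng(child_seed(seed, "recovery"))
    thresholds = RnaiThresholds()
    n_correct = 0
    for i in range(n_pairs):
        regime = REGIMES[i % len(REGIMES)]
        genome = make_genome(GenomeSpec(segment_lengths=(genome_length,),
                                        seed=child_seed(seed, f"recov-g{i}")))
        cfg = draw_regime_config(regime, rng, n_reads=n_reads,
                                 seed=child_seed(seed, f"recov-r{i}"))
        reads, labels = simulate_small_rna_library(genome, cfg)
        alignments = truth_alignments(labels)
        read_seqs = {rec.id: str(rec.seq) for rec in reads}
        *_, call = profile_pair(alignments, read_seqs, thresholds)
        if call.status == REGIME_STATUS[regime]:
            n_correct += 1
    return n_correct, n_pairs


def pingpong_zscore(seed: int = 0, n_reads: int = 20000,
                    pingpong_prob: float = 0.5,
                    genome_length: int = 4000) -> tuple[float, int]:
    """z[10] and argmax overlap of one ping-pong-positive library."""
    genome = make_genome(GenomeSpec(segment_lengths=(genome_length,),
                                    seed=child_seed(seed, "pp-genome")))
    cfg = SmallRnaSimConfig(n_reads=n_reads, frac_sirna=0.0, frac_pirna=0.8,
                            frac_noise=0.2, pingpong_prob=pingpong_prob,
                            seed=child_seed(seed, "pp-reads"))
    _reads, labels = simulate_small_rna_library(genome, cfg)
    pp = pingpong_signature(truth_alignments(labels))
    return pp.z(10), pp.argmax_overlap


def pingpong_null_below(n_runs: int = 100, seed: int = 0, z_thresh: float = 3.0,
                        n_reads: int = 2000,
                        genome_length: int = 4000) -> tuple[int, int]:
    """Count runs with |z[10]| below threshold under independent strands."""
    genome = make_genome(GenomeSpec(segment_lengths=(genome_length,),
                                    seed=child_seed(seed, "null-genome")))
    within = 0
    for i in range(n_runs):
        cfg = SmallRnaSimConfig(n_reads=n_reads, frac_sirna=0.0, frac_pirna=1.0,
                                frac_noise=0.0, pingpong_prob=0.0,
                                u1_bias=0.0, a10_bias=0.0,
                                seed=child_seed(seed, f"null-{i}"))
        _reads, labels = simulate_small_rna_library(genome, cfg)
        pp = pingpong_signature(truth_alignments(labels))
        if abs(pp.z(10)) < z_thresh:
            within += 1
    return within, n_runs


# Reference panel conditions for co-occurrence power: 40 libraries,
# prevalence drawn U(0.3, 0.7), dropout 0.01, contamination 0.005.
POWER_PANEL = dict(n_libraries=40, segment_dropout=0.01,
                   contamination_rate=0.005)


def cooccur_power(n_panels: int = 100, seed: int = 0,
                  n_permutations: int = 499) -> tuple[int, int]:
    """Fraction of two-segment-virus panels incriminated as same-virus."""
    rng = np.random.default_rng(child_seed(seed, "power"))
    rule = IncriminationRule()
    hits = 0
    for i in range(n_panels):
        vm = VirusModel("v", ("s1", "s2"),
                        prevalence=float(rng.uniform(0.3, 0.7)))
        cfg = PanelSimConfig(virus_models=(vm,),
                             seed=child_seed(seed, f"power-{i}"), **POWER_PANEL)
        presence, _, _ = simulate_presence_panel(cfg)
        stats = permutation_test(presence, ["s1", "s2"],
                                 n_permutations=n_permutations,
                                 seed=child_seed(seed, f"power-perm-{i}"))
        if incriminate(stats, rule).decision == "same-virus":
            hits += 1
    return hits, n_panels


def cooccur_calibration(n_runs: int = 200, seed: int = 0,
                        n_permutations: int = 199,
                        n_libraries: int = 40) -> tuple[int, int]:
    """Count p-values below 0.05 for independent segments (null calibration)."""
    below = 0
    done = 0
    for i in range(n_runs):
        models = (VirusModel("a", ("s1",), prevalence=0.5),
                  VirusModel("b", ("s2",), prevalence=0.5))
        cfg = PanelSimConfig(n_libraries=n_libraries, virus_models=models,
                             seed=child_seed(seed, f"cal-{i}"))
        presence, _, _ = simulate_presence_panel(cfg)
        stats = permutation_test(presence, ["s1", "s2"],
                                 n_permutations=n_permutations,
                                 seed=child_seed(seed, f"cal-perm-{i}"))
        if not stats.p_defined:
            continue  # degenerate marginal draw; excluded from calibration
        done += 1
        if stats.permutation_p < 0.05:
            below += 1
    return below, done
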
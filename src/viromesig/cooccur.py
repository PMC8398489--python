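"""Segment co-appearance statistics and incrimination of multi-segment sets.

Segments of one virus must co-appear across libraries; consistency is the
fraction of libraries positive for any segment of the candidate set that
are positive for all of them.  A permutation null shuffles each segment's
presence column independently across libraries (preserving per-segment
prevalence) to guard against prevalence-driven coincidence.  Asymmetric
conditional presence (satellite implies core, core often without the
satellite) flags a likely satellite segment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class CooccurrenceStats:
    segment_ids: tuple[str, ...]
    n_libraries: int
    n_any: int
    n_all: int
    consistency: float
    conditional_presence: pd.DataFrame   # P(row present | column present)
    permutation_p: float = float("nan")
    p_defined: bool = False
    n_permutations: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class IncriminationRule:
    min_positive_libraries: int = 2
    min_consistency: float = 0.9
    alpha: float = 0.01

    def __post_init__(self):
        if self.min_positive_libraries < 2:
            raise ValueError("min_positive_libraries must be >= 2 "
                             "(co-appearance needs multiple libraries)")


def _submatrix(panel: pd.DataFrame, segment_ids: Sequence[str]) -> np.ndarray:
    missing = [s for s in segment_ids if s not in panel.index]
    if missing:
        raise KeyError(f"unknown segment id(s): {missing}")
    if len(set(segment_ids)) != len(segment_ids):
        raise ValueError("segment_ids must be unique")
    return panel.loc[list(segment_ids)].to_numpy(dtype=bool)


def co_appearance(panel: pd.DataFrame, segment_ids: Sequence[str]) -> CooccurrenceStats:
    """Exact co-appearance counts and conditional presence matrix."""
    S = _submatrix(panel, segment_ids)
    n_any = int(S.any(axis=0).sum())
    n_all = int(S.all(axis=0).sum())
    consistency = n_all / n_any if n_any else float("nan")
    k = len(segment_ids)
    cond = np.full((k, k), np.nan)
    col_counts = S.sum(axis=1)
    for j in range(k):
        if col_counts[j] > 0:
            cond[:, j] = (S & S[j]).sum(axis=1) / col_counts[j]
    cond_df = pd.DataFrame(cond, index=list(segment_ids), columns=list(segment_ids))
    return CooccurrenceStats(segment_ids=tuple(segment_ids),
                             n_libraries=panel.shape[1], n_any=n_any,
                             n_all=n_all, consistency=consistency,
                             conditional_presence=cond_df)


def permutation_test(panel: pd.DataFrame, segment_ids: Sequence[str],
                     n_permutations: int = 999, seed: int = 0) -> CooccurrenceStats:
    """Co-appearance stats plus a marginal-preserving permutation p-value.

    p = (1 + #{null consistency >= observed}) / (n_permutations + 1).
    Degenerate marginals (a segment present everywhere or nowhere) leave
    the p-value undefined-flagged.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    stats = co_appearance(panel, segment_ids)
    stats.n_permutations = n_permutations
    stats.seed = seed
    S = _submatrix(panel, segment_ids)
    n_lib = S.shape[1]
    marg = S.sum(axis=1)
    if np.isnan(stats.consistency) or (marg == 0).any() or (marg == n_lib).any():
        return stats  # p stays NaN / undefined
    rng = np.random.default_rng(seed)
    tiled = np.broadcast_to(S, (n_permutations, *S.shape)).copy()
    null = rng.permuted(tiled, axis=2)   # each segment row shuffled independently
    n_all = null.all(axis=1).sum(axis=1)
    n_any = null.any(axis=1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        null_cons = np.where(n_any > 0, n_all / np.maximum(n_any, 1), 0.0)
    exceed = int((null_cons >= stats.consistency - 1e-12).sum())
    stats.permutation_p = (1 + exceed) / (n_permutations + 1)
    stats.p_defined = True
    return stats


@dataclass
class Incrimination:
    decision: str                 # same-virus | satellite-of | unsupported
    rationale: str
    satellite_ids: tuple[str, ...] = field(default_factory=tuple)


def incriminate(stats: CooccurrenceStats,
                rule: IncriminationRule = IncriminationRule()) -> Incrimination:
    """Decide whether a segment set behaves as one virus, a satellite, or neither."""
    cond = stats.conditional_presence
    if (stats.n_all >= rule.min_positive_libraries
            and not np.isnan(stats.consistency)
            and stats.consistency >= rule.min_consistency
            and stats.p_defined and stats.permutation_p <= rule.alpha):
        return Incrimination(
            "same-virus",
            f"all {len(stats.segment_ids)} segments co-appear in "
            f"{stats.n_all}/{stats.n_any} positive libraries "
            f"(consistency {stats.consistency:.3f}, p={stats.permutation_p:.4g})")
    # Satellite pattern: whenever the candidate is present the others are
    # too, but the others appear without it.
    for sat in stats.segment_ids:
        others = [s for s in stats.segment_ids if s != sat]
        p_core_given_sat = cond.loc[others, sat].min()
        p_sat_given_core = cond.loc[sat, others].min()
        if (not np.isnan(p_core_given_sat)
                and p_core_given_sat >= rule.min_consistency
                and not np.isnan(p_sat_given_core)
                and p_sat_given_core < rule.min_consistency):
            return Incrimination(
                "satellite-of",
                f"{sat} is present only alongside {others} "
                f"(P(core|{sat})={p_core_given_sat:.3f}) but the core appears "
                f"without it (P({sat}|core)={p_sat_given_core:.3f})",
                satellite_ids=(sat,))
    return Incrimination(
        "unsupported",
        f"co-appearance insufficient: n_all={stats.n_all}, "
        f"consistency={stats.consistency}, p={stats.permutation_p}")
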
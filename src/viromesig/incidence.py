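"""Per-library virus abundance, presence calling and clustered incidence.

Abundance is RPKM = mapped_reads / (library_total/1e6 x genome_length/1e3);
presence requires either a read-count-plus-breadth rule (breadth of
coverage formalises "sufficient coverage" inspection of mapping profiles)
or an assembly-contig rule (>85% nucleotide identity over >=500 bp).
Incidence matrices carry log10(RPKM + 1) and are ordered by agglomerative
complete-linkage clustering under the Pearson correlation distance
d(x, y) = 1 - r(x, y), the construction behind the usual virome heat maps.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

ZERO_VARIANCE_DISTANCE = 2.0  # maximum of 1 - r; declared convention


# ------------------------------------------------------------ quantification

@dataclass
class VirusQuant:
    """Abundance of one virus in one library."""

    virus_id: str
    library_id: str
    mapped_reads: int
    library_total_reads: int
    genome_length_nt: int
    breadth: float = 0.0

    def __post_init__(self):
        if self.library_total_reads <= 0:
            raise ValueError("library_total_reads must be positive")
        if self.genome_length_nt <= 0:
            raise ValueError("genome_length_nt must be positive")
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError("breadth must lie in [0, 1]")

    @property
    def rpkm(self) -> float:
        return self.mapped_reads / (
            (self.library_total_reads / 1e6) * (self.genome_length_nt / 1e3))

    @property
    def percent_mapped(self) -> float:
        """Percent of the library mapping to this virus, half-up to 2 dp."""
        return round_half_up(100.0 * self.mapped_reads / self.library_total_reads, 2)


def quantify(virus_id: str, library_id: str, mapped_reads: int,
             library_total_reads: int, genome_length_nt: int,
             breadth: float = 0.0) -> VirusQuant:
    return VirusQuant(virus_id=virus_id, library_id=library_id,
                      mapped_reads=int(mapped_reads),
                      library_total_reads=int(library_total_reads),
                      genome_length_nt=int(genome_length_nt), breadth=breadth)


def percent_mapped(mapped_reads: int, library_total_reads: int) -> float:
    """Reported mapping percentage, rounded half-up to two decimals."""
    if library_total_reads <= 0:
        raise ValueError("library_total_reads must be positive")
    return round_half_up(100.0 * mapped_reads / library_total_reads, 2)


# ------------------------------------------------------------ presence calls

@dataclass(frozen=True)
class PresenceThresholds:
    """Read-based rule (N_min AND breadth) OR contig rule (identity/length)."""

    n_min: int = 100
    breadth_min: float = 0.10
    contig_min_identity: float = 0.85   # exclusive: identity must exceed this
    contig_min_bp: int = 500


def call_presence(quant: VirusQuant,
                  contig_hits: Iterable[tuple[float, int]] | None = None,
                  thresholds: PresenceThresholds = PresenceThresholds()
                  ) -> tuple[bool, str]:
    """Presence decision with a reason code naming the clause that fired."""
    t = thresholds
    for identity, aligned_bp in (contig_hits or []):
        if identity > t.contig_min_identity and aligned_bp >= t.contig_min_bp:
            return True, "contig_hit"
    if quant.mapped_reads >= t.n_min:
        if quant.breadth >= t.breadth_min:
            return True, "reads_and_breadth"
        return False, "low_breadth"
    return False, "low_reads"


# ---------------------------------------------------------- incidence matrix

@dataclass
class PresenceMatrix:
    """Taxa x libraries booleans plus the parallel log-abundance matrix."""

    presence: pd.DataFrame
    log_abundance: pd.DataFrame   # log10(rpkm + pseudocount) where present, else 0
    thresholds: PresenceThresholds = field(default_factory=PresenceThresholds)


def incidence_matrix(quants: Sequence[VirusQuant],
                     presence_calls: dict[tuple[str, str], bool],
                     thresholds: PresenceThresholds = PresenceThresholds(),
                     pseudocount: float = 1.0) -> PresenceMatrix:
    """Assemble the clustered-heat-map input: presence + log10(RPKM + 1)."""
    taxa, libraries, seen = [], [], set()
    for q in quants:
        key = (q.virus_id, q.library_id)
        if key in seen:
            raise ValueError(f"duplicate (taxon, library) entry {key}")
        seen.add(key)
        if q.virus_id not in taxa:
            taxa.append(q.virus_id)
        if q.library_id not in libraries:
            libraries.append(q.library_id)
    presence = pd.DataFrame(False, index=taxa, columns=libraries)
    log_ab = pd.DataFrame(0.0, index=taxa, columns=libraries)
    for q in quants:
        present = presence_calls.get((q.virus_id, q.library_id), False)
        presence.loc[q.virus_id, q.library_id] = present
        if present:
            log_ab.loc[q.virus_id, q.library_id] = float(
                np.log10(q.rpkm + pseudocount))
    return PresenceMatrix(presence=presence, log_abundance=log_ab,
                          thresholds=thresholds)


# -------------------------------------------------------------- clustering

def pearson_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r; zero-variance profiles get the maximum 2."""
    n = profiles.shape[0]
    D = np.zeros((n, n))
    sd = profiles.std(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0.0 or sd[j] == 0.0:
                d = ZERO_VARIANCE_DISTANCE
            else:
                r = float(np.corrcoef(profiles[i], profiles[j])[0, 1])
                d = 1.0 - r
            D[i, j] = D[j, i] = d
    return D


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage layout (leaves 0..n-1)."""

    merges: np.ndarray          # (n-1, 4): left id, right id, height, size
    labels: list[str]

    def to_newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            left = f"{node[a]}:{h - height[a]:.6g}"
            right = f"{node[b]}:{h - height[b]:.6g}"
            nid = n + step
            node[nid] = f"({left},{right})"
            height[nid] = float(h)
        return node[n + len(self.merges) - 1] + ";"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Agglomerative complete-linkage clustering under Pearson distance.

    Ties in the minimum inter-cluster distance are broken by the smallest
    original leaf index of the two candidate clusters; complete linkage
    makes merge heights non-decreasing.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    frame = matrix if axis == "rows" else matrix.T
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 profiles to cluster")
    labels = [str(x) for x in frame.index]
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    D = pearson_distance_matrix(X)

    cluster_id = list(range(n))          # current scipy-style id per active cluster
    rep = list(range(n))                 # smallest original leaf index per cluster
    size = [1] * n
    active = list(range(n))              # positions into the D matrix rows
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (D[i, j], min(rep[i], rep[j]), max(rep[i], rep[j]))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        (dist, _r1, _r2), ai, aj = best
        i, j = active[ai], active[aj]
        a, b = sorted((cluster_id[i], cluster_id[j]))
        merges[step] = (a, b, dist, size[i] + size[j])
        # complete linkage via Lance-Williams: d(new, m) = max(d(i,m), d(j,m))
        for m in active:
            if m not in (i, j):
                D[i, m] = D[m, i] = max(D[i, m], D[j, m])
        cluster_id[i] = next_id
        rep[i] = min(rep[i], rep[j])
        size[i] = size[i] + size[j]
        next_id += 1
        active.pop(aj)
    return Dendrogram(merges=merges, labels=labels)


def plot_heatmap(matrix: PresenceMatrix, path, *, cluster: bool = True) -> None:
    """Optional heat-map rendering of log10(RPKM + 1) incidence."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.log_abundance
    if cluster and data.shape[0] >= 2:
        order = _leaf_order(hierarchical_cluster(data, "rows"))
        data = data.iloc[order]
    if cluster and data.shape[1] >= 2:
        order = _leaf_order(hierarchical_cluster(data, "columns"))
        data = data.iloc[:, order]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * data.shape[1]),
                                    max(3, 0.4 * data.shape[0])))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log10(RPKM + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _leaf_order(dend: Dendrogram) -> list[int]:
    n = len(dend.labels)
    children = {n + s: (int(a), int(b)) for s, (a, b, _h, _sz) in enumerate(dend.merges)}

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    return leaves(n + len(dend.merges) - 1)
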
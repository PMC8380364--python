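"""Enterotype-like clustering of community profiles.

Samples are clustered on genus-level relative abundances using the
root Jensen–Shannon divergence (a metric on the probability simplex) and
Partitioning Around Medoids (PAM). The number of clusters is chosen by the
Calinski–Harabasz (CH) index computed directly from the distance matrix via
the Huygens/Gower identity; the mean silhouette width is reported alongside
as a robustness check. Each cluster is labelled by its dominant genus
(highest mean relative abundance), mirroring the Prevotella- vs
Treponema-dominated community types seen in pig cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .tables import OtuTable

__all__ = [
    "DistanceMatrix",
    "EnterotypeResult",
    "jsd_matrix",
    "pam_cluster",
    "select_k",
    "enterotype_profile",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample identifiers."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class EnterotypeResult:
    k_selected: int
    assignments: pd.Series          # sample id -> cluster label (0-based)
    medoids: list[str]
    ch_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    dominant_taxon: dict[int, str] = field(default_factory=dict)


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    """Shannon entropy of each row, natural log, 0*log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=1)


def jsd_matrix(table: OtuTable, sqrt: bool = True) -> DistanceMatrix:
    """Pairwise (root) Jensen–Shannon divergence between sample profiles.

    JSD(x, y) = H((x+y)/2) - (H(x) + H(y))/2 with natural-log entropies —
    algebraically identical to the half-KL form and finite with zeros
    because the mixture is positive wherever either argument is. The
    default returns sqrt(JSD), which is a metric; ``sqrt=False`` gives the
    raw divergence.
    """
    if table.kind != "relative":
        raise ValueError("jsd_matrix expects a relative-abundance table")
    p = table.values
    n = p.shape[0]
    h = _entropy_rows(p)
    d = np.zeros((n, n))
    # blocked pairwise mixture entropies: O(n^2 G) flops, modest memory
    block = max(1, int(2e7 // max(1, n * p.shape[1])))
    for start in range(0, n, block):
        stop = min(start + block, n)
        m = (p[start:stop, None, :] + p[None, :, :]) / 2.0
        hm = _entropy_rows(m.reshape(-1, p.shape[1])).reshape(stop - start, n)
        d[start:stop] = hm - (h[start:stop, None] + h[None, :]) / 2.0
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    if sqrt:
        d = np.sqrt(d)
    return DistanceMatrix(table.sample_ids, d)


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam_cluster(
    dist: DistanceMatrix, k: int, seed: int | None = None
) -> tuple[np.ndarray, list[int]]:
    """Classic PAM (BUILD then best-improvement SWAP) on a distance matrix.

    Deterministic: ties are broken toward the lowest index, so the result
    does not depend on ``seed`` (kept for interface symmetry). Returns
    (assignments as indices into ``dist.ids`` of shape n, medoid indices).
    """
    d = dist.d
    n = dist.n
    if not 2 <= k < n:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")

    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP: best improving (medoid, candidate) exchange until none improves
    cost = _pam_cost(d, medoids)
    for _ in range(200):
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            d_others = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for c in range(n):
                if c in med_set:
                    continue
                new_cost = float(np.minimum(d_others, d[:, c]).sum())
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, c)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        new_cost = _pam_cost(d, medoids)
        assert new_cost <= cost + 1e-9, "SWAP must never increase the cost"
        cost = new_cost
    medoids = sorted(medoids)
    assignments = np.argmin(d[:, medoids], axis=1)
    return assignments, medoids


def _ch_index(d: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Calinski–Harabasz from squared pairwise distances (Huygens identity).

    W = sum_clusters (1/n_c) sum_{i<j in c} d^2_ij; B = T - W with
    T = (1/n) sum_{i<j} d^2_ij; CH = [B/(k-1)] / [W/(n-k)]. W = 0 (perfect
    duplicate clusters) maps to +inf.
    """
    n = len(labels)
    d2 = d**2
    total = d2[np.triu_indices(n, 1)].sum() / n
    within = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    between = max(total - within, 0.0)
    if within <= 1e-15:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def select_k(
    dist: DistanceMatrix, k_range: range | list[int] = range(2, 11)
) -> EnterotypeResult:
    """Run PAM across ``k_range`` and pick k by the CH index.

    The mean silhouette width at each k is reported for robustness but does
    not drive the choice. k values that produce an empty cluster are
    skipped with a warning.
    """
    ks = [k for k in k_range if 2 <= k < dist.n]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    ch_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    results: dict[int, tuple[np.ndarray, list[int]]] = {}
    for k in ks:
        labels, medoids = pam_cluster(dist, k)
        if len(np.unique(labels)) < k:
            warnings.warn(f"k={k} produced an empty cluster; skipped")
            continue
        ch_by_k[k] = _ch_index(dist.d, labels, k)
        sil_by_k[k] = float(
            silhouette_score(dist.d, labels, metric="precomputed")
        )
        results[k] = (labels, medoids)
    if not ch_by_k:
        raise ValueError("no k in range produced a valid clustering")
    k_sel = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    labels, medoids = results[k_sel]
    assignments = pd.Series(labels, index=pd.Index(dist.ids, name="sample_id"),
                            name="enterotype")
    return EnterotypeResult(
        k_selected=k_sel,
        assignments=assignments,
        medoids=[dist.ids[m] for m in medoids],
        ch_by_k=ch_by_k,
        silhouette_by_k=sil_by_k,
    )


def enterotype_profile(
    table: OtuTable, assignments: pd.Series
) -> dict[int, str]:
    """Dominant taxon (highest mean relative abundance) per cluster.

    Exact ties are broken lexicographically with a warning. ``table`` is
    usually genus-level (see ``tables.aggregate_by_rank``).
    """
    if set(assignments.index) != set(table.sample_ids):
        raise ValueError("assignments do not cover the table's samples")
    out: dict[int, str] = {}
    for c in sorted(assignments.unique()):
        samples = assignments.index[assignments == c]
        means = table.data.loc[samples].mean(axis=0)
        top = means.max()
        winners = sorted(means.index[means == top])
        if len(winners) > 1:
            warnings.warn(
                f"cluster {c}: tie between {winners}; choosing {winners[0]}"
            )
        out[int(c)] = winners[0]
    return out
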
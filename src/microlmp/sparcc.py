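"""Compositionally-aware correlation (SparCC) and co-abundance groups.

Relative abundances are compositional — the sum-to-one closure induces
spurious negative correlation — so ordinary Pearson correlations of
fractions are biased. SparCC estimates the correlations of the *basis*
(unobserved absolute) abundances from log-ratio variances:

    t_ij = var(log(x_i / x_j))
         = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j)

Under a sparsity assumption (most true correlations near 0), the basis
variances omega solve the linear system t_i ~= (D-1) omega_i +
sum_{j != i} omega_j where t_i = sum_j t_ij, and the basis correlation
follows as rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)).
Strongly correlated pairs violate the sparsity assumption, so the
strongest pair is iteratively excluded from the system and the variances
re-solved. Counting noise is integrated out by resampling fractions from a
Dirichlet posterior (counts + 1) and taking the median estimate.

Co-abundance groups (CAGs) are then defined by Ward hierarchical
clustering of the dissimilarity (1 - rho)/2, validated by PERMANOVA on the
same dissimilarity, and summarized by per-sample CAG abundances correlated
with the phenotype (Spearman, BH-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enterotype import DistanceMatrix
from .tables import OtuTable
from .twopart import bh_adjust

__all__ = [
    "SparccResult",
    "CagAssignment",
    "sparcc",
    "cluster_cags",
    "scan_cags",
    "permanova",
    "cag_abundance",
    "cag_phenotype_correlation",
]


@dataclass
class SparccResult:
    rho: pd.DataFrame                 # taxa x taxa basis correlations
    omega: np.ndarray                 # per-taxon basis variances (last fit)
    t_matrix: np.ndarray              # log-ratio variance matrix
    excluded_pairs: list[tuple[str, str]]
    n_resamples: int
    seed: int | None


@dataclass
class CagAssignment:
    labels: pd.Series                 # taxon id -> CAG label (1-based)
    n_cags: int
    linkage_height_cut: float
    permanova_pseudo_F: float | None = None
    permanova_p: float | None = None


# ---------------------------------------------------------------------------
# SparCC core

def _logratio_variances(frac: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of log(x_i/x_j), via the covariance identity."""
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


def _solve_basis(t: np.ndarray, excluded: set[frozenset[int]]) -> np.ndarray:
    """Solve the sparsity approximation for the basis variances omega."""
    d = t.shape[0]
    m = np.ones((d, d))
    np.fill_diagonal(m, d - 1)
    t_eff = t.copy()
    for pair in excluded:
        i, j = tuple(pair)
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = t_eff[j, i] = 0.0
    t_vec = t_eff.sum(axis=1)
    return np.linalg.solve(m, t_vec)


def _basis_correlations(
    frac: np.ndarray,
    exclusion_threshold: float,
    max_exclusion_rounds: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, set[frozenset[int]]]:
    """One SparCC fit on a fraction matrix: (rho, omega, t, excluded pairs)."""
    t = _logratio_variances(frac)
    d = t.shape[0]
    excluded: set[frozenset[int]] = set()
    rho = omega = None
    for _ in range(max_exclusion_rounds + 1):
        omega = _solve_basis(t, excluded)
        bad = omega <= 0
        om = np.where(bad, np.nan, omega)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 2.0 * np.sqrt(np.outer(om, om))
            rho = (om[:, None] + om[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # strongest still-included off-diagonal pair above the threshold
        absr = np.abs(rho)
        np.fill_diagonal(absr, 0.0)
        for pair in excluded:
            i, j = tuple(pair)
            absr[i, j] = absr[j, i] = 0.0
        absr = np.where(np.isnan(absr), 0.0, absr)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= exclusion_threshold or len(excluded) >= max_exclusion_rounds:
            break
        excluded.add(frozenset((int(i), int(j))))
    if (omega <= 0).any():
        warnings.warn(
            f"{int((omega <= 0).sum())} taxa with non-positive basis variance; "
            "their correlations are undefined (NaN)"
        )
    return rho, omega, t, excluded


def sparcc(
    table: OtuTable,
    n_resamples: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    seed: int | None = 0,
) -> SparccResult:
    """Estimate basis correlations from a counts table.

    With ``n_resamples >= 1`` (default 20), fractions are drawn per sample
    from a Dirichlet posterior with a uniform prior (counts + 1) and the
    final rho is the entrywise median over resamples — robust to counting
    noise and occasional negative-variance pathologies. ``n_resamples=0``
    is the exact mode: fractions are the observed counts / row totals
    (requires a zero-free table; scale-invariant by construction).
    """
    if table.kind != "counts":
        raise ValueError("sparcc expects a counts table")
    counts = table.values.astype(float)
    n, d = counts.shape
    if d <= 3:
        raise ValueError("SparCC needs more than 3 taxa (basis system is degenerate)")
    if n < 25:
        warnings.warn("fewer than 25 samples; SparCC estimates will be noisy")

    if n_resamples == 0:
        if (counts == 0).any():
            raise ValueError(
                "exact mode (n_resamples=0) requires a zero-free table; "
                "use Dirichlet resampling for tables with zeros"
            )
        frac = counts / counts.sum(axis=1, keepdims=True)
        rho, omega, t, excl = _basis_correlations(
            frac, exclusion_threshold, max_exclusion_rounds
        )
    else:
        rng = np.random.default_rng(seed)
        rhos = []
        omega = t = None
        excl: set[frozenset[int]] = set()
        for _ in range(n_resamples):
            gam = rng.gamma(counts + 1.0)
            frac = gam / gam.sum(axis=1, keepdims=True)
            r, omega, t, e = _basis_correlations(
                frac, exclusion_threshold, max_exclusion_rounds
            )
            rhos.append(r)
            excl |= e
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rho = np.nanmedian(np.stack(rhos), axis=0)
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)

    ids = table.taxon_ids
    return SparccResult(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        omega=omega,
        t_matrix=t,
        excluded_pairs=[tuple(sorted((ids[i], ids[j]))) for i, j in
                        (tuple(p) for p in excl)],
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CAGs

def correlation_dissimilarity(rho: pd.DataFrame, mode: str = "half") -> pd.DataFrame:
    """(1 - rho)/2 (default, maps [-1,1] -> [0,1]) or 1 - rho."""
    if mode == "half":
        d = (1.0 - rho) / 2.0
    elif mode == "one_minus":
        d = 1.0 - rho
    else:
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d.values, 0.0)
    return d


def cluster_cags(
    rho: pd.DataFrame, n_cags: int, mode: str = "half"
) -> CagAssignment:
    """Ward-linkage clustering of the correlation dissimilarity into CAGs.

    Taxa whose correlations are undefined (NaN rows from a negative basis
    variance) are assigned singleton CAGs with a warning. Deterministic:
    Ward agglomeration on a fixed dissimilarity involves no randomness.
    """
    d_all = rho.shape[0]
    if not 1 <= n_cags <= d_all:
        raise ValueError(f"n_cags must be in [1, {d_all}]")
    nan_rows = rho.isna().any(axis=1)
    good = rho.index[~nan_rows].tolist()
    bad = rho.index[nan_rows].tolist()
    if bad:
        warnings.warn(f"{len(bad)} taxa with undefined correlations -> singleton CAGs")
    diss = correlation_dissimilarity(rho.loc[good, good], mode=mode)
    n_core = max(n_cags - len(bad), 1)
    if len(good) >= 2 and n_core >= 1:
        z = linkage(squareform(diss.values, checks=False), method="ward")
        core_labels = fcluster(z, t=n_core, criterion="maxclust")
        heights = z[:, 2]
        cut_idx = len(good) - n_core - 1
        height = float(heights[cut_idx]) if 0 <= cut_idx < len(heights) else 0.0
    else:
        core_labels = np.ones(len(good), dtype=int)
        height = 0.0
    labels = pd.Series(np.zeros(d_all, dtype=int),
                       index=pd.Index(rho.index, name="taxon_id"), name="cag")
    labels.loc[good] = core_labels
    next_label = int(core_labels.max()) + 1 if len(good) else 1
    for taxon in bad:
        labels.loc[taxon] = next_label
        next_label += 1
    return CagAssignment(
        labels=labels,
        n_cags=int(labels.nunique()),
        linkage_height_cut=height,
    )


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F with a label-permutation p-value.

    SS_total = (1/n) sum_{i<j} d^2_ij; SS_within = sum_g (1/n_g)
    sum_{i<j in g} d^2_ij; pseudo-F = [(SS_total - SS_within)/(g-1)] /
    [SS_within/(n-g)]; p = (1 + #{permuted F >= observed}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    n = dist.n
    if len(groups) != n:
        raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    d2 = dist.d**2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    g = len(uniq)

    codes = np.searchsorted(uniq, groups)

    def ss_within(c: np.ndarray) -> float:
        s = 0.0
        for k in range(g):
            idx = np.flatnonzero(c == k)
            sub = d2[np.ix_(idx, idx)]
            s += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return s

    def pseudo_f(c: np.ndarray) -> float:
        ssw = ss_within(c)
        if ssw <= 0:
            return np.inf
        return ((ss_total - ssw) / (g - 1)) / (ssw / (n - g))

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)


def scan_cags(
    rho: pd.DataFrame,
    n_range,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int | None = 0,
    mode: str = "half",
) -> tuple[CagAssignment, pd.DataFrame]:
    """Smallest CAG count whose grouping passes PERMANOVA at ``alpha``.

    For each candidate n_cags the taxa are Ward-clustered and PERMANOVA is
    run on the (1 - rho)/2 dissimilarity grouped by CAG label (singleton
    CAGs are excluded from the test). Returns the selected assignment and a
    report of (n_cags, pseudo_F, p) per candidate.
    """
    report = []
    selected = None
    diss_all = correlation_dissimilarity(
        rho.fillna(0.0), mode=mode
    )
    for n_cags in n_range:
        assign = cluster_cags(rho, n_cags, mode=mode)
        sizes = assign.labels.value_counts()
        keep = assign.labels[assign.labels.map(sizes) >= 2]
        if keep.nunique() < 2:
            report.append((n_cags, np.nan, np.nan))
            continue
        ids = keep.index.tolist()
        sub = DistanceMatrix(ids, diss_all.loc[ids, ids].to_numpy())
        f, p = permanova(sub, keep.to_numpy(), n_perm=n_perm, seed=seed)
        assign.permanova_pseudo_F = f
        assign.permanova_p = p
        report.append((n_cags, f, p))
        if selected is None and p < alpha:
            selected = assign
    report_df = pd.DataFrame(report, columns=["n_cags", "pseudo_F", "p"])
    if selected is None:
        warnings.warn(f"no candidate n_cags reached PERMANOVA p < {alpha}")
    return selected, report_df


def cag_abundance(table: OtuTable, assignment: CagAssignment) -> pd.DataFrame:
    """Per-sample CAG abundance: sum of member-taxon relative abundances."""
    if table.kind != "relative":
        raise ValueError("cag_abundance expects a relative-abundance table")
    missing = set(table.taxon_ids) - set(assignment.labels.index)
    if missing:
        raise ValueError(f"assignment does not cover taxa: {sorted(missing)[:10]}")
    labels = assignment.labels.loc[table.taxon_ids]
    out = table.data.T.groupby(labels.to_numpy()).sum().T
    out.columns = [f"CAG{c}" for c in out.columns]
    out.index.name = "sample_id"
    return out


def cag_phenotype_correlation(
    cag_table: pd.DataFrame, adj_p: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of each CAG's abundance with the phenotype.

    Returns per-CAG (rho, p, p_adj) with Benjamini–Hochberg adjustment
    across CAGs; constant CAGs get NaN and are excluded from the family.
    """
    common = cag_table.index.intersection(adj_p.index)
    if len(common) < 5:
        raise ValueError("need at least 5 overlapping samples")
    y = adj_p.loc[common].to_numpy(dtype=float)
    rows = []
    for cag in cag_table.columns:
        x = cag_table.loc[common, cag].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((cag, np.nan, np.nan))
            continue
        r, p = stats.spearmanr(x, y)
        rows.append((cag, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["cag", "rho", "p"]).set_index("cag")
    defined = out["p"].notna()
    out["p_adj"] = np.nan
    if defined.any():
        out.loc[defined, "p_adj"] = bh_adjust(out.loc[defined, "p"].to_numpy())
    return out
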
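"""Two-part association of microbial abundance with a continuous phenotype.

Relative abundances of gut microbes are zero-inflated: a taxon is absent
from many samples and heavy-tailed where present. The two-part model tests
each taxon twice against the covariate-adjusted phenotype ``adj_p``:

* **binary part** — OLS of ``adj_p`` on detection (0/1); the slope equals
  the detected-minus-undetected mean difference, tested with a t statistic;
* **quantitative part** — OLS of ``adj_p`` on the (log10-transformed,
  z-scored) abundance among detected samples only;
* **meta part** — unweighted (Stouffer) Z combination of the two parts,
  Z = sum(z_i)/sqrt(k). By default z_i = sign(beta_i) * Phi^-1(1 - P_i/2),
  the signed two-sided conversion, so concordant effects reinforce;
  ``signed=False`` gives the literal sign-blind z_i = Phi^-1(P_i).

The final p-value is the minimum over defined parts. Taking a minimum of
dependent tests is anti-conservative, so significance is calibrated by
permuting ``adj_p`` across samples and estimating a permutation FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import OtuTable

__all__ = [
    "BinaryFit",
    "QuantitativeFit",
    "MetaResult",
    "binary_association",
    "quantitative_association",
    "meta_combine",
    "two_part_scan",
    "permutation_fdr",
    "shannon_index",
    "group_compare",
    "bh_adjust",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass
class BinaryFit:
    beta1: float
    p_binary: float
    n_detected: int
    n_undetected: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_binary)


@dataclass
class QuantitativeFit:
    beta2: float
    p_quant: float
    n_used: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_quant)


@dataclass
class MetaResult:
    z_scores: tuple[float, ...]
    k: int
    Z: float
    p_meta: float


def _slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-OLS slope and its two-sided t-test p (closed form)."""
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0 or n < 3:
        return np.nan, np.nan
    slope = float(xc @ y) / sxx
    resid = y - y.mean() - slope * xc
    sse = float(resid @ resid)
    df = n - 2
    if sse <= 0.0:
        return slope, 0.0
    se = np.sqrt(sse / df / sxx)
    t = slope / se
    return slope, float(2.0 * stats.t.sf(abs(t), df))


def binary_association(adj_p: np.ndarray, presence: np.ndarray) -> BinaryFit:
    """Detection effect: mean(adj_p | detected) - mean(adj_p | undetected).

    Undefined (NaN fields) when either class has fewer than 2 samples.
    """
    adj_p = np.asarray(adj_p, dtype=float)
    b = np.asarray(presence).astype(float)
    n1 = int(b.sum())
    n0 = len(b) - n1
    if n1 < 2 or n0 < 2:
        return BinaryFit(np.nan, np.nan, n1, n0)
    slope, p = _slope_test(b, adj_p)
    return BinaryFit(slope, p, n1, n0)


def quantitative_association(
    adj_p: np.ndarray,
    abundance: np.ndarray,
    transform: str = "log10",
) -> QuantitativeFit:
    """Abundance effect among detected samples.

    ``abundance`` is relative abundance; zeros mark undetected samples and
    are excluded. The detected values are transformed (``log10`` default,
    ``rank`` or ``identity`` available) then z-scored, so ``beta2`` is in
    phenotype units per standard deviation of transformed abundance.
    Undefined when fewer than 3 samples are detected or the transformed
    abundance is constant.
    """
    adj_p = np.asarray(adj_p, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    det = abundance > 0
    n_used = int(det.sum())
    if n_used < 3:
        return QuantitativeFit(np.nan, np.nan, n_used)
    x = _transform(abundance[det], transform)
    sd = x.std(ddof=1)
    if sd == 0.0:
        return QuantitativeFit(np.nan, np.nan, n_used)
    x = (x - x.mean()) / sd
    slope, p = _slope_test(x, adj_p[det])
    return QuantitativeFit(slope, p, n_used)


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10":
        return np.log10(x)
    if transform == "rank":
        return stats.rankdata(x)
    if transform == "identity":
        return x.astype(float)
    raise ValueError(f"unknown transform {transform!r}")


def meta_combine(
    p_values, directions, signed: bool = True
) -> MetaResult:
    """Unweighted-Z combination of the part p-values.

    signed (default): z_i = sign(direction_i) * Phi^-1(1 - P_i/2) and
    p_meta is the two-sided tail of Z — concordant directions reinforce,
    discordant ones cancel. ``signed=False`` uses the literal sign-blind
    z_i = Phi^-1(P_i) (audit mode). p-values at exactly 0 or 1 are clamped.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(directions, dtype=float)
    if len(p) < 1:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0/1 clamped for the normal quantile")
        p = np.clip(p, _P_FLOOR, _P_CEIL)
    if signed:
        z = np.sign(d) * stats.norm.isf(p / 2.0)
    else:
        z = stats.norm.ppf(p)
    k = len(p)
    Z = float(z.sum() / np.sqrt(k))
    p_meta = float(2.0 * stats.norm.sf(abs(Z)))
    return MetaResult(tuple(float(v) for v in z), k, Z, p_meta)


# ---------------------------------------------------------------------------
# vectorized scan core — one pass over all taxa, reused by the permutations

def _prepare_scan(
    rel: np.ndarray, transform: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute per-taxon design quantities that do not depend on adj_p.

    Returns (presence bool n x D, X n x D with z-scored transformed
    abundance on detected entries and 0 elsewhere, sxx length-D with the
    per-taxon sum of squares of X; NaN where the quantitative part is
    undefined).
    """
    n, d = rel.shape
    presence = rel > 0
    X = np.zeros((n, d))
    sxx = np.full(d, np.nan)
    for j in range(d):
        det = presence[:, j]
        nd = int(det.sum())
        if nd < 3:
            continue
        x = _transform(rel[det, j], transform)
        sd = x.std(ddof=1)
        if sd == 0.0:
            continue
        x = (x - x.mean()) / sd
        X[det, j] = x
        sxx[j] = float(x @ x)
    return presence, X, sxx


def _scan_core(
    y: np.ndarray,
    presence: np.ndarray,
    X: np.ndarray,
    sxx: np.ndarray,
    signed: bool = True,
) -> dict[str, np.ndarray]:
    """All three parts for every taxon, closed-form and fully vectorized."""
    n, d = presence.shape
    n1 = presence.sum(axis=0)
    n0 = n - n1
    ybar = y.mean()
    syy = float(((y - ybar) ** 2).sum())

    # binary part: OLS on the 0/1 indicator
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = presence.T @ y
        m1 = s1 / n1
        m0 = (y.sum() - s1) / n0
        beta1 = m1 - m0
        sxx_b = n1 * n0 / n
        sse_b = np.maximum(syy - beta1**2 * sxx_b, 0.0)
        se_b = np.sqrt(sse_b / (n - 2) / sxx_b)
        t_b = beta1 / se_b
    p_binary = 2.0 * stats.t.sf(np.abs(t_b), n - 2)
    p_binary[sse_b == 0.0] = 0.0
    undef_b = (n1 < 2) | (n0 < 2)
    beta1[undef_b] = np.nan
    p_binary[undef_b] = np.nan

    # quantitative part: OLS on z-scored transformed abundance, detected only
    ndet = n1.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ysum_det = presence.T @ y
        ymean_det = ysum_det / ndet
        syy_det = presence.T @ (y**2) - ndet * ymean_det**2
        sxy = X.T @ y  # X columns have zero mean over detected entries
        beta2 = sxy / sxx
        sse_q = np.maximum(syy_det - beta2**2 * sxx, 0.0)
        df_q = ndet - 2
        se_q = np.sqrt(sse_q / df_q / sxx)
        t_q = beta2 / se_q
    p_quant = np.full(d, np.nan)
    ok = np.isfinite(sxx)
    p_quant[ok] = 2.0 * stats.t.sf(np.abs(t_q[ok]), df_q[ok])
    p_quant[ok & (sse_q == 0.0)] = 0.0
    beta2[~ok] = np.nan

    # meta part: defined only when both parts are
    both = ~undef_b & ok
    pb = np.clip(p_binary, _P_FLOOR, _P_CEIL)
    pq = np.clip(p_quant, _P_FLOOR, _P_CEIL)
    with np.errstate(invalid="ignore"):
        if signed:
            z_b = np.sign(beta1) * stats.norm.isf(pb / 2.0)
            z_q = np.sign(beta2) * stats.norm.isf(pq / 2.0)
        else:
            z_b = stats.norm.ppf(pb)
            z_q = stats.norm.ppf(pq)
    Z = np.full(d, np.nan)
    Z[both] = (z_b[both] + z_q[both]) / np.sqrt(2.0)
    p_meta = np.full(d, np.nan)
    p_meta[both] = 2.0 * stats.norm.sf(np.abs(Z[both]))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_final = np.nanmin(np.column_stack([p_binary, p_quant, p_meta]), axis=1)

    # direction: sign of the stronger (smaller-p) part's effect
    use_binary = np.where(
        np.isnan(p_quant), True, np.where(np.isnan(p_binary), False, p_binary <= p_quant)
    )
    direction = np.sign(np.where(use_binary, beta1, beta2))

    return {
        "beta1": beta1,
        "p_binary": p_binary,
        "n_detected": n1,
        "n_undetected": n0,
        "beta2": beta2,
        "p_quant": p_quant,
        "Z": Z,
        "p_meta": p_meta,
        "p_final": p_final,
        "direction": direction,
    }


def two_part_scan(
    table: OtuTable,
    metadata: pd.DataFrame,
    transform: str = "log10",
    signed: bool = True,
) -> pd.DataFrame:
    """Run the two-part test for every taxon.

    ``table`` is a relative-abundance table (apply the inclusion filter
    first); ``metadata`` must carry the sex/batch-adjusted phenotype in an
    ``adj_p`` column, indexed by sample id. Returns one row per taxon with
    columns beta1, p_binary, n_detected, n_undetected, beta2, p_quant, Z,
    p_meta, p_final, direction. Taxa for which every part is undefined are
    dropped with a warning.
    """
    if table.kind != "relative":
        raise ValueError("two_part_scan expects a relative-abundance table")
    if "adj_p" not in metadata.columns:
        raise ValueError("metadata lacks an 'adj_p' column; run adjust_phenotype")
    missing = set(table.sample_ids) ^ set(metadata.index)
    if missing:
        raise ValueError(f"sample-id mismatch between table and metadata: {sorted(missing)[:10]}")
    y = metadata.loc[table.sample_ids, "adj_p"].to_numpy(dtype=float)
    presence, X, sxx = _prepare_scan(table.values, transform)
    res = _scan_core(y, presence, X, sxx, signed=signed)
    out = pd.DataFrame(res, index=pd.Index(table.taxon_ids, name="taxon_id"))
    all_undef = out["p_final"].isna()
    if all_undef.any():
        warnings.warn(
            f"{int(all_undef.sum())} taxa with every part undefined were dropped"
        )
        out = out.loc[~all_undef]
    return out


def permutation_fdr(
    assoc: pd.DataFrame,
    table: OtuTable,
    metadata: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    transform: str = "log10",
    signed: bool = True,
) -> pd.DataFrame:
    """Permutation-calibrated q-values for the min-P statistic.

    ``adj_p`` is shuffled across samples ``B`` times and the full scan is
    recomputed each time. For a threshold t, the estimated FDR is

        FDR(t) = mean_b #{permuted p_final <= t} / max(1, #{observed <= t})

    and ``q_perm`` for a taxon is the minimum FDR over thresholds at or
    above its own p_final (capped at 1, monotone in p_final). Requires
    B >= 100; use B = 1000 for production calls.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a usable FDR estimate")
    rng = np.random.default_rng(seed)
    y = metadata.loc[table.sample_ids, "adj_p"].to_numpy(dtype=float)
    presence, X, sxx = _prepare_scan(table.values, transform)

    perm_p: list[np.ndarray] = []
    for _ in range(B):
        yp = rng.permutation(y)
        pf = _scan_core(yp, presence, X, sxx, signed=signed)["p_final"]
        perm_p.append(pf[np.isfinite(pf)])
    pooled = np.sort(np.concatenate(perm_p))

    obs = assoc["p_final"].to_numpy(dtype=float)
    order = np.argsort(obs, kind="stable")
    obs_sorted = obs[order]
    n_le_perm = np.searchsorted(pooled, obs_sorted, side="right")
    ranks = np.arange(1, len(obs_sorted) + 1)  # observed count <= t at t = each obs p
    fdr = (n_le_perm / B) / ranks
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    out = assoc.copy()
    out["q_perm"] = q
    return out


def shannon_index(abundance) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) after normalization."""
    x = np.asarray(abundance, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def group_compare(values, groups) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between the two labels in ``groups``.

    Exact p for small untied samples, normal approximation with tie
    correction otherwise. Returns (U statistic, p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {list(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment across a family of tests."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
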
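"""Differential allele-frequency testing between two DNA pools.

Each biallelic site yields a 2x2 table of post-filter read counts

    [[ref_low, alt_low],
     [ref_high, alt_high]]

which is tested with a two-tailed Fisher's exact test; multiple testing is
controlled with the Benjamini-Hochberg step-up procedure across all tested
sites. Helpers produce ranked top lists with a minimum genomic spacing and
summaries of the distribution of frequency differentials.

The two-sided p-value follows the point-probability rule: with the margins
fixed, p is the sum of hypergeometric point probabilities over all tables
whose point probability does not exceed that of the observed table. Tables
are counted as ties when their point probability is within a relative 1e-12
of the observed one. Probabilities are computed from a log-factorial table,
so large read depths cannot overflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kurtosis, norm, skew

from .errors import ArgumentError

__all__ = [
    "fisher_exact_two_tailed",
    "fisher_exact_vector",
    "bh_adjust",
    "compare_pools",
    "top_k_spaced",
    "differential_distribution",
]

#: relative tolerance when deciding whether two point probabilities tie
TIE_RTOL = 1e-12

_LOGFACT_CACHE = np.array([])


def _logfact(n: int) -> np.ndarray:
    """Log-factorial lookup table covering 0..n (grown lazily, cached)."""
    global _LOGFACT_CACHE
    if _LOGFACT_CACHE.size <= n:
        _LOGFACT_CACHE = gammaln(
            np.arange(max(n + 1, 1024) + 1, dtype=float) + 1.0)
    return _LOGFACT_CACHE


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher's exact p-value for one 2x2 count table.

    Parameters
    ----------
    table
        ``[[ref_low, alt_low], [ref_high, alt_high]]`` of non-negative ints.

    Returns
    -------
    float
        p in (0, 1].
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ArgumentError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ArgumentError("contingency table entries must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ArgumentError("contingency table entries must be integers")
        t = np.round(t).astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if a + b + c + d == 0:
        raise ArgumentError("at least one margin must be positive")
    p = fisher_exact_vector(
        np.array([a]), np.array([b]), np.array([c]), np.array([d])
    )[0]
    return float(p)


def fisher_exact_vector(ref_low, alt_low, ref_high, alt_high,
                        chunk_size: int = 32768) -> np.ndarray:
    """Vectorised two-tailed Fisher's exact test over many 2x2 tables.

    All four arguments are equal-length integer arrays; table *i* is
    ``[[ref_low[i], alt_low[i]], [ref_high[i], alt_high[i]]]``. Work is
    chunked so memory stays bounded at roughly
    ``chunk_size * max_support`` doubles.
    """
    a = np.asarray(ref_low, dtype=np.int64)
    b = np.asarray(alt_low, dtype=np.int64)
    c = np.asarray(ref_high, dtype=np.int64)
    d = np.asarray(alt_high, dtype=np.int64)
    if not (a.shape == b.shape == c.shape == d.shape):
        raise ArgumentError("count arrays must have identical shapes")
    if min(a.min(initial=0), b.min(initial=0), c.min(initial=0),
           d.min(initial=0)) < 0:
        raise ArgumentError("contingency table entries must be non-negative")
    n = a.size
    out = np.empty(n, dtype=float)
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        out[lo:hi] = _fisher_chunk(a[lo:hi], b[lo:hi], c[lo:hi], d[lo:hi])
    return out

def _fisher_chunk(a, b, c, d):
    r1 = a + b          # row margins
    r2 = c + d
    c1 = a + c          # column margin (reference allele)
    ntot = r1 + r2
    lf = _logfact(int(ntot.max(initial=0)))

    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(r1, c1)
    width = int((hi - lo).max(initial=0)) + 1
    k = lo[:, None] + np.arange(width)[None, :]          # candidate a-values
    valid = k <= hi[:, None]
    kc = np.where(valid, k, 0)

    # log P(X = k) for hypergeometric with margins (r1, r2, c1)
    logpmf = (
        lf[r1][:, None] - lf[kc] - lf[(r1[:, None] - kc)]
        + lf[r2][:, None] - lf[(c1[:, None] - kc)]
        - lf[(r2 - c1)[:, None] + kc]
        - (lf[ntot] - lf[c1] - lf[ntot - c1])[:, None]
    )
    pmf = np.where(valid, np.exp(logpmf), np.inf)
    p_obs = np.take_along_axis(pmf, (a - lo)[:, None], axis=1)
    p = np.where(pmf <= p_obs * (1.0 + TIE_RTOL), pmf, 0.0)
    total = p.sum(axis=1)
    # empty tables (all margins zero) are undefined; callers pre-validate,
    # but guard anyway
    total = np.where(ntot == 0, np.nan, np.minimum(total, 1.0))
    return total


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, ``q_(i) = min_{j>=i} p_(j) * m / j`` clipped to 1,
    returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ArgumentError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def compare_pools(calls: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Fisher/BH comparison of per-pool allele counts at called sites.

    Parameters
    ----------
    calls
        Variant-call table with columns ``chrom, pos, ref, alt, ref_low,
        alt_low, ref_high, alt_high, af_low, af_high, called`` (the output
        of :func:`pooldiver.calling.call_variants`).
    alpha
        Experiment-wise BH significance level (default 0.01).

    Returns
    -------
    DataFrame with one row per tested site: the locus columns plus
    ``af_low, af_high, differential (= af_high - af_low), p, q,
    significant``. Sites that are uncalled, or with zero depth in either
    pool (no 2x2 table exists), are excluded.
    """
    if not 0 < alpha < 1:
        raise ArgumentError("alpha must be in (0, 1)")
    cols = ["chrom", "pos", "ref", "alt", "af_low", "af_high"]
    if calls.empty:
        return pd.DataFrame(
            columns=cols + ["differential", "p", "q", "significant"])
    depth_low = calls["ref_low"] + calls["alt_low"]
    depth_high = calls["ref_high"] + calls["alt_high"]
    testable = calls["called"] & (depth_low > 0) & (depth_high > 0)
    sub = calls.loc[testable].reset_index(drop=True)
    out = sub[cols].copy()
    out["differential"] = sub["af_high"] - sub["af_low"]
    if len(sub):
        out["p"] = fisher_exact_vector(
            sub["ref_low"].to_numpy(), sub["alt_low"].to_numpy(),
            sub["ref_high"].to_numpy(), sub["alt_high"].to_numpy())
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p"] = np.array([], dtype=float)
        out["q"] = np.array([], dtype=float)
    out["significant"] = out["q"] < alpha
    return out


def top_k_spaced(results: pd.DataFrame, k: int = 20,
                 min_distance: int = 10_000_000,
                 category: str | None = None,
                 class_column: str = "feature_class") -> pd.DataFrame:
    """Top-k most significant sites, enforcing a minimum genomic spacing.

    Greedy by ascending p: a site is accepted iff it lies at least
    ``min_distance`` bases from every already-accepted site on the same
    chromosome; selection stops after ``k`` acceptances. When ``category``
    is given, only sites whose ``class_column`` equals it compete.
    """
    if k < 0:
        raise ArgumentError("k must be non-negative")
    df = results
    if category is not None:
        df = df[df[class_column] == category]
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort")
    accepted: list[int] = []
    taken: dict[str, list[int]] = {}
    for idx, row in df.iterrows():
        if len(accepted) >= k:
            break
        positions = taken.setdefault(str(row["chrom"]), [])
        if all(abs(int(row["pos"]) - p) >= min_distance for p in positions):
            accepted.append(idx)
            positions.append(int(row["pos"]))
    return df.loc[accepted]


def differential_distribution(results: pd.DataFrame, bins: int = 30) -> dict:
    """Summaries of the allele-frequency differential distribution.

    Returns histogram bin counts, sample skewness, excess kurtosis, and
    theoretical-vs-sample normal quantile pairs (Q-Q data). With fewer than
    two results or a zero-variance sample the moments are reported missing.
    """
    if len(results) < 2:
        raise ArgumentError("need at least two results to summarise")
    x = results["differential"].to_numpy(dtype=float)
    counts, edges = np.histogram(x, bins=bins)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    sd = x.std()
    if sd == 0:
        skewness, excess_kurt = float("nan"), float("nan")
        z = np.zeros_like(x)
    else:
        skewness = float(skew(x))
        excess_kurt = float(kurtosis(x, fisher=True))
        z = (x - x.mean()) / sd
    n = x.size
    theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "sample": np.sort(z)})
    return {
        "histogram": hist,
        "skewness": skewness,
        "excess_kurtosis": excess_kurt,
        "qq": qq,
    }
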
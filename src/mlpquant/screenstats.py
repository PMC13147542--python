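"""Hit calling and statistics for phenotype screens.

Thresholding (percentile, elbow, strong-adhesion cutoff), replicate-based
hit confirmation, permutation tests, multiple-testing corrections,
expression-phenotype correlation, and median-of-ratios count normalization.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HitConfig",
    "TestResult",
    "strong_adhesion_call",
    "percentile_threshold",
    "elbow_threshold",
    "confirm_hits",
    "permutation_t_test",
    "bonferroni",
    "bh_fdr",
    "median_ratio_size_factors",
    "correlate_phenotype",
]

#: Adhesion ratio above which a phenotype is called strong (post/pre > 0.2).
STRONG_ADHESION_CUTOFF = 0.2


@dataclass(frozen=True)
class HitConfig:
    """Thresholds for confirming screen hits from replicate measurements.

    A replicate is *valid* when both densities allow robust quantification
    (pre > ``pre_min`` and post > ``post_min``); a strain is a hit when it
    has at least ``min_repeats`` valid replicates and its ratio exceeds
    ``ratio_min``. With ``per_replicate=False`` (default) the mean ratio over
    valid replicates is compared against ``ratio_min``; with ``True`` every
    valid replicate must individually exceed it.
    """

    min_repeats: int = 5
    pre_min: float = 0.1
    post_min: float = 0.05
    ratio_min: float = 0.086
    per_replicate: bool = False

    def __post_init__(self) -> None:
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")
        if min(self.pre_min, self.post_min, self.ratio_min) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n_permutations: int
    alternative: str
    exhaustive: bool
    p_adjusted: float | None = None


def strong_adhesion_call(ratio: float) -> bool:
    """True when the adhesion ratio exceeds the strong-phenotype cutoff (0.2).

    The boundary is strict: a ratio of exactly 0.2 is not called strong.
    """
    if ratio < 0:
        raise ValueError("adhesion ratio must be >= 0")
    return ratio > STRONG_ADHESION_CUTOFF


def percentile_threshold(values, q: float = 95.0) -> float:
    """q-th percentile of finite values under linear interpolation.

    Used as the screen-positive cutoff: strains strictly above the returned
    value sit in the top (100-q) percent of the screen.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("percentile_threshold needs at least 2 finite values")
    return float(np.percentile(arr, q, method="linear"))


def elbow_threshold(values) -> float:
    """Elbow of the descending-sorted value curve.

    Sorts values in decreasing order and returns the value at the index of
    maximum perpendicular distance to the chord joining the first and last
    points of the sorted curve (kneedle-style knee detection).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError("elbow_threshold needs at least 3 values")
    y = np.sort(arr)[::-1]
    if np.isclose(y[0], y[-1]):
        warnings.warn("all values (nearly) equal; no elbow exists", stacklevel=2)
        return float(y[0])
    n = y.size
    x = np.arange(n, dtype=float)
    # perpendicular distance of each point to the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    if np.allclose(dist, dist[0]):
        warnings.warn("value curve is linear; returning midpoint", stacklevel=2)
        return float(y[n // 2])
    return float(y[int(np.argmax(dist))])


def confirm_hits(table: pd.DataFrame, config: HitConfig | None = None) -> pd.DataFrame:
    """Confirm screen hits from a replicate table.

    Parameters
    ----------
    table
        Long-format replicates with columns ``strain``, ``pre_density``,
        ``post_density``, ``ratio``.
    config
        Thresholds; defaults follow the confirmation screen (>= 5 valid
        repeats with pre > 0.1 and post > 0.05, mean ratio > 0.086).

    Returns
    -------
    One row per strain: ``n_valid``, ``mean_ratio`` (over valid replicates),
    ``hit``.
    """
    if config is None:
        config = HitConfig()
    required = {"strain", "pre_density", "post_density", "ratio"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("replicate table is empty")

    valid = (table["pre_density"] > config.pre_min) & (
        table["post_density"] > config.post_min
    )
    tab = table.assign(_valid=valid)
    grouped = tab.groupby("strain", sort=True)
    n_valid = grouped["_valid"].sum().astype(int)
    mean_ratio = (
        tab[tab["_valid"]].groupby("strain")["ratio"].mean().reindex(n_valid.index)
    )
    if config.per_replicate:
        ratio_ok = (
            tab[tab["_valid"]]
            .groupby("strain")["ratio"]
            .apply(lambda r: bool((r > config.ratio_min).all()))
            .reindex(n_valid.index, fill_value=False)
        )
    else:
        ratio_ok = mean_ratio > config.ratio_min
    out = pd.DataFrame(
        {
            "n_valid": n_valid,
            "mean_ratio": mean_ratio,
            "hit": (n_valid >= config.min_repeats) & ratio_ok.fillna(False),
        }
    )
    return out.reset_index()


def _perm_pvalue(observed: float, null: np.ndarray, alternative: str) -> float:
    # +1 convention: the observed labeling counts as one draw
    if alternative == "greater":
        extreme = np.sum(null >= observed)
    elif alternative == "less":
        extreme = np.sum(null <= observed)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float((1 + extreme) / (1 + null.size))


def permutation_t_test(
    x,
    y,
    n_perm: int = 10_000,
    alternative: str = "two-sided",
    seed: int | None = None,
) -> TestResult:
    """Permutation test on the difference of group means.

    The statistic is ``mean(x) - mean(y)``; the null is built by relabeling
    the pooled observations into groups of the original sizes. When the
    number of distinct splits C(n_x+n_y, n_x) is at most ``n_perm`` the null
    is enumerated exhaustively, otherwise ``n_perm`` random relabelings are
    sampled. p = (1 + #extreme) / (1 + #draws), so the smallest attainable
    p is 1/(n_perm+1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size

    n_splits = math.comb(n, nx)
    exhaustive = n_splits <= n_perm
    if exhaustive:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), nx)),
            dtype=np.intp,
        ).reshape(n_splits, nx)
        sx = pooled[idx].mean(axis=1)
        # mean(y) from the complement via the pooled total
        sy = (pooled.sum() - pooled[idx].sum(axis=1)) / (n - nx)
        null = sx - sy
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        chunk = max(1, min(n_perm, 50_000_000 // max(n, 1)))
        total = pooled.sum()
        for start in range(0, n_perm, chunk):
            k = min(chunk, n_perm - start)
            perms = rng.permuted(np.tile(pooled, (k, 1)), axis=1)
            sx = perms[:, :nx].mean(axis=1)
            sy = (total - perms[:, :nx].sum(axis=1)) / (n - nx)
            null[start : start + k] = sx - sy
    p = _perm_pvalue(observed, null, alternative)
    return TestResult(
        statistic=observed,
        p=p,
        n_permutations=int(null.size),
        alternative=alternative,
        exhaustive=exhaustive,
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    return np.minimum(1.0, p * p.size)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _check_pvalues(p: np.ndarray) -> None:
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")


def median_ratio_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples count matrix).

    For each gene with nonzero counts in every sample, the pseudo-reference
    is the geometric mean across samples; each sample's factor is the median
    over such genes of count / pseudo-reference. Dividing a sample's counts
    by its factor equalizes sequencing depth.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2:
        raise ValueError("counts must be a 2-D genes x samples matrix")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    usable = np.all(c > 0, axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    cu = c[usable]
    reference = np.exp(np.mean(np.log(cu), axis=1, keepdims=True))
    return np.median(cu / reference, axis=0)


def correlate_phenotype(
    expression: pd.DataFrame,
    phenotype: pd.Series,
    method: str = "spearman",
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Correlate each gene's expression with a per-strain phenotype.

    ``expression`` is genes x strains; ``phenotype`` is indexed by strain.
    Only shared strains are used (at least 3 required). Constant genes get a
    missing correlation and are excluded from the FDR. Returns per-gene
    ``r``, ``p``, ``q``, ``significant`` (q < ``fdr_level``).
    """
    shared = expression.columns.intersection(phenotype.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 strains shared with the phenotype")
    X = expression[shared].to_numpy(dtype=float)
    y = phenotype.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")

    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = math.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    constant = sx == 0
    r[constant] = np.nan
    r = np.clip(r, -1.0, 1.0)

    # two-sided p from the t transform of r (n-2 df), as in the classical test
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = np.finfo(float).tiny
    p[constant] = np.nan

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_fdr(np.clip(p[tested], np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "q": q,
            "significant": np.where(tested, q < fdr_level, False),
        },
        index=expression.index,
    )
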
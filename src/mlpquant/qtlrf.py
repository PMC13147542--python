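"""Random-forest QTL mapping with a permutation null.

Markers are collapsed into haplotype blocks (runs of adjacent markers whose
genotype columns are identical across all segregants), a "selection
frequency" importance is computed for each block — the fraction of
regression trees, across an ensemble of independent forests, that use the
block in at least one split — and significance comes from re-computing the
importance under phenotype permutations, with Bonferroni correction across
blocks. The forest considers many blocks jointly at every split, which lets
strong linked or epistatic structure compete within a single model rather
than marker-by-marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .varianteffects import GenotypeMatrix

__all__ = [
    "HaplotypeBlock",
    "ImportanceProfile",
    "collapse_blocks",
    "selection_frequency",
    "permutation_null",
    "qtl_pvalues",
    "min_permutations",
    "map_qtl",
]

_CODES = {"P1": 0.0, "P2": 1.0}


@dataclass(frozen=True)
class HaplotypeBlock:
    block_id: str
    chromosome: str
    members: tuple[str, ...]  # marker names, contiguous within the chromosome
    representative_pos: int


@dataclass(frozen=True)
class ImportanceProfile:
    selection_frequency: np.ndarray  # per block, in [0, 1]
    n_forests: int
    n_trees: int
    seed: int | None
    flagged_constant_phenotype: bool = False


def encode_genotypes(matrix: GenotypeMatrix) -> pd.DataFrame:
    """P1/P2 calls -> 0/1 floats, with residual missing calls filled.

    Calls still missing after flank-agreement imputation (chromosome ends,
    disagreeing flanks) are filled per strain with the nearest called
    genotype on the same chromosome — the linkage-faithful guess — falling
    back to the per-marker majority when a strain has no call on the
    chromosome at all.
    """
    num = matrix.data.astype(object).map(lambda v: _CODES.get(v, np.nan)).astype(float)
    for _, grp in matrix.markers.groupby("chromosome", sort=False):
        cols = list(grp.index)
        block = num[cols]
        if block.isna().any().any():
            num[cols] = block.ffill(axis=1).bfill(axis=1)
    for col in num.columns:
        if num[col].isna().any():
            called = num[col].dropna()
            majority = 1.0 if len(called) and called.mean() > 0.5 else 0.0
            num[col] = num[col].fillna(majority)
    return num


def collapse_blocks(
    matrix: GenotypeMatrix,
) -> tuple[list[HaplotypeBlock], pd.DataFrame]:
    """Merge adjacent markers with identical genotype columns into blocks.

    Best applied after :func:`~mlpquant.varianteffects.impute_flanked`;
    any residual missing calls are filled with the per-marker majority
    label before comparison. Returns the block descriptions and the reduced
    strains x blocks matrix (0 = P1, 1 = P2 of the representative marker).
    """
    num = encode_genotypes(matrix)
    runs: list[tuple[str, list[str], np.ndarray]] = []  # (chrom, members, column)
    for chrom, grp in matrix.markers.groupby("chromosome", sort=False):
        for marker in grp.index:
            col = num[marker].to_numpy()
            if runs and runs[-1][0] == chrom and np.array_equal(col, runs[-1][2]):
                runs[-1][1].append(marker)
            else:
                runs.append((str(chrom), [marker], col))
    blocks = []
    for i, (chrom, members, _) in enumerate(runs):
        pos = matrix.markers.loc[members, "pos"].to_numpy()
        blocks.append(
            HaplotypeBlock(
                block_id=f"b{i + 1}",
                chromosome=chrom,
                members=tuple(members),
                representative_pos=int(pos[len(pos) // 2]),
            )
        )
    frame = pd.DataFrame(
        {b.block_id: run[2] for b, run in zip(blocks, runs)},
        index=matrix.data.index,
    )
    return blocks, frame


def _stump_usage(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
    min_samples_leaf: int,
) -> np.ndarray:
    """Exact vectorized usage counts for greedy single-split (stump) trees.

    Each tree draws a bootstrap sample and splits on the binary block with
    the largest weighted variance reduction (equivalently the largest
    sum of squared group means weighted by group size), subject to the
    minimum leaf weight. Statistically identical to depth-1 regression
    trees considering every feature, but runs as a few matrix products.
    """
    n, b = X.shape
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_trees).astype(float)
    S = counts @ y
    W1 = counts @ X
    S1 = (counts * y) @ X
    W0 = n - W1
    S0 = S[:, None] - S1
    with np.errstate(divide="ignore", invalid="ignore"):
        score = S1**2 / W1 + S0**2 / W0
    valid = (W1 >= min_samples_leaf) & (W0 >= min_samples_leaf)
    score = np.where(valid, score, -np.inf)
    best = np.argmax(score, axis=1)
    usable = valid.any(axis=1)
    return np.bincount(best[usable], minlength=b)


def _tree_usage(forest: RandomForestRegressor, n_features: int) -> np.ndarray:
    """Count, per feature, the trees using it in >= 1 split."""
    used = np.zeros(n_features, dtype=np.int64)
    for est in forest.estimators_:
        feats = est.tree_.feature
        used[np.unique(feats[feats >= 0])] += 1
    return used


def selection_frequency(
    X,
    y,
    n_forests: int = 100,
    n_trees: int = 100,
    seed: int | None = None,
    max_features: int | float | str | None = 1.0,
    min_samples_leaf: int = 5,
    max_depth: int | None = 1,
) -> ImportanceProfile:
    """Per-block selection frequency over an ensemble of small forests.

    Trains ``n_forests`` independent regression forests of ``n_trees``
    bootstrap trees each and returns, per block, the fraction of all trees
    that split on it at least once. The default trees are greedy
    single-split stumps (all blocks considered, ``max_depth=1``): with few
    haplotype blocks the frequency then measures how stably a block gives
    the best split across bootstrap resamples, which stays discriminating
    where deep subsampled trees saturate (every block used somewhere in
    almost every deep tree once the block count is small). For dense marker
    panels with hundreds of blocks, deeper trees with feature subsampling
    (``max_depth=None``, ``max_features="sqrt"``) are the classic choice
    and are fully supported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be strains x blocks")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 strains")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    if n_forests < 1 or n_trees < 1:
        raise ValueError("n_forests and n_trees must be >= 1")
    flagged = bool(np.ptp(y) == 0)
    if flagged:
        warnings.warn(
            "constant phenotype: selection frequencies are meaningless",
            stacklevel=2,
        )
    if max_features is None or max_features == "sqrt":
        max_features = max(1, math.ceil(math.sqrt(X.shape[1])))
    rng = np.random.default_rng(seed)
    binary = bool(np.isin(X, (0.0, 1.0)).all())
    if max_depth == 1 and max_features == 1.0 and binary:
        # greedy stumps over binary blocks: exact closed-form path
        used = _stump_usage(X, y, n_forests * n_trees, rng, min_samples_leaf)
        return ImportanceProfile(
            selection_frequency=used / (n_forests * n_trees),
            n_forests=n_forests,
            n_trees=n_trees,
            seed=seed,
            flagged_constant_phenotype=flagged,
        )
    used = np.zeros(X.shape[1], dtype=np.int64)
    for _ in range(n_forests):
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            max_depth=max_depth,
            bootstrap=True,
            n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X, y)
        used += _tree_usage(forest, X.shape[1])
    return ImportanceProfile(
        selection_frequency=used / (n_forests * n_trees),
        n_forests=n_forests,
        n_trees=n_trees,
        seed=seed,
        flagged_constant_phenotype=flagged,
    )


def permutation_null(
    X,
    y,
    n_perm: int,
    n_forests: int = 1,
    n_trees: int = 100,
    seed: int | None = None,
    **forest_kwargs,
) -> np.ndarray:
    """Null selection frequencies from phenotype permutations.

    For each of ``n_perm`` permutations the phenotype is shuffled across
    strains and the selection frequency recomputed with ``n_forests`` x
    ``n_trees`` trees. Returns an (n_perm, n_blocks) array. The per-
    permutation ensemble defaults to a single 100-tree forest, which keeps
    large nulls affordable at the price of a somewhat wider (conservative)
    null than the observed ensemble.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, X.shape[1]))
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant phenotype stays constant
            profile = selection_frequency(
                X,
                y_perm,
                n_forests=n_forests,
                n_trees=n_trees,
                seed=int(rng.integers(2**31 - 1)),
                **forest_kwargs,
            )
        null[i] = profile.selection_frequency
    return null


def qtl_pvalues(
    observed: ImportanceProfile,
    null: np.ndarray,
    blocks: list[HaplotypeBlock] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-block permutation p-values with Bonferroni correction.

    p = (1 + #{null >= observed}) / (1 + n_perm) per block, against that
    block's own null draws; Bonferroni multiplies by the number of blocks.
    """
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[0] < 1:
        raise ValueError("null must be a non-empty (n_perm, n_blocks) array")
    freq = observed.selection_frequency
    if null.shape[1] != freq.size:
        raise ValueError("null and observed block counts differ")
    n_perm = null.shape[0]
    p = (1 + np.sum(null >= freq[None, :], axis=0)) / (1 + n_perm)
    p_bonf = np.minimum(1.0, p * freq.size)
    out = pd.DataFrame(
        {
            "importance": freq,
            "p": p,
            "p_bonferroni": p_bonf,
            "significant": p_bonf < alpha,
        }
    )
    if blocks is not None:
        out.insert(0, "block", [b.block_id for b in blocks])
        out.insert(1, "chromosome", [b.chromosome for b in blocks])
        out.insert(2, "pos", [b.representative_pos for b in blocks])
        out.insert(3, "n_markers", [len(b.members) for b in blocks])
    return out


def min_permutations(n_blocks: int, alpha: float) -> float:
    """Permutation count that must be exceeded for Bonferroni significance.

    The smallest attainable permutation p is 1/(n_perm+1); after Bonferroni
    correction across ``n_blocks`` blocks, genome-wide significance at level
    ``alpha`` therefore requires n_perm > n_blocks / alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    value = n_blocks / alpha
    snapped = round(value)
    return float(snapped) if math.isclose(value, snapped, rel_tol=1e-9) else value


def map_qtl(
    matrix: GenotypeMatrix,
    phenotype: pd.Series,
    n_forests: int = 100,
    n_trees: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    null_forests: int = 1,
) -> pd.DataFrame:
    """End-to-end mapping: collapse blocks, score, permute, correct.

    ``phenotype`` is indexed by strain and must cover every strain in the
    genotype matrix.
    """
    missing = set(matrix.data.index) - set(phenotype.index)
    if missing:
        raise ValueError(f"phenotype missing strains: {sorted(missing)[:5]}...")
    y = phenotype.loc[matrix.data.index].to_numpy(dtype=float)
    blocks, reduced = collapse_blocks(matrix)
    X = reduced.to_numpy(dtype=float)
    if n_perm <= min_permutations(len(blocks), alpha) - 1:
        warnings.warn(
            f"{n_perm} permutations cannot reach Bonferroni significance for "
            f"{len(blocks)} blocks at alpha={alpha} "
            f"(need > {min_permutations(len(blocks), alpha):.0f})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    observed = selection_frequency(
        X, y, n_forests=n_forests, n_trees=n_trees, seed=int(rng.integers(2**31 - 1))
    )
    null = permutation_null(
        X,
        y,
        n_perm=n_perm,
        n_forests=null_forests,
        n_trees=n_trees,
        seed=int(rng.integers(2**31 - 1)),
    )
    return qtl_pvalues(observed, null, blocks=blocks, alpha=alpha)


def manhattan_plot(results: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Save a Manhattan-style plot of -log10 block p-values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(len(results))
    ax.scatter(x, -np.log10(results["p"]), c="steelblue", s=18)
    n_blocks = len(results)
    ax.axhline(-math.log10(alpha / n_blocks), ls="-", c="k", lw=0.8)
    ax.set_xlabel("haplotype block")
    ax.set_ylabel("-log10 p")
    if "chromosome" in results:
        ticks = {
            chrom: grp.index.to_numpy().mean()
            for chrom, grp in results.groupby("chromosome", sort=False)
        }
        ax.set_xticks(list(ticks.values()))
        ax.set_xticklabels(list(ticks.keys()))
        ax.set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
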
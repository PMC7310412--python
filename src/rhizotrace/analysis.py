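"""Genotype-level trait analysis: CV, z-scoring, complete-linkage clustering.

The trait matrix is a pandas DataFrame with genotypes as rows, traits as
columns and ``NaN`` for missing cells (missing is flagged, never encoded as
zero).  Columns are standardised to zero mean and unit variance (column
z-scores), genotypes are compared by Euclidean distance over mutually
observed columns (rescaled by sqrt(p / p_shared) so sparsities stay
comparable), and the dendrogram is built by complete-linkage agglomeration
with deterministic lexicographic tie-breaking.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "coefficient_of_variation",
    "zscore_standardize",
    "pairwise_distances",
    "complete_linkage",
    "cut_tree",
    "trait_correlations",
    "genotype_means",
    "plot_trait_heatmap",
]


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: ``100 * sample sd / mean`` (sd with n-1 denominator).

    Requires at least two values; returns ``nan`` (with a warning) when the
    mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        warnings.warn("coefficient of variation undefined for zero mean")
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores: ``(x - mean) / sd`` over non-missing entries.

    Missing cells stay missing.  Columns with fewer than 2 observations or
    zero variance carry no information for clustering and are dropped with a
    warning.
    """
    out = {}
    for col in matrix.columns:
        x = pd.to_numeric(matrix[col], errors="coerce")
        n = x.notna().sum()
        sd = x.std(ddof=1)
        if n < 2 or not np.isfinite(sd) or sd == 0:
            warnings.warn(f"column {col!r} dropped (constant or <2 observations)")
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=matrix.index)


def pairwise_distances(matrix: pd.DataFrame, rescale_missing: bool = True) -> pd.DataFrame:
    """Euclidean distances between rows over mutually non-missing columns.

    With ``rescale_missing`` the squared distance over the shared columns is
    scaled by ``p / p_shared`` (p = total columns), i.e. the available
    coordinates stand in for the missing ones; with ``False`` only complete
    columns are used for every pair (complete-case).  A pair with no shared
    column is an error.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if rescale_missing:
        cols_ok = np.ones(p, dtype=bool)
    else:
        cols_ok = ~np.isnan(X).any(axis=0)
        if not cols_ok.any():
            raise ValueError("no complete columns for complete-case distances")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = cols_ok & ~np.isnan(X[i]) & ~np.isnan(X[j])
            p_shared = int(shared.sum())
            if p_shared == 0:
                raise ValueError(
                    f"rows {matrix.index[i]!r} and {matrix.index[j]!r} share no observed trait"
                )
            d2 = float(((X[i, shared] - X[j, shared]) ** 2).sum())
            if rescale_missing:
                d2 *= p / p_shared
            D[i, j] = D[j, i] = np.sqrt(d2)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Agglomeration record: ``merges[i] = (a, b, height, size)``.

    Cluster ids follow the scipy convention: leaves are 0..n-1, the cluster
    formed by merge ``i`` has id ``n + i``.  Complete linkage guarantees
    non-decreasing heights.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage_matrix(self) -> np.ndarray:
        """Scipy-compatible (n-1, 4) linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the dendrogram (for heatmap display)."""
        n = self.n_leaves

        def expand(cid: int) -> list[int]:
            if cid < n:
                return [cid]
            a, b, _h, _s = self.merges[cid - n]
            return expand(a) + expand(b)

        return expand(n + len(self.merges) - 1) if self.merges else list(range(n))


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Complete-linkage (farthest-neighbour) agglomerative clustering.

    At every step the pair of active clusters with the smallest maximum
    pairwise member distance is merged; ties are broken by the smallest
    (i, j) cluster-id pair, making the result bit-stable across platforms.
    """
    D0 = dist.to_numpy(dtype=float)
    n = D0.shape[0]
    if D0.shape[0] != D0.shape[1] or n < 2:
        raise ValueError("need a square distance matrix over >= 2 items")
    if not np.allclose(D0, D0.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    # inter-cluster distances, grown as clusters are created
    size = {i: 1 for i in range(n)}
    D: dict[tuple[int, int], float] = {
        (i, j): float(D0[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda ij: (D[ij], ij),
        )
        h = D[best]
        i, j = best
        for k in active - {i, j}:
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            D[(k, next_id)] = max(dik, djk)
        size[next_id] = size[i] + size[j]
        merges.append((i, j, h, size[next_id]))
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return Dendrogram(merges=merges, labels=list(dist.index))


def cut_tree(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels (1..k) from the first ``n - k`` merges.

    Labels are assigned in order of first appearance along the leaf list so
    the output is deterministic.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h, _s) in enumerate(dendrogram.merges[: n - k]):
        new_id = n + step
        parent[find(a)] = new_id
        parent[find(b)] = new_id
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, root in enumerate(roots):
        if root not in relabel:
            relabel[root] = len(relabel) + 1
        out[i] = relabel[root]
    return out


def trait_correlations(matrix: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between traits.

    Cells with fewer than ``min_pairs`` paired observations are NaN.
    """
    return matrix.apply(pd.to_numeric, errors="coerce").corr(method="pearson", min_periods=min_pairs)


def genotype_means(traits: pd.DataFrame, genotype_col: str = "genotype") -> pd.DataFrame:
    """Mean trait value per genotype from a tidy per-plant trait table."""
    if genotype_col not in traits.columns:
        raise KeyError(f"column {genotype_col!r} not in trait table")
    numeric = traits.select_dtypes(include=[np.number]).columns
    return traits.groupby(genotype_col)[list(numeric)].mean()


def plot_trait_heatmap(
    matrix: pd.DataFrame,
    path: str,
    row_dendrogram: Optional[Dendrogram] = None,
    col_dendrogram: Optional[Dendrogram] = None,
) -> None:
    """Render a z-score heatmap (red-yellow) ordered by the dendrograms.

    Presentation only; all computation happens in the functions above.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.copy()
    if row_dendrogram is not None:
        data = data.iloc[row_dendrogram.leaf_order()]
    if col_dendrogram is not None:
        data = data.iloc[:, col_dendrogram.leaf_order()]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * data.shape[1]), max(4, 0.12 * data.shape[0])))
    masked = np.ma.masked_invalid(data.to_numpy(dtype=float))
    cmap = plt.get_cmap("autumn").copy()
    cmap.set_bad("white")
    im = ax.pcolormesh(masked, cmap=cmap)
    ax.set_xticks(np.arange(data.shape[1]) + 0.5)
    ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(data.shape[0]) + 0.5)
    ax.set_yticklabels(data.index, fontsize=5)
    ax.invert_yaxis()
    fig.colorbar(im, ax=ax, label="column z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
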
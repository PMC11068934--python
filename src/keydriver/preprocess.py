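"""Expression-matrix filtering, log transform, marker splitting and discretization.

Expression matrices are pandas DataFrames in the field's genes x samples
orientation (rows = gene identifiers, columns = sample identifiers,
TPM-scale non-negative values).  The module-level functions operate on that
orientation.  The sklearn-style transformers (:class:`LowExpressionFilter`,
:class:`LogTransformer`, :class:`KMeansDiscretizer`) follow the sklearn
samples x features convention, so they compose with pipelines; they simply
transpose at the boundary.

Discretization maps every gene independently onto the ordered three-level
alphabet ``low < medium < high`` via one-dimensional k-means (k = 3) with
clusters relabelled by ascending centroid, so level assignment is monotone
in the underlying continuous value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

__all__ = [
    "LEVELS",
    "filter_low_expression",
    "log_transform",
    "split_by_marker",
    "discretize_kmeans",
    "read_expression",
    "write_expression",
    "LowExpressionFilter",
    "LogTransformer",
    "KMeansDiscretizer",
]

#: the ordered discretization alphabet
LEVELS = ("low", "medium", "high")


def _check_frame(mat: pd.DataFrame) -> None:
    if mat.empty:
        raise ValueError("expression matrix is empty")
    if not mat.index.is_unique:
        raise ValueError("gene identifiers are not unique")
    if not mat.columns.is_unique:
        raise ValueError("sample identifiers are not unique")


def _check_expression(mat: pd.DataFrame) -> None:
    _check_frame(mat)
    if (mat.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")


def filter_low_expression(
    mat: pd.DataFrame, threshold: float = 0.1, fraction: float = 0.8
) -> pd.DataFrame:
    """Drop genes below ``threshold`` TPM in more than ``fraction`` of samples.

    A gene is removed iff the proportion of samples with value < ``threshold``
    is strictly greater than ``fraction`` (so a gene low in exactly 80% of
    samples is retained at the defaults).  Idempotent; samples unchanged.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    _check_expression(mat)
    low_fraction = (mat < threshold).mean(axis=1)
    return mat.loc[low_fraction <= fraction]


def log_transform(mat: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Natural-log transform ``x -> ln(x + offset)`` (monotone, defined at 0)."""
    _check_expression(mat)
    return np.log(mat + offset)


def split_by_marker(
    mat: pd.DataFrame, marker: str, threshold: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition samples into marker-high and marker-low groups.

    Used to confirm sex assignments from a sex-specific transcript (e.g. the
    X-inactivation marker XIST): samples with marker expression above the
    threshold form the first group.  When ``threshold`` is None it defaults
    to the midpoint of a 2-means split of the marker's values.
    """
    if marker not in mat.index:
        raise KeyError(f"marker gene {marker!r} not in matrix")
    values = mat.loc[marker]
    if threshold is None:
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
            np.sort(values.to_numpy())[:, None]
        )
        threshold = float(np.mean(np.sort(km.cluster_centers_.ravel())))
    high = mat.loc[:, values > threshold]
    low = mat.loc[:, values <= threshold]
    if high.shape[1] == 0 or low.shape[1] == 0:
        warnings.warn(
            f"marker split on {marker!r} at {threshold} left one group empty",
            stacklevel=2,
        )
    return high, low


def _discretize_gene(values: np.ndarray, seed: int) -> np.ndarray:
    """Three-level k-means for one gene; returns integer levels 0/1/2."""
    uniq = np.unique(values)
    if uniq.size == 1:
        return np.ones(values.size, dtype=np.int8)  # constant -> medium
    if uniq.size == 2:
        return np.where(values == uniq[0], 0, 2).astype(np.int8)  # low / high
    # Fit on sorted values so the result is invariant to sample ordering,
    # then assign by the induced interval boundaries.
    order = np.sort(values)
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(order[:, None])
    centroids = km.cluster_centers_.ravel()
    rank = np.argsort(np.argsort(centroids, kind="stable"), kind="stable")
    sorted_levels = rank[km.labels_]
    if len(np.unique(sorted_levels)) < 3:  # collapsed cluster: tertile fallback
        parts = np.array_split(order, 3)
        cuts = [(parts[0][-1] + parts[1][0]) / 2.0, (parts[1][-1] + parts[2][0]) / 2.0]
        return np.searchsorted(np.asarray(cuts), values, side="right").astype(np.int8)
    # 1-D k-means clusters are contiguous intervals: cut points between levels
    cuts = []
    for lvl in (0, 1):
        below = order[sorted_levels == lvl]
        above = order[sorted_levels > lvl]
        cuts.append((below.max() + above.min()) / 2.0)
    return np.searchsorted(np.asarray(cuts), values, side="right").astype(np.int8)


def discretize_kmeans(
    mat: pd.DataFrame, k: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Discretize each gene into ``low``/``medium``/``high`` via 1-D k-means.

    Per-gene clustering (level boundaries are gene-specific); clusters are
    relabelled by ascending centroid so the assignment is monotone in the
    continuous value.  Degenerate genes: constant -> all ``medium``; exactly
    two distinct values -> ``low``/``high`` (with a warning).

    Returns a genes x samples DataFrame over the :data:`LEVELS` alphabet.
    """
    if k != 3:
        raise ValueError(f"only k=3 (low/medium/high) is supported, got k={k}")
    _check_frame(mat)  # discretization also runs on (possibly negative) log scale
    values = mat.to_numpy(dtype=float)
    out = np.empty(values.shape, dtype=np.int8)
    n_degenerate = 0
    for i in range(values.shape[0]):
        if np.unique(values[i]).size < 3:
            n_degenerate += 1
        out[i] = _discretize_gene(values[i], seed)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} gene(s) with < 3 distinct values discretized "
            "by the degenerate rule",
            stacklevel=2,
        )
    labels = np.asarray(LEVELS, dtype=object)
    return pd.DataFrame(labels[out], index=mat.index, columns=mat.columns)


def encode_levels(levels: pd.DataFrame) -> pd.DataFrame:
    """Map a low/medium/high DataFrame to integer codes 0/1/2."""
    mapping = {lvl: np.int8(i) for i, lvl in enumerate(LEVELS)}
    coded = np.vectorize(mapping.__getitem__, otypes=[np.int8])(levels.to_numpy())
    return pd.DataFrame(coded, index=levels.index, columns=levels.columns)


# -- tab-delimited matrix I/O ---------------------------------------------


def read_expression(path) -> pd.DataFrame:
    """Read a tab-delimited genes x samples matrix (first column = gene ids)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    return mat


def write_expression(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="gene")


# -- sklearn transformers (samples x genes orientation) --------------------


class LowExpressionFilter(TransformerMixin, BaseEstimator):
    """Remove lowly expressed genes (features) from a samples x genes frame.

    Fitted attributes
    -----------------
    keep_genes_ : pandas.Index
        Genes retained by the threshold/fraction rule.
    """

    def __init__(self, threshold: float = 0.1, fraction: float = 0.8):
        self.threshold = threshold
        self.fraction = fraction

    def fit(self, X: pd.DataFrame, y=None):
        kept = filter_low_expression(X.T, self.threshold, self.fraction)
        self.keep_genes_ = kept.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.keep_genes_]


class LogTransformer(TransformerMixin, BaseEstimator):
    """Natural-log ``ln(x + offset)`` transform; stateless."""

    def __init__(self, offset: float = 1.0):
        self.offset = offset

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if (np.asarray(X) < 0).any():
            raise ValueError("expression values must be non-negative")
        return np.log(X + self.offset)


class KMeansDiscretizer(TransformerMixin, BaseEstimator):
    """Per-gene three-level k-means discretizer (samples x genes frames)."""

    def __init__(self, k: int = 3, random_state: int = 0):
        self.k = k
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return discretize_kmeans(X.T, k=self.k, seed=self.random_state).T
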
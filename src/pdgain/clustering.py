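"""Clustering of image series by their [I_alpha, P_alpha] spectra.

Each frame pair contributes one feature row ``[I_a1..I_aG, P_a1..P_aG]``
(26 features on the default 13-point grid); rows are optionally z-scored per
column, projected to principal components, clustered with k-means++ under the
squared Euclidean metric, and the labels renamed to appear consecutively
along the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .sequence import SpectrumTable

__all__ = [
    "FeatureMatrix",
    "ClusterLabels",
    "feature_matrix",
    "standardize",
    "cluster",
    "relabel_consecutive",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-pair feature rows: I spectrum then P spectrum, column-aligned."""

    values: np.ndarray  # (n_pairs, 2 * n_alphas)
    alphas: tuple
    pair_indices: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] != 2 * len(self.alphas):
            raise ValueError("feature matrix must have 2 * len(alphas) columns")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains missing values")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "pair_indices", np.asarray(self.pair_indices, dtype=np.int64)
        )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusterLabels:
    """1-based cluster assignment per feature row."""

    labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.min() < 1 or labels.max() > self.k:
            raise ValueError("labels must lie in 1..K")
        object.__setattr__(self, "labels", labels)


def feature_matrix(spectrum: SpectrumTable) -> FeatureMatrix:
    """Reshape a long-form spectrum table into per-pair feature rows.

    Row ``t`` is ``[I_alpha(t) for alpha in grid] + [P_alpha(t) ...]``; every
    pair must have been computed on the same alpha grid.
    """
    df = spectrum.data
    alphas = tuple(spectrum.alphas)
    pair_ids = np.sort(df["pair_index"].unique())
    pivot_i = df.pivot(index="pair_index", columns="alpha", values="I_alpha")
    pivot_p = df.pivot(index="pair_index", columns="alpha", values="P_alpha")
    expected = list(alphas)
    for pivot in (pivot_i, pivot_p):
        if sorted(pivot.columns) != sorted(expected) or pivot.isna().any().any():
            raise ValueError("inconsistent alpha grids across frame pairs")
    values = np.hstack(
        [pivot_i.loc[pair_ids, expected].to_numpy(), pivot_p.loc[pair_ids, expected].to_numpy()]
    )
    return FeatureMatrix(values=values, alphas=alphas, pair_indices=pair_ids)


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (sample standard deviation, Matlab convention).

    Constant columns map to all-zero instead of dividing by zero; the
    operation is idempotent.
    """
    if fm.n_rows < 2:
        raise ValueError("standardization needs at least two rows")
    values = fm.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    centered = values - mean
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return FeatureMatrix(
        values=out,
        alphas=fm.alphas,
        pair_indices=fm.pair_indices,
        standardized=True,
    )


def cluster(
    fm: FeatureMatrix,
    k: int,
    seed: int = 0,
    n_components: float | int | None = 0.95,
    use_pca: bool = True,
    n_restarts: int = 10,
) -> ClusterLabels:
    """k-means++ clustering of the feature rows in principal-component space.

    ``n_components`` follows scikit-learn semantics (a fraction keeps enough
    components to explain that share of variance; ``None`` keeps all);
    ``use_pca=False`` clusters the raw feature space instead.  Fixed seed and
    inputs give identical labels.
    """
    if not 2 <= k:
        raise ValueError("need at least two clusters")
    if k > fm.n_rows:
        raise ValueError(f"cannot form {k} clusters from {fm.n_rows} rows")
    x = fm.values
    if use_pca:
        max_comp = min(x.shape[0], x.shape[1])
        if n_components is None:
            n_components_eff = max_comp
        elif isinstance(n_components, float) and 0 < n_components < 1:
            n_components_eff = n_components if max_comp > 1 else 1
        else:
            n_components_eff = min(int(n_components), max_comp)
        if np.allclose(x, x[0]):
            warnings.warn("degenerate (constant) feature matrix", stacklevel=2)
            x = np.zeros((x.shape[0], 1))
        else:
            x = PCA(n_components=n_components_eff, random_state=seed).fit_transform(x)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
    )
    raw = km.fit_predict(x)
    if len(np.unique(raw)) < k:
        warnings.warn("degenerate clustering: fewer than K distinct clusters", stacklevel=2)
    return ClusterLabels(labels=raw + 1, k=k, seed=seed)


def relabel_consecutive(labels: ClusterLabels) -> ClusterLabels:
    """Rename clusters by order of first appearance along the series.

    The partition is unchanged; the first row gets label 1 and each new label
    first appears only after all smaller ones.
    """
    raw = labels.labels
    mapping: dict[int, int] = {}
    for lab in raw:
        if int(lab) not in mapping:
            mapping[int(lab)] = len(mapping) + 1
    renamed = np.array([mapping[int(lab)] for lab in raw], dtype=np.int64)
    return ClusterLabels(labels=renamed, k=labels.k, seed=labels.seed)
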
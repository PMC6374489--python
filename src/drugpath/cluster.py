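"""Sample-similarity and inhibitor-response clustering.

Three views: a Pearson-correlation matrix between samples over inhibitor
z-score profiles; a complete-linkage dendrogram on Euclidean distances
between rows of the Spearman-correlation matrix (so the distance between
two samples reflects how similarly they correlate with everyone else —
rank-based, hence invariant to monotone per-sample transforms); and a PCA
of the transposed z-matrix with the first two component scores.

Determinism: scipy's linkage resolves distance ties by lowest pair index;
PCA signs follow the convention that each component's largest-magnitude
loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_types import CONTROL_KINDS
from .normalization import ZScoreMatrix


@dataclass
class ClusterResult:
    correlations: pd.DataFrame
    linkage: np.ndarray
    labels: list[str]
    flat_clusters: dict[int, np.ndarray]
    pca_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def _process_matrix(
    z: ZScoreMatrix, process: str, conditions: list[str] | None
) -> pd.DataFrame:
    mat = z.data[process]
    if conditions is None:
        conditions = [c for c in mat.index if c not in CONTROL_KINDS]
    return mat.loc[conditions]


def sample_correlations(
    z: ZScoreMatrix, process: str, conditions: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations between samples over condition vectors.

    ``conditions`` restricts the profile to e.g. significant hits only;
    default is all inhibitor conditions.  Constant sample vectors yield NaN
    entries (flagged missing, never coerced to 0); the diagonal is exactly 1.
    """
    mat = _process_matrix(z, process, conditions)
    if len(mat) < 2:
        raise ValueError("need >= 2 conditions for sample correlations")
    x = mat.to_numpy(dtype=float)
    const = x.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=mat.columns, columns=mat.columns)


def spearman_distance_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between rows of the Spearman-correlation matrix."""
    rho = stats.spearmanr(mat.to_numpy(dtype=float), axis=0).statistic
    rho = np.atleast_2d(rho)
    d = np.sqrt(((rho[:, None, :] - rho[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


def hierarchical_cluster(
    z: ZScoreMatrix,
    process: str,
    conditions: list[str] | None = None,
    n_clusters: int | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Complete-linkage dendrogram of samples; optional flat cut.

    Returns (scipy linkage matrix, leaf labels, flat labels at the cut).
    """
    mat = _process_matrix(z, process, conditions)
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    dist = spearman_distance_matrix(mat)
    condensed = dist.to_numpy()[np.triu_indices(len(dist), k=1)]
    link = hierarchy.linkage(condensed, method="complete")
    labels = list(mat.columns)
    flat = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return link, labels, flat


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def pca_scores(
    z: ZScoreMatrix,
    process: str,
    conditions: list[str] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores of samples on the first principal components.

    Samples are observations (the z-matrix is transposed), condition means
    are removed, and components come from the SVD of the centered matrix.
    Sign convention: the largest-magnitude loading of each component is
    positive, making output deterministic.
    """
    mat = _process_matrix(z, process, conditions)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 conditions for PCA")
    x = mat.to_numpy(dtype=float).T  # samples x conditions
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    evr = (s[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    df = pd.DataFrame(
        scores, index=mat.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, evr
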
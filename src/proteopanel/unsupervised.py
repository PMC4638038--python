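"""Unsupervised structure: SVD-based PCA and hierarchical clustering.

Samples are the observations and proteins the variables; each protein is
centered across samples before the singular value decomposition. The loadings
of a component rank the proteins driving it, and the pair of components that
best separates two known subtype labels can be selected automatically by the
between-group t statistic of the scores.

Hierarchical clustering uses Pearson-correlation distance (1 - r) with average
linkage — the standard choice for expression heatmaps; the two-cluster cut of
the sample dendrogram is compared against the subtype labels to decide whether
unsupervised clustering recovers the subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import ttest_ind

__all__ = [
    "PCAResult",
    "pca",
    "select_component_pair",
    "top_loadings",
    "signature_pca",
    "Dendrogram",
    "hierarchical_cluster",
    "subtype_split_correct",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_fraction: np.ndarray
    n_signature_matched: int | None = None  # set by signature_pca


def pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA by SVD of the protein-centered samples x proteins matrix.

    Deterministic sign convention: each loading column is flipped so its
    largest-magnitude entry is positive (scores flipped accordingly).
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = matrix.T.to_numpy(dtype=float)  # samples x proteins
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention on loadings
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * S
    total = float(np.sum(S**2))
    frac = S**2 / total if total > 0 else np.zeros_like(S)
    comp_names = [f"PC{k+1}" for k in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comp_names),
        explained_variance_fraction=frac,
    )


def select_component_pair(result: PCAResult, labels: pd.Series) -> tuple[str, str]:
    """The two components whose scores best separate the two label groups.

    Separation is the absolute two-sample t statistic of the component scores
    between groups; returns the component names of the top two.
    """
    lab = labels.reindex(result.scores.index)
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise ValueError("exactly two label classes required")
    a = result.scores[lab == classes[0]]
    b = result.scores[lab == classes[1]]
    t = ttest_ind(a, b, axis=0).statistic
    t = np.nan_to_num(np.abs(np.asarray(t)), nan=0.0)
    order = np.argsort(-t, kind="stable")
    cols = result.scores.columns
    return cols[order[0]], cols[order[1]]


def top_loadings(result: PCAResult, component: str, k: int) -> pd.DataFrame:
    """Top-k proteins by |loading| on a component, with loading sign.

    Ties are broken by stable protein-ID order. The sign column says which
    score direction the protein pushes samples toward.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    col = result.loadings[component]
    if k > len(col):
        raise ValueError("k exceeds protein count")
    df = pd.DataFrame({"loading": col, "abs_loading": col.abs()})
    df = df.sort_values(["abs_loading"], ascending=False, kind="stable").head(k)
    df["sign"] = np.where(df["loading"] >= 0, "+", "-")
    return df[["loading", "sign"]]


def signature_pca(matrix: pd.DataFrame, signature_ids) -> PCAResult:
    """PCA restricted to a protein signature; records how many IDs matched."""
    present = [p for p in signature_ids if p in matrix.index]
    if len(present) < 3:
        raise ValueError(f"only {len(present)} signature proteins present; need >= 3")
    res = pca(matrix.loc[present])
    res.n_signature_matched = len(present)
    return res


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage matrix) over labelled items."""

    linkage_matrix: np.ndarray
    item_ids: list[str]
    axis: str

    def cut(self, n_clusters: int) -> pd.Series:
        assign = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.item_ids)

    def to_newick(self) -> str:
        n = len(self.item_ids)
        Z = self.linkage_matrix

        def rec(node: int) -> str:
            if node < n:
                return self.item_ids[node]
            a, b, h, _ = Z[node - n]
            return f"({rec(int(a))},{rec(int(b))}):{h:.6g}"

        return rec(2 * n - 2) + ";"


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "samples") -> Dendrogram:
    """Average-linkage clustering with Pearson-correlation distance (1 - r)."""
    if axis not in ("samples", "proteins"):
        raise ValueError("axis must be 'samples' or 'proteins'")
    data = matrix.T if axis == "samples" else matrix
    ids = list(data.index)
    if len(ids) < 2:
        raise ValueError(f"need at least 2 {axis}")
    X = data.to_numpy(dtype=float)
    const = np.isclose(X.std(axis=1), 0.0)
    if const.any():
        bad = [ids[i] for i in np.nonzero(const)[0]]
        raise ValueError(f"constant profiles make correlation undefined: {bad[:5]}")
    Z = linkage(pdist(X, metric="correlation"), method="average")
    return Dendrogram(linkage_matrix=Z, item_ids=ids, axis=axis)


def subtype_split_correct(dendrogram: Dendrogram, labels: pd.Series) -> bool:
    """True iff the two-cluster cut bipartitions samples exactly by label."""
    cut = dendrogram.cut(2)
    lab = labels.reindex(cut.index)
    groups = [set(cut.index[cut == c]) for c in sorted(cut.unique())]
    truth = [set(lab.index[lab == c]) for c in sorted(lab.unique())]
    if len(groups) != 2 or len(truth) != 2:
        return False
    return (groups[0] == truth[0] and groups[1] == truth[1]) or (
        groups[0] == truth[1] and groups[1] == truth[0]
    )
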
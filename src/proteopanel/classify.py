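"""Supervised subtype classification and minimal-panel extraction.

Features (proteins) are ranked by a moderated two-sample statistic
d = (mean_A - mean_B) / (se + s0): the constant s0 added to the pooled
standard error damps the statistic of low-variance, low-fold-change proteins,
so proteins with larger between-subtype fold changes obtain better ranks than
under the classical t statistic. A linear soft-margin SVM is the classifier.

Both feature ranking and classifier training run inside a random-sampling
cross-validation (stratified 90% training draws by default): per repetition
the features are ranked on the training samples only, SVMs are trained on the
top-k features over a grid of k, and held-out errors are aggregated into a
per-k error curve. The optimal panel size is the smallest k minimizing the
mean held-out error. A complementary, coarser cutoff takes the largest k for
which unsupervised hierarchical clustering of the samples restricted to the
top-k features still splits into the correct subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .unsupervised import Dendrogram, hierarchical_cluster, subtype_split_correct

__all__ = [
    "ModeratedStatParams",
    "CVConfig",
    "CVReport",
    "moderated_t",
    "rank_features",
    "train_svm",
    "cv_feature_selection",
    "final_panel",
    "clustering_loss_cutoff",
    "default_k_grid",
]


@dataclass(frozen=True)
class ModeratedStatParams:
    s0: float = 0.1
    p_mode: str = "parametric"
    n_permutations: int = 250

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.p_mode not in ("parametric", "permutation"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")


def default_k_grid(n_features: int | None = None) -> list[int]:
    grid = list(range(1, 21)) + [25, 30, 40, 50, 75, 100, 150, 200, 300, 400, 500]
    if n_features is not None:
        grid = [k for k in grid if k <= n_features]
    return grid


@dataclass(frozen=True)
class CVConfig:
    train_fraction: float = 0.9
    repetitions: int = 1000
    k_grid: tuple[int, ...] = ()
    seed: int = 0
    svm_cost: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if list(self.k_grid) != sorted(set(self.k_grid)):
            raise ValueError("k_grid must be strictly ascending")


def _group_stats(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    ma = X[:, mask_a].mean(axis=1)
    mb = X[:, mask_b].mean(axis=1)
    va = X[:, mask_a].var(axis=1, ddof=1)
    vb = X[:, mask_b].var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return ma - mb, se, na, nb


def moderated_t(
    matrix: pd.DataFrame,
    labels: pd.Series,
    params: ModeratedStatParams = ModeratedStatParams(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Moderated statistic d and p-value per protein.

    d = (mean_A - mean_B) / (se + s0) with se the pooled two-sample standard
    error. Parametric p uses a Student reference with n_A + n_B - 2 df on |d|
    (exact only at s0 = 0; at s0 > 0 it is the conventional plug-in used for
    ranking). Permutation mode compares |d| against label permutations.
    """
    lab = labels.reindex(matrix.columns)
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    mask_a = (lab == classes[0]).to_numpy()
    mask_b = (lab == classes[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    diff, se, na, nb = _group_stats(X, mask_a, mask_b)
    if params.s0 == 0 and (se == 0).any():
        raise ValueError("zero-variance protein with s0 = 0")
    d = diff / (se + params.s0)
    df = na + nb - 2
    if params.p_mode == "parametric":
        p = 2.0 * stats.t.sf(np.abs(d), df)
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        exceed = np.zeros(X.shape[0])
        idx = np.arange(X.shape[1])
        for _ in range(params.n_permutations):
            perm = rng.permutation(idx)
            pa, pb = np.zeros_like(mask_a), np.zeros_like(mask_b)
            pa[perm[: na]] = True
            pb[perm[na:]] = True
            pd_, pse, _, _ = _group_stats(X, pa, pb)
            exceed += np.abs(pd_ / (pse + params.s0)) >= np.abs(d)
        p = (1.0 + exceed) / (1.0 + params.n_permutations)
    return pd.DataFrame({"d": d, "p": p, "log2fc": diff}, index=matrix.index)


def rank_features(
    matrix: pd.DataFrame,
    labels: pd.Series,
    params: ModeratedStatParams = ModeratedStatParams(),
) -> list[str]:
    """Protein IDs sorted by ascending p, ties by |fold change| then ID."""
    res = moderated_t(matrix, labels, params)
    order = res.assign(absfc=res["log2fc"].abs()).sort_values(
        ["p", "absfc"], ascending=[True, False], kind="stable"
    )
    return list(order.index)


class LinearSVMPredictor:
    """Linear soft-margin SVM over a fixed feature list."""

    def __init__(self, clf: SVC, feature_ids: list[str], classes: list[str]):
        self._clf = clf
        self.feature_ids = feature_ids
        self.classes = classes

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        X = matrix.loc[self.feature_ids].T.to_numpy(dtype=float)
        return pd.Series(self._clf.predict(X), index=matrix.columns)

    def decision_margin(self, matrix: pd.DataFrame) -> pd.Series:
        X = matrix.loc[self.feature_ids].T.to_numpy(dtype=float)
        return pd.Series(self._clf.decision_function(X), index=matrix.columns)

    @property
    def support_sample_indices(self) -> np.ndarray:
        return self._clf.support_


def train_svm(
    train_matrix: pd.DataFrame, train_labels: pd.Series, cost: float = 1.0
) -> LinearSVMPredictor:
    lab = train_labels.reindex(train_matrix.columns)
    classes = sorted(lab.unique())
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(train_matrix.T.to_numpy(dtype=float), lab.to_numpy())
    return LinearSVMPredictor(clf, list(train_matrix.index), classes)


@dataclass
class CVReport:
    """Result of the cross-validated feature selection."""

    k_grid: list[int]
    mean_error: pd.Series  # per k
    sd_error: pd.Series  # per k (across repetitions)
    optimal_k: int
    selection_frequency: pd.Series  # per feature, within top-optimal_k
    panel: list[str]  # full-data top-optimal_k ranking
    repetitions: int
    n_redrawn: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"cross-validation: {self.repetitions} repetitions, "
            f"{self.n_redrawn} redrawn splits",
            f"optimal panel size k = {self.optimal_k} "
            f"(mean held-out error {100 * self.mean_error[self.optimal_k]:.1f}%)",
            "panel (full-data ranking, CV selection frequency):",
        ]
        for pid in self.panel:
            lines.append(f"  {pid}  {self.selection_frequency.get(pid, 0.0):.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_grid": list(self.k_grid),
            "mean_error": {int(k): float(v) for k, v in self.mean_error.items()},
            "sd_error": {int(k): float(v) for k, v in self.sd_error.items()},
            "optimal_k": int(self.optimal_k),
            "panel": list(self.panel),
            "selection_frequency": {
                k: float(v) for k, v in self.selection_frequency.items()
            },
            "repetitions": int(self.repetitions),
            "n_redrawn": int(self.n_redrawn),
            "seed": int(self.seed),
        }


def _stratified_split(lab: pd.Series, train_fraction: float, rng: np.random.Generator):
    train_idx: list[int] = []
    for cls in sorted(lab.unique()):
        members = np.nonzero((lab == cls).to_numpy())[0]
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.extend(rng.choice(members, size=n_train, replace=False))
    mask = np.zeros(len(lab), dtype=bool)
    mask[train_idx] = True
    return mask


def cv_feature_selection(
    matrix: pd.DataFrame,
    labels: pd.Series,
    cv: CVConfig = CVConfig(),
    stat: ModeratedStatParams = ModeratedStatParams(),
) -> CVReport:
    """Random-sampling cross-validation with embedded feature selection.

    Per repetition: a stratified random draw of ``train_fraction`` of each
    class trains; features are ranked on the training samples only; for each k
    in the grid a linear SVM on the top-k training features predicts the
    held-out samples. Mean error per k pools misclassifications over all
    held-out predictions. optimal_k is the smallest k attaining the minimum.
    """
    lab = labels.reindex(matrix.columns)
    k_grid = list(cv.k_grid) or default_k_grid(matrix.shape[0])
    rng = np.random.default_rng(cv.seed)
    n_feat = matrix.shape[0]
    k_grid = [k for k in k_grid if k <= n_feat]
    errors = {k: [] for k in k_grid}  # per-rep (n_wrong, n_test)
    top_sets: list[list[str]] = []
    n_redrawn = 0
    for _ in range(cv.repetitions):
        # stratification guarantees both classes in the held-out set; the
        # redraw guard protects degenerate configurations all the same
        for _attempt in range(100):
            train_mask = _stratified_split(lab, cv.train_fraction, rng)
            test_mask = ~train_mask
            if lab[test_mask].nunique() == 2:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a held-out set with both classes")
        train_cols = matrix.columns[train_mask]
        test_cols = matrix.columns[test_mask]
        ranked = rank_features(matrix[train_cols], lab[train_cols], stat)
        top_sets.append(ranked[: max(k_grid)])
        for k in k_grid:
            feats = ranked[:k]
            pred = train_svm(matrix.loc[feats, train_cols], lab[train_cols], cv.svm_cost)
            yhat = pred.predict(matrix.loc[feats, test_cols])
            wrong = int((yhat != lab[test_cols]).sum())
            errors[k].append((wrong, len(test_cols)))

    mean_err, sd_err = {}, {}
    for k in k_grid:
        wrongs = np.array([w for w, _ in errors[k]], dtype=float)
        tests = np.array([t for _, t in errors[k]], dtype=float)
        mean_err[k] = float(wrongs.sum() / tests.sum())
        sd_err[k] = float(np.std(wrongs / tests, ddof=1)) if len(wrongs) > 1 else 0.0
    mean_series = pd.Series(mean_err)
    optimal_k = int(min(k for k in k_grid if mean_err[k] == mean_series.min()))

    counts: dict[str, int] = {}
    for top in top_sets:
        for pid in top[:optimal_k]:
            counts[pid] = counts.get(pid, 0) + 1
    freq = pd.Series(counts, dtype=float).sort_values(ascending=False) / cv.repetitions
    panel = final_panel(matrix, lab, optimal_k, stat)
    return CVReport(
        k_grid=k_grid,
        mean_error=mean_series,
        sd_error=pd.Series(sd_err),
        optimal_k=optimal_k,
        selection_frequency=freq,
        panel=panel,
        repetitions=cv.repetitions,
        n_redrawn=n_redrawn,
        seed=cv.seed,
    )


def final_panel(
    matrix: pd.DataFrame,
    labels: pd.Series,
    k: int,
    stat: ModeratedStatParams = ModeratedStatParams(),
) -> list[str]:
    """Top-k features of the full-data ranking (deterministic)."""
    if k < 1 or k > matrix.shape[0]:
        raise ValueError("k out of range")
    return rank_features(matrix, labels, stat)[:k]


def clustering_loss_cutoff(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ranked_ids: list[str],
    scan_grid: list[int] | None = None,
) -> int:
    """Largest k such that top-k features still cluster the subtypes correctly.

    Scans k upward (default grid: every rank up to 50, then steps of 10);
    returns the largest k with a correct two-cluster split at every scanned
    k' <= k. Returns 0 if the split is wrong already at the smallest k.
    """
    n = len(ranked_ids)
    if scan_grid is None:
        scan_grid = list(range(1, min(50, n) + 1)) + list(range(60, n + 1, 10))
    scan_grid = [k for k in scan_grid if 1 <= k <= n]
    best = 0
    for k in scan_grid:
        sub = matrix.loc[ranked_ids[:k]]
        try:
            if k <= 2:
                # correlation distance is undefined on one feature and
                # degenerate (only +/-1) on two, since each sample profile is
                # centered; fall back to Euclidean average linkage there
                from scipy.cluster.hierarchy import linkage as _linkage

                Z = _linkage(sub.T.to_numpy(dtype=float), method="average")
                dend = Dendrogram(Z, list(sub.columns), axis="samples")
            else:
                dend = hierarchical_cluster(sub, axis="samples")
        except ValueError:
            break  # constant profiles: treat as split lost
        if subtype_split_correct(dend, labels):
            best = k
        else:
            break
    return best
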
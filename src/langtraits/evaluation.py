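"""Generalizability battery: likes clustering and cross-validated prediction.

Continuous outcomes are predicted with ridge regression and reported as the
mean Pearson r over random train/test splits; binary like-cluster targets
are predicted with L2 logistic regression and reported as mean AUC over the
targets and splits. Fine-grained likes are first grouped into a small
number of broad binary targets by non-negative matrix factorization of the
user-item matrix. All penalties are chosen by inner cross-validated grid
search on the training part of each split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import NMF
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, ShuffleSplit

from .factor_model import FactorScores

logger = logging.getLogger(__name__)

PENALTY_GRID = np.logspace(-3, 3, 7)
INNER_CV_FOLDS = 3


@dataclass
class LikesMatrix:
    """Sparse binary users x items matrix of fine-grained likes."""

    matrix: sp.csr_matrix
    user_ids: list[str]
    item_ids: list[str]

    def __post_init__(self) -> None:
        data = self.matrix.data
        if data.size and not np.isin(data, (0, 1)).all():
            raise ValueError("likes entries must be 0/1")

    @property
    def popularity(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


@dataclass
class LikeClusters:
    n_clusters: int
    item_ids: list[str]
    item_membership: np.ndarray  # items x n_clusters, nonnegative
    user_labels: np.ndarray  # users x n_clusters, binary
    user_ids: list[str]
    top_items: dict[int, list[str]]

    def item_assignment(self) -> np.ndarray:
        return self.item_membership.argmax(axis=1)


@dataclass
class PredictionReport:
    outcome: str
    feature_set: str
    metric: str  # "pearson_r" or "auc"
    per_split: list[float]
    n_splits: int
    grid: list[float] = field(default_factory=lambda: list(PENALTY_GRID))
    per_target: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_split))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_split, ddof=1)) if len(self.per_split) > 1 else 0.0


def cluster_likes(
    likes: LikesMatrix,
    top_items: int = 10000,
    n_clusters: int = 20,
    seed: int = 0,
) -> LikeClusters:
    """Group fine-grained likes into broad targets with rank-``n_clusters``
    NMF of the (popularity-restricted) binary matrix.

    Items keep their cluster memberships from the item-side factor; each
    user gets one binary label per cluster by thresholding the user-side
    weight at that cluster's median, which yields balanced targets.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if likes.matrix.nnz == 0:
        raise ValueError("empty likes matrix")
    pop = likes.popularity
    order = np.lexsort((likes.item_ids, -pop))
    keep = np.sort(order[: min(top_items, len(pop))])
    mat = likes.matrix[:, keep].astype(float)
    item_ids = [likes.item_ids[j] for j in keep]
    if n_clusters > min(mat.shape):
        raise ValueError(
            f"n_clusters={n_clusters} exceeds matrix dimension {min(mat.shape)}"
        )
    nmf = NMF(
        n_components=n_clusters, init="nndsvda", random_state=seed,
        max_iter=600, tol=1e-6,
    )
    w = nmf.fit_transform(mat)  # users x clusters
    h = nmf.components_  # clusters x items
    item_membership = h.T
    medians = np.median(w, axis=0)
    user_labels = (w > medians).astype(int)
    top: dict[int, list[str]] = {}
    for c in range(n_clusters):
        rank = np.lexsort((item_ids, -item_membership[:, c]))
        top[c] = [item_ids[j] for j in rank[:10]]
    return LikeClusters(
        n_clusters=n_clusters,
        item_ids=item_ids,
        item_membership=item_membership,
        user_labels=user_labels,
        user_ids=list(likes.user_ids),
        top_items=top,
    )


def cluster_purity(assignment: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of items whose cluster's majority true label matches theirs."""
    assignment = np.asarray(assignment)
    truth = np.asarray(truth)
    total = 0
    for c in np.unique(assignment):
        labels = truth[assignment == c]
        total += np.bincount(labels).max()
    return total / len(truth)


def _splits(n: int, n_splits: int, test_size: float, seed: int):
    return ShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed).split(
        np.arange(n)
    )


def evaluate_regression(
    features: np.ndarray,
    outcome: np.ndarray,
    n_splits: int = 10,
    seed: int = 0,
    test_size: float = 0.25,
    name: str = "outcome",
    feature_set: str = "features",
) -> PredictionReport:
    """Ridge regression predictive validity: mean Pearson r over
    ``n_splits`` random 75/25 train/test splits, penalty grid-searched by
    inner cross-validation on each training part.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and outcome are not row-aligned")
    if np.std(y) == 0:
        raise ValueError("constant outcome: Pearson r undefined")
    per_split: list[float] = []
    for train, test in _splits(len(y), n_splits, test_size, seed):
        gs = GridSearchCV(
            Ridge(), {"alpha": PENALTY_GRID}, cv=INNER_CV_FOLDS,
            scoring="neg_mean_squared_error",
        )
        gs.fit(x[train], y[train])
        pred = gs.predict(x[test])
        if np.std(pred) == 0 or np.std(y[test]) == 0:
            per_split.append(0.0)
        else:
            per_split.append(float(stats.pearsonr(pred, y[test])[0]))
    return PredictionReport(name, feature_set, "pearson_r", per_split, n_splits)


def evaluate_classification(
    features: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 10,
    seed: int = 0,
    test_size: float = 0.25,
    name: str = "targets",
    feature_set: str = "features",
    target_names: list[str] | None = None,
) -> PredictionReport:
    """L2 logistic-regression AUC for a matrix of binary targets.

    Per split and target, the penalty is grid-searched with inner CV and
    AUC measured on the test part; the report's per-split values are means
    over targets and ``per_target`` holds each target's mean over splits.
    Targets with a single class overall are skipped with a warning; splits
    leaving a training side single-class for some target are redrawn.
    """
    x = np.asarray(features, dtype=float)
    lab = np.asarray(labels)
    if lab.ndim == 1:
        lab = lab[:, None]
    if target_names is None:
        target_names = [f"target{j}" for j in range(lab.shape[1])]
    usable = []
    for j in range(lab.shape[1]):
        if len(np.unique(lab[:, j])) < 2:
            logger.warning("target %s has a single class overall; skipped", target_names[j])
        else:
            usable.append(j)
    if not usable:
        raise ValueError("no target with both classes present")

    rng = np.random.default_rng(seed)
    n = len(lab)
    per_split: list[float] = []
    per_target = {target_names[j]: [] for j in usable}
    splits = list(_splits(n, n_splits, test_size, seed))
    for si, (train, test) in enumerate(splits):
        attempts = 0
        while any(
            len(np.unique(lab[train, j])) < 2 or len(np.unique(lab[test, j])) < 2
            for j in usable
        ):
            attempts += 1
            if attempts > 50:
                raise RuntimeError("could not draw a split with both classes per target")
            logger.info("resampling split %d: single-class target in partition", si)
            perm = rng.permutation(n)
            cut = len(test)
            test, train = perm[:cut], perm[cut:]
        aucs = []
        for j in usable:
            gs = GridSearchCV(
                LogisticRegression(max_iter=2000),
                {"C": PENALTY_GRID}, cv=INNER_CV_FOLDS, scoring="roc_auc",
            )
            gs.fit(x[train], lab[train, j])
            prob = gs.predict_proba(x[test])[:, 1]
            auc = float(roc_auc_score(lab[test, j], prob))
            aucs.append(auc)
            per_target[target_names[j]].append(auc)
        per_split.append(float(np.mean(aucs)))
    report = PredictionReport(name, feature_set, "auc", per_split, n_splits)
    report.per_target = {t: float(np.mean(v)) for t, v in per_target.items()}
    return report


def add_covariates(features: pd.DataFrame, demographics: pd.DataFrame) -> pd.DataFrame:
    """Concatenate z-scored age and 0/1 gender to the feature columns.

    Alignment is by user id (inner join); users with missing demographic
    values are dropped with a logged count. Passing an empty feature frame
    reproduces the demographics-only baseline.
    """
    demo = demographics[["age", "gender"]].copy()
    n_missing = int(demo.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d users with missing demographics", n_missing)
        demo = demo.dropna()
    if features.shape[1] == 0:
        joined = demo.loc[demo.index.intersection(features.index)].sort_index()
    else:
        joined = features.join(demo, how="inner").sort_index()
    age = joined.pop("age").to_numpy(dtype=float)
    sd = age.std()
    joined["age_z"] = (age - age.mean()) / (sd if sd > 0 else 1.0)
    joined["gender"] = joined.pop("gender").astype(int)
    return joined


def residualize(scores: FactorScores, demographics: pd.DataFrame) -> FactorScores:
    """Replace each factor column by its OLS residual on [1, age_z, gender].

    Residuals are exactly uncorrelated with the retained covariates;
    constant covariates are dropped with a warning.
    """
    sf = scores.to_frame()
    demo = demographics[["age", "gender"]].reindex(sf.index)
    if demo.isna().any().any():
        raise ValueError("demographics missing for some scored users")
    cols = [np.ones(len(sf))]
    for c in ("age", "gender"):
        v = demo[c].to_numpy(dtype=float)
        if np.std(v) == 0:
            logger.warning("covariate %s is constant; dropped from residualization", c)
            continue
        cols.append((v - v.mean()) / v.std())
    design = np.column_stack(cols)
    y = sf.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return FactorScores(list(sf.index), resid, model_id=scores.model_id)


def rank_targets(reports: list[PredictionReport], top_n: int = 5) -> pd.DataFrame:
    """Order prediction targets by their mean metric, best first.

    All reports must share one metric; ties break by outcome name. The
    returned frame flags the top and bottom ``top_n`` slices.
    """
    if not reports:
        raise ValueError("need at least one report")
    metrics = {r.metric for r in reports}
    if len(metrics) > 1:
        raise ValueError(f"mixed metrics in one ranking: {sorted(metrics)}")
    df = pd.DataFrame(
        {
            "outcome": [r.outcome for r in reports],
            "feature_set": [r.feature_set for r in reports],
            "metric": [r.metric for r in reports],
            "mean": [r.mean for r in reports],
            "sd": [r.sd for r in reports],
        }
    )
    df = df.sort_values(["mean", "outcome"], ascending=[False, True]).reset_index(drop=True)
    df["slice"] = ""
    df.loc[df.index[: min(top_n, len(df))], "slice"] = "top"
    bottom = df.index[-min(top_n, len(df)):]
    df.loc[[i for i in bottom if df.loc[i, "slice"] == ""], "slice"] = "bottom"
    return df


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_likes(likes: LikesMatrix, path: str | Path) -> None:
    coo = likes.matrix.tocoo()
    pd.DataFrame(
        {
            "user_id": [likes.user_ids[i] for i in coo.row],
            "item_id": [likes.item_ids[j] for j in coo.col],
            "value": np.ones(coo.nnz, dtype=int),
        }
    ).to_csv(path, index=False)


def read_likes(path: str | Path) -> LikesMatrix:
    df = pd.read_csv(path, dtype={"user_id": str, "item_id": str})
    users = sorted(df["user_id"].unique())
    items = sorted(df["item_id"].unique())
    ui = {u: i for i, u in enumerate(users)}
    ii = {t: j for j, t in enumerate(items)}
    mat = sp.csr_matrix(
        (
            np.ones(len(df), dtype=np.int8),
            (df["user_id"].map(ui), df["item_id"].map(ii)),
        ),
        shape=(len(users), len(items)),
    )
    mat.data = np.minimum(mat.data, 1).astype(np.int8)
    return LikesMatrix(matrix=mat, user_ids=users, item_ids=items)


def write_reports(reports: list[PredictionReport], path: str | Path) -> None:
    rows = [
        {
            "outcome": r.outcome,
            "feature_set": r.feature_set,
            "metric": r.metric,
            "mean": r.mean,
            "sd": r.sd,
            "n_splits": r.n_splits,
            "per_split": json.dumps(r.per_split),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
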
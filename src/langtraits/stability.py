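"""Temporal and resampling stability of the induced factors.

Test-retest: a model is learned on a random 75% of each user's messages;
the held-out 25% is split into 6-month windows, each window's users are
scored with the fixed model, and per-factor correlations are computed
between every window and the earliest one.

Dropout reliability: the model is refit many times on the training matrix
with a random 20% of users removed; a fixed held-out user set is scored by
every refit, and for every pair of refits the factors are optimally matched
(Hungarian assignment on 1 - |r|) before averaging the matched absolute
correlations. Factor sign and order are arbitrary across refits, which is
exactly what the alignment absorbs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .corpus import (
    MessageCorpus,
    build_user_term_matrix,
    build_vocabulary,
    window_corpus,
    UserTermMatrix,
)
from .factor_model import FactorModelConfig, FactorScores, fit_pipeline, score_users

logger = logging.getLogger(__name__)


@dataclass
class FactorAlignment:
    """Optimal factor matching between two score sets."""

    permutation: np.ndarray  # factor j of A matches factor permutation[j] of B
    signs: np.ndarray  # sign of each matched correlation
    matched_abs_corr: np.ndarray

    @property
    def mean_abs_corr(self) -> float:
        return float(self.matched_abs_corr.mean())


@dataclass
class StabilityReport:
    retest: pd.DataFrame | None = None  # columns: factor, lag, r, n_users
    dropout_pairs: pd.DataFrame | None = None  # run_i, run_j, mean_abs_corr
    n_runs: int = 0
    drop_fraction: float = 0.0

    @property
    def dropout_mean(self) -> float:
        if self.dropout_pairs is None or not len(self.dropout_pairs):
            raise ValueError("no dropout results")
        return float(self.dropout_pairs["mean_abs_corr"].mean())


def _abs_corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    k = a.shape[1]
    out = np.zeros((k, k))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    an = np.linalg.norm(ac, axis=0)
    bn = np.linalg.norm(bc, axis=0)
    for arr, norms, name in ((a, an, "first"), (b, bn, "second")):
        if np.any(norms == 0):
            logger.warning("constant factor column in %s score set; correlation set to 0", name)
    an = np.where(an == 0, np.inf, an)
    bn = np.where(bn == 0, np.inf, bn)
    out = (ac.T @ bc) / np.outer(an, bn)
    return out


def align_factors(scores_a: FactorScores, scores_b: FactorScores) -> FactorAlignment:
    """Hungarian matching of factors by maximal absolute correlation.

    Cost C[i, j] = 1 - |pearson(a_i, b_j)|; the exact assignment minimizing
    total cost is returned with the signs of the matched correlations.
    """
    if scores_a.row_users != scores_b.row_users:
        raise ValueError("score sets must cover the same users in the same order")
    if scores_a.k != scores_b.k:
        raise ValueError("score sets must have the same number of factors")
    r = _abs_corr_matrix(scores_a.scores, scores_b.scores)
    rows, cols = linear_sum_assignment(1 - np.abs(r))
    perm = np.empty_like(cols)
    perm[rows] = cols
    matched = np.abs(r[rows, cols])
    signs = np.sign(r[rows, cols])
    signs[signs == 0] = 1
    return FactorAlignment(permutation=perm, signs=signs, matched_abs_corr=matched)


def split_messages_per_user(
    corpus: MessageCorpus, train_fraction: float, seed: int
) -> tuple[MessageCorpus, MessageCorpus]:
    """Random per-user message split so every user appears in both parts."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    rec = corpus.records
    train_mask = np.zeros(len(rec), dtype=bool)
    for _, idx in rec.groupby("user_id").indices.items():
        idx = np.asarray(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_mask[chosen] = True
    train = MessageCorpus(rec[train_mask].reset_index(drop=True), corpus.user_meta,
                          dict(corpus.attrs))
    test = MessageCorpus(rec[~train_mask].reset_index(drop=True), corpus.user_meta,
                         dict(corpus.attrs))
    return train, test


def test_retest(
    corpus: MessageCorpus,
    model_config: FactorModelConfig,
    train_fraction: float = 0.75,
    window_months: int = 6,
    min_words: int = 1000,
    seed: int = 0,
) -> StabilityReport:
    """Cross-window correlation of factor scores inferred from held-out text.

    The per-user message split keeps every user in both portions; the model
    (vocabulary, standardization, loadings) is learned on the training
    portion only, then applied to each window of the test portion. For each
    factor and lag t, Pearson r is computed between window-t and window-0
    scores over the users present in both windows (lag 0 is identically 1).
    """
    train, test = split_messages_per_user(corpus, train_fraction, seed)
    vocab = build_vocabulary(train, top_k=model_config.vocab_top_k)
    utm = build_user_term_matrix(train, vocab, transform=model_config.transform)
    model, _ = fit_pipeline(utm, model_config)

    windows = window_corpus(test, window_months=window_months,
                            min_words_per_window=min_words)
    if len(windows) < 2:
        raise ValueError("need at least 2 non-empty windows for test-retest")
    scored: dict[int, pd.DataFrame] = {}
    for w, wc in windows:
        wm = build_user_term_matrix(wc, vocab, transform=model_config.transform)
        scored[w] = score_users(model, wm).to_frame()
    w0 = min(scored)
    base = scored[w0]
    rows = []
    for w in sorted(scored):
        lag = w - w0
        common = base.index.intersection(scored[w].index)
        if len(common) < 3:
            logger.warning("lag %d: only %d common users with window 0; omitted", lag, len(common))
            continue
        a = base.loc[common].to_numpy()
        b = scored[w].loc[common].to_numpy()
        for j in range(model.k):
            if lag == 0:
                r = 1.0
            else:
                r = float(np.corrcoef(a[:, j], b[:, j])[0, 1])
            rows.append({"factor": j, "lag": lag, "r": r, "n_users": len(common)})
    return StabilityReport(retest=pd.DataFrame(rows))


def dropout_reliability(
    train_matrix: UserTermMatrix,
    test_matrix: UserTermMatrix,
    model_config: FactorModelConfig,
    drop_fraction: float = 0.2,
    n_runs: int = 100,
    seed: int = 0,
) -> StabilityReport:
    """Stability of factors under resampling of the training population.

    Each run refits the model on the training matrix with ``drop_fraction``
    of its users removed at random (columns re-standardized on the retained
    rows) and scores the fixed held-out users. Every unordered pair of runs
    is aligned with the Hungarian matching and the mean matched |r| over
    pairs is reported alongside the full pair distribution.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must lie in (0,1)")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if set(train_matrix.row_users) & set(test_matrix.row_users):
        raise ValueError("train and test user sets must be disjoint")
    rng = np.random.default_rng(seed)
    n = len(train_matrix.row_users)
    n_drop = int(round(drop_fraction * n))
    run_scores: list[FactorScores] = []
    for _ in range(n_runs):
        dropped = rng.choice(n, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(n), dropped)
        sub = train_matrix.subset(keep, restandardize=True)
        model, _ = fit_pipeline(sub, model_config)
        run_scores.append(score_users(model, test_matrix))
    rows = []
    for i, j in itertools.combinations(range(n_runs), 2):
        al = align_factors(run_scores[i], run_scores[j])
        rows.append({"run_i": i, "run_j": j, "mean_abs_corr": al.mean_abs_corr})
    return StabilityReport(
        dropout_pairs=pd.DataFrame(rows), n_runs=n_runs, drop_fraction=drop_fraction
    )


def save_stability(report: StabilityReport, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.retest is not None:
        report.retest.to_csv(out / "retest.csv", index=False)
    if report.dropout_pairs is not None:
        report.dropout_pairs.to_csv(out / "dropout_pairs.csv", index=False)
        (out / "dropout_summary.txt").write_text(
            f"mean_abs_corr={report.dropout_mean:.6f} "
            f"n_runs={report.n_runs} drop_fraction={report.drop_fraction}\n"
        )
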
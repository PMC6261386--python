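"""Differential language analysis: mass-univariate word-score correlations.

Every vocabulary term is correlated (Pearson) with every factor's scores
across users; two-sided p-values come from the t distribution and are
corrected with Benjamini-Hochberg, by default within each factor's family
of V tests. Terms are tagged with corpus-frequency terciles (low / moderate
/ frequent) — the three-colour encoding conventionally used when the top
correlates are drawn as word clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import UserTermMatrix
from .factor_model import FactorScores

FREQ_TIERS = ("low", "moderate", "frequent")


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags.

    q_(i) = min_{j>=i} p_(j) m / j, clipped at 1, mapped back to the input
    order; a test is significant when q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def _pearson_columns(x: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-by-column Pearson r between x (n x V) and f (n x k).

    Returns (r, degenerate) where degenerate marks constant x columns
    (r set to 0 there).
    """
    xc = x - x.mean(axis=0)
    fc = f - f.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    fn = np.linalg.norm(fc, axis=0)
    # relative threshold: constant columns up to float rounding are degenerate
    scale = np.abs(x).max(axis=0) + np.finfo(float).tiny
    degenerate = xn <= 1e-10 * np.sqrt(x.shape[0]) * scale
    xn_safe = np.where(degenerate, 1.0, xn)
    r = (xc.T @ fc) / np.outer(xn_safe, fn)
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


def _pvals_from_r(r: np.ndarray, n: int) -> np.ndarray:
    rr = np.clip(np.abs(r), 0, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(t, df=n - 2)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def correlate_words(
    M: UserTermMatrix,
    scores: FactorScores,
    alpha: float = 0.05,
    family: str = "per_factor",
) -> pd.DataFrame:
    """Correlate every term's relative frequency with every factor score.

    Returns one row per (term, factor) with r, p, BH q, frequency tier and
    a significance flag. Constant term columns are emitted with r = 0 and
    ``degenerate = True`` and are excluded from the FDR family. ``family``
    is "per_factor" (default) or "global".
    """
    if list(M.row_users) != list(scores.row_users):
        raise ValueError("row users of matrix and scores are not aligned")
    if family not in ("per_factor", "global"):
        raise ValueError(f"unknown FDR family {family!r}")
    x = np.asarray(M.rel_freq.todense(), dtype=float)
    n, v = x.shape
    k = scores.k
    r, degenerate = _pearson_columns(x, scores.scores)
    p = _pvals_from_r(r, n)

    freq = M.term_frequencies()
    lo, hi = np.quantile(freq, [1 / 3, 2 / 3])
    tier = np.where(freq <= lo, "low", np.where(freq <= hi, "moderate", "frequent"))

    rows = []
    q = np.full((v, k), np.nan)
    sig = np.zeros((v, k), dtype=bool)
    ok = ~degenerate
    if family == "per_factor":
        for j in range(k):
            if ok.any():
                q[ok, j], sig[ok, j] = bh_fdr(p[ok, j], alpha)
    else:
        if ok.any():
            qf, sf = bh_fdr(p[ok].ravel(), alpha)
            q[ok] = qf.reshape(-1, k)
            sig[ok] = sf.reshape(-1, k)
    for j in range(k):
        for i in range(v):
            rows.append(
                (
                    M.vocabulary.terms[i], j, r[i, j],
                    p[i, j] if ok[i] else np.nan,
                    q[i, j], tier[i],
                    bool(sig[i, j]), bool(degenerate[i]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["term", "factor", "r", "p", "q", "freq_tier", "significant", "degenerate"],
    )


@dataclass
class TableCorrelation:
    """Factor x outcome-column Pearson correlations with p and BH q."""

    r: pd.DataFrame  # factors x columns
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame  # pairwise user counts

    @property
    def tidy(self) -> pd.DataFrame:
        out = (
            self.r.stack().rename("r").to_frame()
            .join(self.p.stack().rename("p"))
            .join(self.q.stack().rename("q"))
            .join(self.n.stack().rename("n"))
            .reset_index(names=["factor", "column"])
        )
        return out


def correlate_scores_with_table(
    scores: FactorScores, table: pd.DataFrame, alpha: float = 0.05
) -> TableCorrelation:
    """Correlate each factor with each numeric outcome column.

    Users are matched by id (inner join); missing outcome values are dropped
    pairwise. BH correction is applied across the whole factor x column
    family. Raises if fewer than 3 users overlap.
    """
    sf = scores.to_frame()
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    joined = sf.join(table[cols], how="inner")
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} overlapping users (need >= 3)")
    factors = list(sf.columns)
    r = pd.DataFrame(index=factors, columns=cols, dtype=float)
    p = pd.DataFrame(index=factors, columns=cols, dtype=float)
    n = pd.DataFrame(index=factors, columns=cols, dtype=float)
    for c in cols:
        y = joined[c]
        mask = y.notna()
        for f in factors:
            xv = joined.loc[mask, f].to_numpy(dtype=float)
            yv = y[mask].to_numpy(dtype=float)
            n.loc[f, c] = len(xv)
            if len(xv) < 3 or np.std(xv) == 0 or np.std(yv) == 0:
                r.loc[f, c] = 0.0
                p.loc[f, c] = 1.0
                continue
            rr, pp = stats.pearsonr(xv, yv)
            r.loc[f, c] = rr
            p.loc[f, c] = max(pp, np.finfo(float).tiny)
    qflat, _ = bh_fdr(p.to_numpy().ravel(), alpha)
    q = pd.DataFrame(qflat.reshape(p.shape), index=factors, columns=cols)
    return TableCorrelation(r=r, p=p, q=q, n=n)


def top_words(
    dla: pd.DataFrame, factor: int, n: int, direction: str = "positive"
) -> pd.DataFrame:
    """Top significant correlates of one factor, for word-cloud export.

    Sorted by r (descending for "positive", ascending for "negative") with
    deterministic lexicographic tie-break on the term.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    factors = dla["factor"].unique()
    if factor not in factors:
        raise ValueError(f"factor {factor} out of range (have {sorted(factors)})")
    sub = dla[(dla["factor"] == factor) & dla["significant"] & ~dla["degenerate"]]
    ascending = direction == "negative"
    sub = sub.sort_values(["r", "term"], ascending=[ascending, True])
    return sub.head(n)[["term", "r", "freq_tier"]].reset_index(drop=True)
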
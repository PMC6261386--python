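"""Latent factor model over the user-term matrix.

The model is the classical common-factor decomposition M = F L' + E with
heteroscedastic residuals: the observed (standardized) word-frequency
columns are linear in a small number of latent per-user factors. Estimation
is Gaussian maximum likelihood on the correlation scale; a truncated-SVD
estimator is provided as the isotropic-noise special case. Fitted loadings
can be rotated orthogonally (varimax/equamax) or obliquely (promax after an
orthogonal pre-rotation), and held-out users are scored with Thurstone
regression weights derived from the fitted model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis
from sklearn.exceptions import ConvergenceWarning

from .corpus import UserTermMatrix, Vocabulary, apply_standardization

logger = logging.getLogger(__name__)

ROTATIONS = ("varimax", "equamax", "promax")


@dataclass
class FactorModel:
    """Fitted loadings, residual variances, factor correlations and the
    standardization needed to score new users."""

    loadings: np.ndarray  # (V, k) pattern matrix
    psi: np.ndarray  # (V,) residual variances (0 for the SVD estimator)
    phi: np.ndarray  # (k, k) factor correlation matrix
    vocabulary: Vocabulary
    column_means: np.ndarray
    column_sds: np.ndarray
    transform: str
    method: str = "ml_fa"
    rotation: str = "none"
    n_obs: int = 0

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def fitted_covariance(self) -> np.ndarray:
        """Model-implied covariance L Phi L' + diag(psi); invariant under
        rotation."""
        return self.loadings @ self.phi @ self.loadings.T + np.diag(self.psi)

    def communalities(self) -> np.ndarray:
        return np.diag(self.loadings @ self.phi @ self.loadings.T)

    def scoring_weights(self) -> np.ndarray:
        """Thurstone regression-score weights W with F = M_std W.

        W = Sigma^{-1} L Phi, where L Phi is the structure matrix and Sigma
        the model-implied covariance of the standardized variables. For the
        SVD estimator Sigma is singular and the pseudo-inverse is used,
        which reduces to least-squares projection on the loading columns.
        """
        structure = self.loadings @ self.phi
        sigma = self.fitted_covariance()
        if np.all(self.psi > 0):
            return np.linalg.solve(sigma, structure)
        return np.linalg.pinv(sigma, rcond=1e-10) @ structure


@dataclass
class FactorScores:
    row_users: list[str]
    scores: np.ndarray  # (n_users, k)
    model_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite factor scores")
        if len(self.row_users) != self.scores.shape[0]:
            raise ValueError("row_users / scores length mismatch")

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.scores, index=pd.Index(self.row_users, name="user_id"),
                            columns=cols)


@dataclass
class FactorModelConfig:
    """End-to-end model settings: estimator, rotation and vocabulary size.

    k defaults to 5 (the headline trait count, chosen for parity with the
    five-factor questionnaire model); 3, 10 and 30 are the documented
    comparison presets.
    """

    k: int = 5
    method: str = "ml_fa"
    rotation: str = "promax"
    promax_power: int = 4
    initial_orthogonal: str = "equamax"
    tol: float = 1e-6
    max_iter: int = 2000
    vocab_top_k: int = 10000
    transform: str = "relfreq"
    seed: int = 0


def _fix_column_signs(loadings: np.ndarray) -> np.ndarray:
    """Resolve sign indeterminacy: largest-|loading| entry positive per column."""
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit_factor_analysis(
    M: UserTermMatrix,
    k: int,
    method: str = "ml_fa",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[FactorModel, FactorScores]:
    """Fit the unrotated k-factor model on the standardized matrix.

    ``ml_fa`` maximizes the Gaussian factor-model likelihood with
    heteroscedastic residual variances (deterministic SVD-based updates;
    convergence when the per-sample log-likelihood change drops below
    ``tol``). ``svd`` returns the rank-k truncated decomposition — the
    isotropic-noise special case — with psi recorded as zero. Both return
    unrotated loadings with Phi = identity.
    """
    x = M.standardized
    n, v = x.shape
    if not 1 <= k < min(n, v):
        raise ValueError(f"k={k} out of range for matrix of shape {x.shape}")
    if method == "ml_fa":
        fa = FactorAnalysis(
            n_components=k, tol=tol, max_iter=max_iter, svd_method="lapack",
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=ConvergenceWarning)
            try:
                fa.fit(x)
            except ConvergenceWarning as err:
                raise RuntimeError(
                    f"ml_fa did not converge within max_iter={max_iter} iterations"
                ) from err
        loadings = fa.components_.T.copy()
        psi = fa.noise_variance_.copy()
    elif method == "svd":
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        loadings = vt[:k].T * (s[:k] / np.sqrt(n))
        psi = np.zeros(v)
    else:
        raise ValueError(f"unknown method {method!r}")
    loadings = loadings * _fix_column_signs(loadings)
    model = FactorModel(
        loadings=loadings,
        psi=psi,
        phi=np.eye(k),
        vocabulary=M.vocabulary,
        column_means=M.column_means.copy(),
        column_sds=M.column_sds.copy(),
        transform=M.transform,
        method=method,
        rotation="none",
        n_obs=n,
    )
    scores = FactorScores(list(M.row_users), x @ model.scoring_weights())
    return model, scores


def _orthomax(loadings: np.ndarray, gamma: float, max_sweeps: int = 200,
              tol: float = 1e-10) -> np.ndarray:
    """Orthomax rotation matrix (gamma=1: varimax, gamma=k/2: equamax).

    Pairwise planar rotations with the closed-form criterion-maximizing
    angle per column pair, swept until no pair moves. The pairwise update
    is exact, so the iteration cannot stall on symmetric loading patterns.
    """
    p, k = loadings.shape
    rot = np.eye(k)
    if k == 1:
        return rot
    lam = loadings.copy()
    for _ in range(max_sweeps):
        biggest = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = lam[:, i], lam[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                a, b = u.sum(), v.sum()
                num = (2 * u @ v) - gamma * 2 * a * b / p
                den = (u @ u - v @ v) - gamma * (a**2 - b**2) / p
                theta = 0.25 * np.arctan2(num, den)
                if abs(theta) < tol:
                    continue
                biggest = max(biggest, abs(theta))
                cs, sn = np.cos(theta), np.sin(theta)
                g = np.array([[cs, -sn], [sn, cs]])
                lam[:, [i, j]] = lam[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
        if biggest < tol:
            break
    return rot


def rotate(
    model: FactorModel,
    method: str,
    promax_power: int = 4,
    initial_orthogonal: str = "equamax",
) -> FactorModel:
    """Rotate the loading matrix; the fitted covariance is unchanged.

    Orthogonal methods (varimax, equamax) return L R with R orthonormal and
    Phi = identity. ``promax`` first applies the configured orthogonal
    rotation, then regresses the rotated loadings onto their
    power-``promax_power`` simple-structure target, yielding oblique pattern
    loadings and the factor correlation matrix Phi.
    """
    if model.rotation == "promax":
        raise ValueError("model is already obliquely rotated")
    if method not in ROTATIONS:
        raise ValueError(f"unknown rotation {method!r}")
    if promax_power < 1:
        raise ValueError("promax_power must be >= 1")
    L = model.loadings
    k = model.k
    if method in ("varimax", "equamax"):
        gamma = 1.0 if method == "varimax" else k / 2.0
        rot = _orthomax(L, gamma)
        new_L = L @ rot
        new_L = new_L * _fix_column_signs(new_L)
        return replace(model, loadings=new_L, phi=np.eye(k), rotation=method)

    # promax: orthogonal pre-rotation, then oblique target rotation
    gamma = 1.0 if initial_orthogonal == "varimax" else k / 2.0
    lam = L @ _orthomax(L, gamma)
    target = lam * np.abs(lam) ** (promax_power - 1)
    u, *_ = np.linalg.lstsq(lam, target, rcond=None)
    # normalize so the implied factor correlation matrix has unit diagonal
    d = np.sqrt(np.diag(np.linalg.inv(u.T @ u)))
    u = u * d
    pattern = lam @ u
    phi = np.linalg.inv(u.T @ u)
    phi = (phi + phi.T) / 2
    dphi = np.sqrt(np.diag(phi))
    phi = phi / np.outer(dphi, dphi)
    signs = _fix_column_signs(pattern)
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return replace(model, loadings=pattern, phi=phi, rotation="promax")


def score_users(model: FactorModel, M_new: UserTermMatrix) -> FactorScores:
    """Score users of ``M_new`` with the model's regression weights.

    The new matrix must share the model's vocabulary; its relative
    frequencies are re-standardized with the model's stored column
    means/sds, so scoring the fitting matrix reproduces the fitted scores.
    """
    if M_new.vocabulary.terms != model.vocabulary.terms:
        missing = sorted(set(model.vocabulary.terms) - set(M_new.vocabulary.terms))
        raise ValueError(
            f"vocabulary mismatch; {len(missing)} model terms missing, e.g. {missing[:5]}"
        )
    x = apply_standardization(
        M_new.rel_freq, model.transform, model.column_means, model.column_sds
    )
    return FactorScores(list(M_new.row_users), x @ model.scoring_weights())


def fit_pipeline(M: UserTermMatrix, config: FactorModelConfig) -> tuple[FactorModel, FactorScores]:
    """Fit, rotate per config, and score the fitting users."""
    model, _ = fit_factor_analysis(
        M, config.k, method=config.method, seed=config.seed,
        tol=config.tol, max_iter=config.max_iter,
    )
    if config.rotation != "none":
        model = rotate(
            model, config.rotation, promax_power=config.promax_power,
            initial_orthogonal=config.initial_orthogonal,
        )
    scores = FactorScores(list(M.row_users), M.standardized @ model.scoring_weights())
    return model, scores


def scree_acceleration(eigenvalues, return_confidence: bool = False):
    """Acceleration rule on a descending eigenvalue spectrum.

    The discrete acceleration at (1-based) position i is
    a_i = (lambda_{i+1} - lambda_i) - (lambda_i - lambda_{i-1}) for
    i = 2..V-1; the suggested factor count is one less than the position of
    the maximum acceleration — the index just before the sharpest elbow.
    Ties break toward the smaller index; a flat spectrum (all a_i ~ 0)
    returns 1 and is flagged low-confidence.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 4:
        raise ValueError("need at least 4 eigenvalues for a scree test")
    accel = lam[2:] - 2 * lam[1:-1] + lam[:-2]  # positions 2..V-1, 1-based
    j = int(np.argmax(accel))
    confident = accel[j] > 1e-10
    if not confident:
        logger.warning("flat eigenvalue spectrum; scree suggestion is low-confidence")
    suggestion = j + 1  # (position j+2 in 1-based terms) - 1
    if return_confidence:
        return suggestion, bool(confident)
    return suggestion


def suggest_n_factors(M: UserTermMatrix, return_confidence: bool = False):
    """Scree acceleration criterion on the column-correlation spectrum."""
    x = M.standardized
    n, v = x.shape
    if v < 4:
        raise ValueError("need at least 4 observed variables for a scree test")
    corr = (x.T @ x) / n
    lam = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return scree_acceleration(lam, return_confidence=return_confidence)


# ---------------------------------------------------------------------------
# serialization: a directory of CSV matrices plus a JSON manifest
# ---------------------------------------------------------------------------

def save_model(model: FactorModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    terms = model.vocabulary.terms
    cols = [f"f{j + 1}" for j in range(model.k)]
    pd.DataFrame(model.loadings, index=terms, columns=cols).to_csv(
        out / "loadings.csv", index_label="term"
    )
    pd.DataFrame(model.phi, index=cols, columns=cols).to_csv(out / "phi.csv", index_label="factor")
    pd.DataFrame({"term": terms, "psi": model.psi}).to_csv(out / "psi.csv", index=False)
    pd.DataFrame(model.scoring_weights(), index=terms, columns=cols).to_csv(
        out / "weights.csv", index_label="term"
    )
    pd.DataFrame(
        {"term": terms, "mean": model.column_means, "sd": model.column_sds}
    ).to_csv(out / "standardization.csv", index=False)
    manifest = {
        "method": model.method,
        "rotation": model.rotation,
        "k": model.k,
        "transform": model.transform,
        "n_obs": model.n_obs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(in_dir: str | Path) -> FactorModel:
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    loadings_df = pd.read_csv(d / "loadings.csv", index_col="term")
    phi = pd.read_csv(d / "phi.csv", index_col="factor").to_numpy()
    psi = pd.read_csv(d / "psi.csv")["psi"].to_numpy()
    std = pd.read_csv(d / "standardization.csv")
    return FactorModel(
        loadings=loadings_df.to_numpy(),
        psi=psi,
        phi=phi,
        vocabulary=Vocabulary(terms=[str(t) for t in loadings_df.index]),
        column_means=std["mean"].to_numpy(),
        column_sds=std["sd"].to_numpy(),
        transform=manifest["transform"],
        method=manifest["method"],
        rotation=manifest["rotation"],
        n_obs=manifest["n_obs"],
    )


def save_scores(scores: FactorScores, path: str | Path) -> None:
    scores.to_frame().to_csv(path)


def load_scores(path: str | Path) -> FactorScores:
    df = pd.read_csv(path, index_col="user_id")
    return FactorScores([str(u) for u in df.index], df.to_numpy(dtype=float))
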
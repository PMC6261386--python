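"""Synthetic corpora with planted latent traits.

The generative model mirrors the structure of a large social-media study
population: each user carries k latent trait values drawn from a correlated
multivariate normal, traits evolve across 6-month windows as a stationary
AR(1) process, and word choice is multinomial with per-user probabilities

    p_u = softmax(baseline_logfreq + true_loadings @ trait_u),

so marker-word enrichment is monotone in the trait. Baseline frequencies are
Zipf-distributed; demographics (62.8% female, right-skewed ages with median
22 and mean 25.49) match the population the pipeline is designed for.
Outcomes are linear in traits and demographics plus Gaussian noise, and a
likes matrix has planted block structure driven by the traits. Because every
quantity downstream of the corpus has a known ground truth here, each
pipeline stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, log_softmax

from .corpus import MessageCorpus
from .evaluation import LikesMatrix

_BASE_DATE = pd.Timestamp("2014-01-01")
_INJECTED_STOPWORDS = ["the", "is", "and", "to", "a", "of", "in", "i", "it", "you"]
_MEAN_MESSAGE_LEN = 15


@dataclass
class WordCountSpec:
    """Log-normal words-per-user-per-window, truncated below at ``minimum``."""

    mean_log: float = 7.2  # median ~1340 words per window
    sd_log: float = 0.4
    minimum: int = 1000


@dataclass
class OutcomeSpec:
    """One outcome column: y = beta . [traits, age_z, gender] + noise.

    ``beta`` has length k + 2 (the last two entries weight standardized age
    and the 0/1 gender indicator). Binary outcomes threshold the latent
    continuous value at its median.
    """

    name: str
    beta: np.ndarray
    noise_var: float
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")


@dataclass
class LikesSpec:
    n_items: int = 400
    n_clusters: int = 8
    within_p: float = 0.3
    background_p: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.within_p, self.background_p):
            if not 0 <= p <= 1:
                raise ValueError("like probabilities must lie in [0,1]")
        if self.within_p < self.background_p:
            raise ValueError("within_p must be >= background_p")


def default_outcome_specs(k: int) -> list[OutcomeSpec]:
    """Outcome roster emulating the evaluation battery: log-income, IQ,
    life-satisfaction, depression, friend count and one binary target.

    Coefficients are assigned to factors cyclically so the roster is valid
    for any k; noise variances put theoretical R^2 in the 0.1-0.35 range
    typical of individual-difference outcomes.
    """

    def beta(pairs: dict[int, float], age: float = 0.0, gender: float = 0.0) -> np.ndarray:
        b = np.zeros(k + 2)
        for j, v in pairs.items():
            b[j % k] += v
        b[k] = age
        b[k + 1] = gender
        return b

    return [
        OutcomeSpec("log_income", beta({0: 0.45}, age=0.35), noise_var=0.8),
        OutcomeSpec("iq", beta({1: 0.55, 0: 0.15}), noise_var=0.7),
        OutcomeSpec("swl", beta({2: -0.4}, gender=0.2), noise_var=0.9),
        OutcomeSpec("depression", beta({2: 0.45, 1: -0.15}), noise_var=0.8),
        OutcomeSpec("friend_size", beta({0: 0.25, 2: 0.2}, age=-0.2), noise_var=1.0),
        OutcomeSpec("binary_flag", beta({1: 0.6}), noise_var=0.6, kind="binary"),
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-trait population and corpus."""

    n_users: int = 2000
    vocab_size: int = 500
    n_factors: int = 3
    markers_per_factor: int = 60
    loading_magnitude: float = 0.5
    factor_correlation: float = 0.2
    stability_rho: float = 0.85
    n_windows: int = 1
    words_per_user: WordCountSpec = field(default_factory=WordCountSpec)
    zipf_exponent: float = 1.0
    outcome_specs: list[OutcomeSpec] | None = None
    likes_specs: LikesSpec = field(default_factory=LikesSpec)
    female_fraction: float = 0.628
    age_params: tuple[float, float] = (22.0, 25.49)  # (median, mean) years
    stopword_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_specs is None:
            self.outcome_specs = default_outcome_specs(self.n_factors)
        self.validate()

    def validate(self) -> None:
        if min(self.n_users, self.vocab_size, self.n_factors, self.n_windows,
               self.markers_per_factor) < 1:
            raise ValueError("counts must be positive")
        if self.n_factors > self.vocab_size:
            raise ValueError("n_factors must be <= vocab_size")
        if self.markers_per_factor * self.n_factors > self.vocab_size:
            raise ValueError("markers_per_factor * n_factors must be <= vocab_size")
        if not 0 <= self.factor_correlation < 1:
            raise ValueError("factor_correlation must lie in [0,1)")
        if not 0 <= self.stability_rho <= 1:
            raise ValueError("stability_rho must lie in [0,1]")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0,1]")
        if not 0 <= self.stopword_rate < 1:
            raise ValueError("stopword_rate must lie in [0,1)")
        cov = self.trait_covariance()
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("trait covariance is not positive definite") from err

    def trait_covariance(self) -> np.ndarray:
        k, c = self.n_factors, self.factor_correlation
        return (1 - c) * np.eye(k) + c * np.ones((k, k))


@dataclass
class SyntheticPopulation:
    """Ground truth for recovery tests: traits, demographics, loadings."""

    config: SyntheticConfig
    user_ids: list[str]
    traits: np.ndarray  # (n_windows, n_users, k); window 0 is *the* trait
    demographics: pd.DataFrame  # index user_id; age, gender (1 = female)
    terms: list[str]
    baseline_logfreq: np.ndarray  # (V,), normalized log probabilities
    true_loadings: np.ndarray  # (V, k)
    marker_indices: dict[int, np.ndarray]
    outcome_truth: dict = field(default_factory=dict)
    likes_truth: dict = field(default_factory=dict)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent streams so each generator is a pure function of (config, seed)
    return np.random.default_rng([int(config.seed), stream])


def _age_sample(rng: np.random.Generator, n: int, median: float, mean: float) -> np.ndarray:
    # shifted log-normal: 13 + LogNormal(mu, sigma), matched to the printed
    # median and mean, clipped to [13, 65]
    shift = 13.0
    mu = np.log(median - shift)
    sigma = np.sqrt(2 * np.log((mean - shift) / (median - shift)))
    age = shift + rng.lognormal(mu, sigma, size=n)
    return np.clip(age, 13.0, 65.0)


def generate_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Draw traits, demographics, marker loadings and baseline frequencies.

    Window-0 traits are MVN(0, Phi) with Phi the configured equicorrelation
    matrix; later windows follow the stationary AR(1)
    ``t_w = rho t_{w-1} + sqrt(1-rho^2) e_w`` with e_w ~ MVN(0, Phi), so
    corr(window t, window 0) = rho^t per factor. Each factor receives
    ``markers_per_factor`` disjoint marker words with loading
    +/- loading_magnitude (signs split evenly); all other loadings are zero.
    """
    config.validate()
    rng = _rng(config, 0)
    n, k, v = config.n_users, config.n_factors, config.vocab_size
    chol = np.linalg.cholesky(config.trait_covariance())

    traits = np.empty((config.n_windows, n, k))
    traits[0] = rng.standard_normal((n, k)) @ chol.T
    rho = config.stability_rho
    innov_scale = np.sqrt(1 - rho**2)
    for w in range(1, config.n_windows):
        e = rng.standard_normal((n, k)) @ chol.T
        traits[w] = rho * traits[w - 1] + innov_scale * e

    user_ids = [f"u{i:06d}" for i in range(n)]
    gender = (rng.random(n) < config.female_fraction).astype(int)
    age = _age_sample(rng, n, *config.age_params)
    demographics = pd.DataFrame(
        {"age": age, "gender": gender, "country": "US", "language_ok": True},
        index=pd.Index(user_ids, name="user_id"),
    )

    terms = [f"w{j:05d}" for j in range(v)]
    ranks = np.arange(1, v + 1, dtype=float)
    baseline = -config.zipf_exponent * np.log(ranks)
    baseline = log_softmax(baseline)

    loadings = np.zeros((v, k))
    marker_pool = rng.choice(v, size=k * config.markers_per_factor, replace=False)
    marker_indices: dict[int, np.ndarray] = {}
    m = config.markers_per_factor
    for j in range(k):
        idx = np.sort(marker_pool[j * m : (j + 1) * m])
        signs = np.ones(m)
        signs[m // 2 :] = -1.0
        loadings[idx, j] = signs * config.loading_magnitude
        marker_indices[j] = idx

    return SyntheticPopulation(
        config=config,
        user_ids=user_ids,
        traits=traits,
        demographics=demographics,
        terms=terms,
        baseline_logfreq=baseline,
        true_loadings=loadings,
        marker_indices=marker_indices,
    )


def expected_word_probs(pop: SyntheticPopulation, trait: np.ndarray) -> np.ndarray:
    """Closed-form word distribution for a given trait vector."""
    logits = pop.baseline_logfreq + pop.true_loadings @ np.asarray(trait, dtype=float)
    return np.exp(log_softmax(logits))


def generate_messages(pop: SyntheticPopulation, config: SyntheticConfig) -> MessageCorpus:
    """Emit the message corpus: i.i.d. word draws per (user, window),
    partitioned into messages with timestamps inside the window.

    Per user and window the content-word total is log-normal truncated below
    at the configured minimum; common stopwords are interleaved at
    ``stopword_rate`` so the corpus exercises stopword removal without
    touching in-vocabulary relative frequencies. Deterministic given seed.
    """
    if not pop.user_ids:
        raise ValueError("empty population")
    rng = _rng(config, 1)
    wps = config.words_per_user
    n, v = len(pop.user_ids), len(pop.terms)
    terms = np.asarray(pop.terms, dtype=object)
    stop = np.asarray(_INJECTED_STOPWORDS, dtype=object)

    users_col: list[str] = []
    ts_col: list[np.ndarray] = []
    texts: list[str] = []
    word_totals: list[tuple[str, int, int]] = []
    window_secs = []
    for w in range(config.n_windows):
        start = _BASE_DATE + pd.DateOffset(months=6 * w)
        end = _BASE_DATE + pd.DateOffset(months=6 * (w + 1))
        window_secs.append((start, int((end - start).total_seconds())))

    for w in range(config.n_windows):
        start, dur = window_secs[w]
        n_words = np.maximum(
            rng.lognormal(wps.mean_log, wps.sd_log, size=n).astype(int), wps.minimum
        )
        for u in range(n):
            p = expected_word_probs(pop, pop.traits[w, u])
            counts = rng.multinomial(n_words[u], p)
            seq = np.repeat(np.arange(v), counts)
            words = terms[rng.permutation(seq)]
            if config.stopword_rate > 0:
                n_stop = int(round(config.stopword_rate / (1 - config.stopword_rate) * len(words)))
                if n_stop:
                    merged = np.concatenate([words, stop[rng.integers(0, len(stop), n_stop)]])
                    words = merged[rng.permutation(len(merged))]
            # partition into messages of random length
            n_msgs = max(1, len(words) // _MEAN_MESSAGE_LEN)
            cuts = np.sort(rng.choice(np.arange(1, len(words)), size=n_msgs - 1, replace=False)) \
                if n_msgs > 1 else np.array([], dtype=int)
            offsets = np.sort(rng.integers(0, dur, size=n_msgs))
            if w == 0 and u == 0:
                offsets[0] = 0  # pin the corpus start to the window anchor
            pieces = np.split(words, cuts)
            stamps = start + pd.to_timedelta(offsets, unit="s")
            users_col.extend([pop.user_ids[u]] * n_msgs)
            ts_col.append(stamps.to_numpy())
            texts.extend(" ".join(piece) for piece in pieces)
            word_totals.append((pop.user_ids[u], w, int(n_words[u])))

    rec = pd.DataFrame(
        {
            "user_id": users_col,
            "timestamp": np.concatenate(ts_col),
            "text": texts,
        }
    )
    meta = pop.demographics.copy()
    totals = pd.DataFrame(word_totals, columns=["user_id", "window", "n_content_words"])
    return MessageCorpus(rec, meta, attrs={"generator_word_totals": totals})


@dataclass
class OutcomeTable:
    """Per-user outcomes plus the generating truth (betas, theoretical R^2)."""

    table: pd.DataFrame  # index user_id
    truth: dict[str, dict]


def generate_outcomes(pop: SyntheticPopulation, config: SyntheticConfig) -> OutcomeTable:
    """Outcomes linear in window-0 traits and demographics plus noise.

    The theoretical R^2 of each continuous outcome (signal variance over
    total variance under the generating covariance) is stored alongside so
    predictive-validity results can be compared to an oracle.
    """
    if not config.outcome_specs:
        raise ValueError("outcome_specs is empty")
    rng = _rng(config, 2)
    k = config.n_factors
    t0 = pop.traits[0]
    age = pop.demographics["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std()
    gender = pop.demographics["gender"].to_numpy(dtype=float)
    x = np.column_stack([t0, age_z, gender])
    phi = config.trait_covariance()
    f = gender.mean()
    cov_x = np.zeros((k + 2, k + 2))
    cov_x[:k, :k] = phi
    cov_x[k, k] = 1.0
    cov_x[k + 1, k + 1] = f * (1 - f)

    data: dict[str, np.ndarray] = {}
    truth: dict[str, dict] = {}
    for spec in config.outcome_specs:
        if spec.beta.shape != (k + 2,):
            raise ValueError(
                f"outcome {spec.name!r}: beta length {spec.beta.size} != k+2 = {k + 2}"
            )
        latent = x @ spec.beta + rng.normal(0, np.sqrt(spec.noise_var), size=len(t0))
        signal_var = float(spec.beta @ cov_x @ spec.beta)
        r2 = signal_var / (signal_var + spec.noise_var) if signal_var + spec.noise_var > 0 else 0.0
        if spec.kind == "binary":
            data[spec.name] = (latent > np.median(latent)).astype(int)
        else:
            data[spec.name] = latent
        truth[spec.name] = {
            "beta": spec.beta.copy(),
            "noise_var": spec.noise_var,
            "kind": spec.kind,
            "theoretical_r2": r2,
        }
    table = pd.DataFrame(data, index=pd.Index(pop.user_ids, name="user_id"))
    table["age"] = age
    table["gender"] = gender.astype(int)
    pop.outcome_truth = truth
    return OutcomeTable(table=table, truth=truth)


def generate_likes(pop: SyntheticPopulation, config: SyntheticConfig) -> LikesMatrix:
    """Block-structured binary user-item matrix driven by the traits.

    Items are partitioned into ``n_clusters`` equal blocks. Each user's
    cluster propensities are logistic functions of the traits; the user's own
    cluster (the argmax propensity) receives likes with ``within_p``, all
    other items with ``background_p``.
    """
    ls = config.likes_specs
    rng = _rng(config, 3)
    n = len(pop.user_ids)
    item_cluster = np.repeat(
        np.arange(ls.n_clusters), int(np.ceil(ls.n_items / ls.n_clusters))
    )[: ls.n_items]
    # cluster direction vectors over the k traits
    w = rng.standard_normal((ls.n_clusters, config.n_factors))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    propensity = expit(pop.traits[0] @ w.T)  # (n_users, n_clusters)
    user_cluster = propensity.argmax(axis=1)

    probs = np.where(
        item_cluster[None, :] == user_cluster[:, None], ls.within_p, ls.background_p
    )
    likes = (rng.random((n, ls.n_items)) < probs).astype(np.int8)
    matrix = sp.csr_matrix(likes)
    item_ids = [f"like{j:05d}" for j in range(ls.n_items)]
    pop.likes_truth = {
        "item_cluster": item_cluster,
        "user_cluster": user_cluster,
        "propensity": propensity,
    }
    return LikesMatrix(matrix=matrix, user_ids=list(pop.user_ids), item_ids=item_ids)


def generate_all(config: SyntheticConfig):
    """Convenience: population, corpus, outcomes and likes in one call."""
    pop = generate_population(config)
    corpus = generate_messages(pop, config)
    outcomes = generate_outcomes(pop, config)
    likes = generate_likes(pop, config)
    return pop, corpus, outcomes, likes
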
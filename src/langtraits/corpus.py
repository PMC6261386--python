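"""Turn raw message streams into a filtered, windowed user-term matrix.

The central object is :class:`UserTermMatrix`: one row per user, one column
per vocabulary term, holding raw counts, per-user relative frequencies and
column-standardized values. The standardized matrix is the observed-variable
matrix that the latent factor model decomposes into common factors plus
residual noise; the stored column means/sds let held-out users be projected
onto a fitted model without refitting.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

# Emoticons are kept intact; everything else is lowercased word characters
# with word-internal apostrophes preserved ("didn't" stays one token).
_EMOTICON = r"(?:<3|</3|[<>]?[:;=8][\-o\*']?[\)\(\[\]dpo/\\\|\}\{@3])"
_WORD = r"[a-z0-9_]+(?:'[a-z0-9]+)*"
_TOKEN_RE = re.compile(f"{_EMOTICON}|{_WORD}")


def tokenize(text: str) -> list[str]:
    """Lowercase and split ``text`` into word and emoticon tokens.

    Total on strings: empty or punctuation-only input yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def default_stopwords() -> list[str]:
    """Packaged English stopword list (overridable in build_vocabulary)."""
    ref = resources.files("langtraits").joinpath("data/stopwords_en.txt")
    return [w for w in ref.read_text().split() if w]


@dataclass
class MessageCorpus:
    """Message records plus optional per-user metadata.

    ``records`` columns: user_id (str), timestamp (datetime64), text (str).
    ``user_meta`` is indexed by user_id and may carry age, gender, country,
    language_ok. ``attrs`` holds bookkeeping (filter reports, generator
    ground-truth word totals) that travels with the corpus.
    """

    records: pd.DataFrame
    user_meta: pd.DataFrame | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"user_id", "timestamp", "text"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if len(self.records) and self.records["user_id"].astype(str).eq("").any():
            raise ValueError("empty user_id in records")

    @property
    def n_users(self) -> int:
        return self.records["user_id"].nunique()

    @property
    def n_messages(self) -> int:
        return len(self.records)

    def user_ids(self) -> list[str]:
        return sorted(self.records["user_id"].unique())

    def token_counts(self) -> pd.Series:
        """Total token count per user (all tokens, stopwords included)."""
        n_tokens = self.records["text"].map(lambda t: len(tokenize(t)))
        return n_tokens.groupby(self.records["user_id"]).sum()


@dataclass
class Vocabulary:
    """Ordered term list with a term -> column-index map."""

    terms: list[str]
    stopwords_removed: list[str] = field(default_factory=list)
    term_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        self.term_index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class UserTermMatrix:
    """Users x vocabulary matrix of counts / relative frequencies / z-scores.

    ``standardized`` columns are z-scored with ``column_means``/``column_sds``
    computed on this (fitting) set; applying the same statistics to new users
    is how held-out scoring stays on the training scale.
    """

    row_users: list[str]
    vocabulary: Vocabulary
    raw_counts: sp.csr_matrix
    rel_freq: sp.csr_matrix
    standardized: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    transform: str = "relfreq"

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw_counts.shape

    def subset(self, row_indices: np.ndarray, restandardize: bool = True) -> "UserTermMatrix":
        """Row subset; by default column statistics are recomputed on it."""
        row_indices = np.asarray(row_indices)
        counts = self.raw_counts[row_indices]
        rel = self.rel_freq[row_indices]
        users = [self.row_users[i] for i in row_indices]
        if restandardize:
            x = _transformed(rel, self.transform)
            std, means, sds = _zscore_columns(x)
        else:
            means, sds = self.column_means, self.column_sds
            std = self.standardized[row_indices]
        return UserTermMatrix(users, self.vocabulary, counts, rel, std, means, sds, self.transform)

    def term_frequencies(self) -> np.ndarray:
        """Total corpus count per term (the word-frequency tiers use this)."""
        return np.asarray(self.raw_counts.sum(axis=0)).ravel()


def filter_users(
    corpus: MessageCorpus,
    min_words: int = 1000,
    max_age: float | None = 65,
    require_country: str | None = "US",
) -> MessageCorpus:
    """Drop users below ``min_words`` total tokens, above ``max_age``, or
    outside ``require_country``.

    Age/country filters are applied only when the metadata column exists
    (pass None to skip explicitly). The retained set is the intersection of
    all active filters, so filter order cannot matter. Per-criterion drop
    counts are reported in ``attrs['filter_report']``.
    """
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    users = pd.Index(corpus.records["user_id"].unique())
    report: dict[str, int] = {}

    counts = corpus.token_counts().reindex(users, fill_value=0)
    ok = counts >= min_words
    report["dropped_min_words"] = int((~ok).sum())
    keep = users[ok]

    meta = corpus.user_meta
    if meta is not None:
        if max_age is not None and "age" in meta.columns:
            age = meta["age"].reindex(users)
            bad = users[age > max_age]
            report["dropped_max_age"] = len(bad)
            keep = keep.difference(bad)
        if require_country is not None and "country" in meta.columns:
            country = meta["country"].reindex(users)
            bad = users[country.notna() & (country != require_country)]
            report["dropped_country"] = len(bad)
            keep = keep.difference(bad)

    keep_set = set(keep)
    rec = corpus.records[corpus.records["user_id"].isin(keep_set)].reset_index(drop=True)
    new_meta = meta.loc[meta.index.isin(keep_set)] if meta is not None else None
    report["retained_users"] = len(keep_set)
    attrs = dict(corpus.attrs)
    attrs["filter_report"] = report
    logger.info("filter_users: %s", report)
    return MessageCorpus(rec, new_meta, attrs)


def build_vocabulary(
    corpus: MessageCorpus,
    top_k: int,
    stopword_list: list[str] | None = None,
) -> Vocabulary:
    """Top ``top_k`` non-stopword terms by total corpus frequency.

    Ties are broken lexicographically so the result is deterministic under
    any record ordering.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    stop = set(default_stopwords() if stopword_list is None else stopword_list)
    counts: Counter[str] = Counter()
    for text in corpus.records["text"]:
        counts.update(tokenize(text))
    removed = sorted(stop & counts.keys())
    for w in removed:
        del counts[w]
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) < top_k:
        logger.warning(
            "only %d distinct non-stopword terms (< top_k=%d); keeping all",
            len(ordered), top_k,
        )
    terms = [t for t, _ in ordered[:top_k]]
    return Vocabulary(terms=terms, stopwords_removed=removed)


def _transformed(rel: sp.csr_matrix, transform: str) -> sp.csr_matrix:
    if transform == "relfreq":
        return rel
    if transform == "relfreq_sqrt":
        return rel.sqrt()
    raise ValueError(f"unknown transform {transform!r}")


def _zscore_columns(x: sp.spmatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dense = np.asarray(x.todense(), dtype=float)
    means = dense.mean(axis=0)
    sds = dense.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)  # constant columns map to all-zero
    return (dense - means) / sds, means, sds


def apply_standardization(
    rel: sp.csr_matrix, transform: str, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Project relative frequencies onto a previously fitted column scale."""
    dense = np.asarray(_transformed(rel, transform).todense(), dtype=float)
    return (dense - means) / sds


def build_user_term_matrix(
    corpus: MessageCorpus,
    vocab: Vocabulary,
    transform: str = "relfreq",
) -> UserTermMatrix:
    """Accumulate per-user term counts and derive relative frequencies and
    column z-scores.

    Users with zero in-vocabulary tokens are dropped with a warning. Rows of
    ``rel_freq`` sum to one over the retained vocabulary, so the matrix is
    invariant to how a user's words were split across messages.
    """
    index = vocab.term_index
    user_order: list[str] = []
    user_pos: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    per_user: dict[int, Counter] = {}
    for uid, text in zip(corpus.records["user_id"], corpus.records["text"]):
        pos = user_pos.get(uid)
        if pos is None:
            pos = user_pos[uid] = len(user_order)
            user_order.append(uid)
            per_user[pos] = Counter()
        c = per_user[pos]
        for tok in tokenize(text):
            j = index.get(tok)
            if j is not None:
                c[j] += 1
    # deterministic row order regardless of record order
    order = np.argsort(user_order)
    kept_users: list[str] = []
    for pos in order:
        uid = user_order[pos]
        if not per_user[pos]:
            logger.warning("user %s has no in-vocabulary tokens; dropped", uid)
            continue
        r = len(kept_users)
        kept_users.append(uid)
        for j, v in per_user[pos].items():
            rows.append(r)
            cols.append(j)
            vals.append(v)
    if not kept_users:
        raise ValueError("no users with in-vocabulary tokens")
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept_users), len(vocab)), dtype=np.int64
    )
    totals = np.asarray(counts.sum(axis=1)).ravel()
    rel = sp.csr_matrix(counts.multiply(1.0 / totals[:, None]))
    std, means, sds = _zscore_columns(_transformed(rel, transform))
    return UserTermMatrix(kept_users, vocab, counts, rel, std, means, sds, transform)


def window_corpus(
    corpus: MessageCorpus,
    window_months: int = 6,
    min_words_per_window: int = 1000,
) -> list[tuple[int, MessageCorpus]]:
    """Split messages into consecutive calendar windows of ``window_months``.

    Windows are half-open intervals anchored at the earliest timestamp: a
    message exactly on a boundary belongs to the later window. Within each
    window, users below ``min_words_per_window`` tokens are dropped for that
    window only. Empty windows are omitted from the result.
    """
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    ts = pd.to_datetime(corpus.records["timestamp"])
    if ts.isna().any():
        raise ValueError("unparseable timestamps present")
    anchor = ts.min()
    span_months = (ts.max().year - anchor.year) * 12 + (ts.max().month - anchor.month)
    n_bounds = span_months // window_months + 2
    bounds = pd.DatetimeIndex(
        [anchor + pd.DateOffset(months=window_months * i) for i in range(n_bounds + 1)]
    )
    idx = bounds.searchsorted(ts, side="right") - 1
    out: list[tuple[int, MessageCorpus]] = []
    for w in sorted(np.unique(idx)):
        rec = corpus.records[idx == w].reset_index(drop=True)
        sub = MessageCorpus(rec, corpus.user_meta, dict(corpus.attrs))
        counts = sub.token_counts()
        keep = set(counts[counts >= min_words_per_window].index)
        if not keep:
            continue
        rec = rec[rec["user_id"].isin(keep)].reset_index(drop=True)
        out.append((int(w), MessageCorpus(rec, corpus.user_meta, dict(corpus.attrs))))
    return out


# ---------------------------------------------------------------------------
# on-disk formats: line-delimited message records, CSV sidecars
# ---------------------------------------------------------------------------

def write_corpus(corpus: MessageCorpus, path: str | Path, meta_path: str | Path | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for row in corpus.records.itertuples(index=False):
            rec = {
                "user_id": row.user_id,
                "timestamp": pd.Timestamp(row.timestamp).isoformat(),
                "text": row.text,
            }
            fh.write(json.dumps(rec) + "\n")
    if meta_path is not None and corpus.user_meta is not None:
        corpus.user_meta.to_csv(meta_path, index_label="user_id")


def read_corpus(path: str | Path, meta_path: str | Path | None = None) -> MessageCorpus:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    rec = pd.DataFrame(rows, columns=["user_id", "timestamp", "text"])
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col="user_id")
        meta.index = meta.index.astype(str)
    return MessageCorpus(rec, meta)


def save_matrix(utm: UserTermMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = utm.raw_counts.tocoo()
    pd.DataFrame({"row": coo.row, "col": coo.col, "count": coo.data}).to_csv(
        out / "counts.csv", index=False
    )
    pd.Series(utm.row_users, name="user_id").to_csv(out / "users.csv", index=False)
    pd.Series(utm.vocabulary.terms, name="term").to_csv(out / "vocabulary.csv", index=False)
    pd.DataFrame(
        {"term": utm.vocabulary.terms, "mean": utm.column_means, "sd": utm.column_sds}
    ).to_csv(out / "standardization.csv", index=False)
    (out / "manifest.json").write_text(json.dumps({"transform": utm.transform}))


def load_matrix(in_dir: str | Path) -> UserTermMatrix:
    d = Path(in_dir)
    users = pd.read_csv(d / "users.csv")["user_id"].astype(str).tolist()
    terms = pd.read_csv(d / "vocabulary.csv")["term"].astype(str).tolist()
    vocab = Vocabulary(terms=terms)
    tri = pd.read_csv(d / "counts.csv")
    counts = sp.csr_matrix(
        (tri["count"], (tri["row"], tri["col"])), shape=(len(users), len(terms)), dtype=np.int64
    )
    manifest = json.loads((d / "manifest.json").read_text())
    transform = manifest.get("transform", "relfreq")
    totals = np.asarray(counts.sum(axis=1)).ravel()
    rel = sp.csr_matrix(counts.multiply(1.0 / np.where(totals == 0, 1, totals)[:, None]))
    std_df = pd.read_csv(d / "standardization.csv")
    means = std_df["mean"].to_numpy()
    sds = std_df["sd"].to_numpy()
    std = apply_standardization(rel, transform, means, sds)
    return UserTermMatrix(users, vocab, counts, rel, std, means, sds, transform)
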
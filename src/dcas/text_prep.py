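"""Narrative text preparation: normalization, n-grams, and the pruned TF-IDF
document-term matrix.

The pipeline mirrors standard bag-of-words preparation for registry
narratives: lowercase, strip punctuation, drop stopwords, Porter-stem, emit
unigrams plus adjacent bigrams, count into a sparse document-term matrix,
weight by TF-IDF, and prune terms appearing in too few documents.

TF-IDF dialect (deliberately pinned, and narrower than scikit-learn's):

    weight(d, t) = count(d, t) / n_tokens(d) * log2(N / df(t))

where ``n_tokens(d)`` counts all tokens (unigrams and bigrams) of document
``d``, ``N`` is the number of documents and ``df(t)`` the number of documents
containing ``t``.  A term present in every document therefore has weight 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from ._porter import stem as porter_stem

__all__ = [
    "TokenMatrix",
    "load_stopwords",
    "normalize",
    "ngrams",
    "build_matrix",
    "tfidf",
    "prune_sparse",
    "prepare_corpus",
]

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


def load_stopwords() -> frozenset[str]:
    """Pinned English stopword snapshot shipped with the package."""
    text = (
        resources.files("dcas.data").joinpath("stopwords_en.txt").read_text("utf-8")
    )
    return frozenset(w for w in text.split() if w)


_DEFAULT_STOPWORDS = load_stopwords()


def normalize(
    text: str,
    stopwords: frozenset[str] | None = None,
    *,
    stem: bool = True,
) -> list[str]:
    """Normalize raw text to a token stream.

    Lowercase, replace punctuation by spaces (standalone numbers are kept:
    ages carry signal in these narratives), drop stopwords, then Porter-stem
    each remaining token.  Empty input yields an empty stream.

    Stemming is single-pass; pass ``stem=False`` to run only the idempotent
    part of the pipeline (lowercasing, punctuation and stopword removal).
    """
    if stopwords is None:
        stopwords = _DEFAULT_STOPWORDS
    tokens = [t for t in _TOKEN_RE.split(text.lower()) if t and t not in stopwords]
    if stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def ngrams(stream: Sequence[str]) -> list[str]:
    """All unigrams plus adjacent-pair bigrams, in document order.

    Bigrams join the post-stopword, post-stem sequence with a single space,
    so a k-token stream yields k unigrams and max(k - 1, 0) bigrams.
    """
    return list(stream) + [
        f"{a} {b}" for a, b in zip(stream, stream[1:])
    ]


@dataclass
class TokenMatrix:
    """Documents x tokens matrix with its vocabulary bookkeeping.

    ``matrix`` is scipy CSR; ``df`` holds per-token document frequencies
    computed on the corpus the vocabulary was built from (``n_documents``
    documents), which is the denominator corpus for TF-IDF even after row
    subsetting.
    """

    matrix: sp.csr_matrix
    doc_ids: list[str]
    tokens: list[str]
    df: np.ndarray
    n_documents: int
    weighting: str = "count"  # "count" | "tfidf"
    row_token_totals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.doc_ids) != self.matrix.shape[0]:
            raise ValueError("doc_ids length does not match matrix rows")
        if len(self.tokens) != self.matrix.shape[1]:
            raise ValueError("tokens length does not match matrix columns")
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError("duplicate document ids")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens")

    @property
    def token_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.tokens)}

    def rows(self, doc_ids: Iterable[str]) -> "TokenMatrix":
        """Row subset (e.g. the labeled documents), vocabulary unchanged."""
        index = {d: i for i, d in enumerate(self.doc_ids)}
        wanted = list(doc_ids)
        missing = [d for d in wanted if d not in index]
        if missing:
            raise KeyError(f"unknown document ids: {missing[:5]}")
        sel = np.array([index[d] for d in wanted], dtype=int)
        totals = (
            None if self.row_token_totals is None else self.row_token_totals[sel]
        )
        return replace(
            self,
            matrix=self.matrix[sel],
            doc_ids=wanted,
            row_token_totals=totals,
        )


def build_matrix(
    token_lists: Sequence[Sequence[str]],
    doc_ids: Sequence[str] | None = None,
) -> TokenMatrix:
    """Count token occurrences into a sparse document-term matrix.

    ``token_lists`` are per-document token sequences (typically the output of
    :func:`ngrams`).  Document frequency of a token is the number of
    documents in which its count is > 0.
    """
    n_docs = len(token_lists)
    if n_docs == 0:
        raise ValueError("cannot build a document-term matrix from zero documents")
    if doc_ids is None:
        doc_ids = [f"d{i}" for i in range(n_docs)]

    vocab: dict[str, int] = {}
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for toks in token_lists:
        counts: dict[int, int] = {}
        for t in toks:
            j = vocab.setdefault(t, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        indices.extend(counts.keys())
        data.extend(counts.values())
        indptr.append(len(indices))

    matrix = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(n_docs, len(vocab)),
    )
    # canonical (sorted) column order for reproducible signatures
    tokens = sorted(vocab)
    order = np.array([vocab[t] for t in tokens], dtype=int)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    matrix = matrix[:, order]
    matrix.sort_indices()
    df = np.asarray((matrix > 0).sum(axis=0)).ravel().astype(np.int64)
    totals = np.asarray(matrix.sum(axis=1)).ravel()
    return TokenMatrix(
        matrix=matrix,
        doc_ids=list(doc_ids),
        tokens=tokens,
        df=df,
        n_documents=n_docs,
        weighting="count",
        row_token_totals=totals,
    )


def tfidf(tm: TokenMatrix) -> TokenMatrix:
    """Weight a count matrix by relative term frequency x log2 inverse df.

    Documents with zero tokens keep all-zero rows.
    """
    if tm.weighting != "count":
        raise ValueError("tfidf expects a count-weighted matrix")
    totals = (
        tm.row_token_totals
        if tm.row_token_totals is not None
        else np.asarray(tm.matrix.sum(axis=1)).ravel()
    )
    inv_totals = np.divide(
        1.0, totals, out=np.zeros_like(totals, dtype=np.float64), where=totals > 0
    )
    idf = np.log2(tm.n_documents / tm.df.astype(np.float64))
    weighted = sp.diags(inv_totals) @ tm.matrix @ sp.diags(idf)
    return replace(tm, matrix=weighted.tocsr(), weighting="tfidf")


def prune_sparse(tm: TokenMatrix, min_doc_fraction: float = 0.0005) -> TokenMatrix:
    """Drop sparse terms: retain token t iff df(t) >= ceil(fraction * N).

    The inclusive-retain reading of "appearing in only 0.05% of documents";
    rows are unchanged and surviving document frequencies are preserved.
    """
    if not 0 <= min_doc_fraction <= 1:
        raise ValueError("min_doc_fraction must be in [0, 1]")
    threshold = int(np.ceil(min_doc_fraction * tm.n_documents))
    keep = np.flatnonzero(tm.df >= threshold)
    if keep.size == 0:
        raise ValueError(
            "sparse-term pruning removed every token; lower min_doc_fraction"
        )
    return replace(
        tm,
        matrix=tm.matrix[:, keep].tocsr(),
        tokens=[tm.tokens[j] for j in keep],
        df=tm.df[keep],
    )


def prepare_corpus(
    texts: Sequence[str],
    doc_ids: Sequence[str] | None = None,
    *,
    stopwords: frozenset[str] | None = None,
    min_doc_fraction: float = 0.0005,
) -> TokenMatrix:
    """Full preparation: normalize -> n-grams -> counts -> TF-IDF -> prune."""
    streams = [ngrams(normalize(t, stopwords)) for t in texts]
    tm = build_matrix(streams, doc_ids)
    return tfidf(prune_sparse(tm, min_doc_fraction))
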
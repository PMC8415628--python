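"""Normalization, n-grams, document-term matrix, TF-IDF and pruning, each
checked against independent brute-force oracles."""

from __future__ import annotations

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcas._porter import stem
from dcas.text_prep import (
    TokenMatrix,
    build_matrix,
    load_stopwords,
    ngrams,
    normalize,
    prune_sparse,
    tfidf,
)

# ---------------------------------------------------------------- stemming

STEM_VECTORS = {
    "walking": "walk", "walked": "walk", "walks": "walk",
    "licenses": "licens", "license": "licens", "revoked": "revok",
    "caresses": "caress", "ponies": "poni", "ties": "ti", "cats": "cat",
    "feed": "feed", "agreed": "agre", "plastered": "plaster",
    "motoring": "motor", "sing": "sing", "hopping": "hop",
    "falling": "fall", "filing": "file", "happy": "happi", "sky": "sky",
    "relational": "relat", "conditional": "condit", "rational": "ration",
    "operator": "oper", "feudalism": "feudal", "decisiveness": "decis",
    "hopefulness": "hope", "triplicate": "triplic", "formative": "form",
    "formalize": "formal", "electrical": "electr", "hopeful": "hope",
    "goodness": "good", "adjustable": "adjust", "defensible": "defens",
    "replacement": "replac", "adoption": "adopt", "communism": "commun",
    "activate": "activ", "effective": "effect", "rate": "rate",
    "cease": "ceas", "controlling": "control", "driving": "drive",
    "vision": "vision", "deceased": "deceas", "ability": "abil",
}


@pytest.mark.parametrize("word, expected", sorted(STEM_VECTORS.items()))
def test_porter_known_vectors(word, expected):
    assert stem(word) == expected


# ------------------------------------------------------------- normalize

def test_normalize_collapses_inflections():
    assert normalize("walking, walked, walks") == ["walk", "walk", "walk"]


def test_normalize_drops_stopwords_and_stems():
    assert normalize("The licenses were revoked") == ["licens", "revok"]


def test_normalize_empty_text():
    assert normalize("") == []


def test_normalize_keeps_standalone_numbers():
    assert normalize("76 year old male") == ["76", "year", "old", "male"]


def test_normalize_strips_punctuation_and_case(small_corpus):
    _, texts, _ = small_corpus
    for text in list(texts.values())[:200]:
        for tok in normalize(text):
            assert tok == tok.lower()
            assert re.fullmatch(r"[a-z0-9]+", tok), tok


def test_non_stemming_pipeline_is_idempotent(small_corpus):
    """Lowercasing, punctuation and stopword removal are a no-op on an
    already-normalized stream (stemming is applied once, by design)."""
    _, texts, _ = small_corpus
    for text in list(texts.values())[:200]:
        toks = normalize(text)
        assert normalize(" ".join(toks), stem=False) == toks


def test_stopword_snapshot_is_pinned():
    sw = load_stopwords()
    assert {"the", "and", "were", "was", "a", "no", "not"} <= sw
    assert "drive" not in sw and "longer" not in sw


# ---------------------------------------------------------------- ngrams

def test_ngrams_example():
    assert ngrams(["white", "male", "drove"]) == [
        "white", "male", "drove", "white male", "male drove",
    ]


def test_ngrams_single_token():
    assert ngrams(["alone"]) == ["alone"]


@given(st.lists(st.sampled_from("abcde"), min_size=0, max_size=30))
@settings(deadline=None, max_examples=50)
def test_ngrams_count_identity(tokens):
    out = ngrams(tokens)
    k = len(tokens)
    assert len(out) == k + max(k - 1, 0)
    assert all(" " in b for b in out[k:])


# ----------------------------------------------------- document-term matrix

def _brute_force_counts(docs):
    vocab = sorted({t for d in docs for t in d})
    dense = np.zeros((len(docs), len(vocab)))
    for i, d in enumerate(docs):
        for j, t in enumerate(vocab):
            dense[i, j] = sum(1 for x in d if x == t)
    df = (dense > 0).sum(axis=0)
    return vocab, dense, df


def test_build_matrix_small_example():
    tm = build_matrix([["a", "b"], ["b", "b"]])
    idx = tm.token_index
    assert tm.matrix[1, idx["b"]] == 2
    assert tm.df[idx["b"]] == 2
    assert tm.df[idx["a"]] == 1


def test_build_matrix_rejects_empty_corpus():
    with pytest.raises(ValueError, match="zero documents"):
        build_matrix([])


def test_build_matrix_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    alphabet = [f"w{i}" for i in range(12)]
    docs = [
        [alphabet[j] for j in rng.integers(0, 12, size=rng.integers(0, 15))]
        for _ in range(20)
    ]
    docs[3] = []  # empty document allowed
    tm = build_matrix(docs)
    vocab, dense, df = _brute_force_counts(docs)
    assert tm.tokens == vocab
    np.testing.assert_array_equal(tm.matrix.toarray(), dense)
    np.testing.assert_array_equal(tm.df, df)


# ----------------------------------------------------------------- tf-idf

def test_tfidf_token_in_every_document_weighs_zero():
    tm = tfidf(build_matrix([["a", "b"], ["a"], ["a", "c"]]))
    col = tm.token_index["a"]
    assert np.allclose(tm.matrix.toarray()[:, col], 0.0)


def test_tfidf_closed_form():
    # token "x" in 1 of 4 docs with relative frequency 1/2: 0.5*log2(4) = 1
    tm = tfidf(build_matrix([["x", "a"], ["a"], ["a"], ["a"]]))
    assert tm.matrix[0, tm.token_index["x"]] == pytest.approx(1.0)


def test_tfidf_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    docs = [
        [f"w{j}" for j in rng.integers(0, 15, size=rng.integers(1, 12))]
        for _ in range(10)
    ]
    tm = tfidf(build_matrix(docs))
    vocab, dense, df = _brute_force_counts(docs)
    n = len(docs)
    expected = np.zeros_like(dense)
    for i in range(n):
        total = dense[i].sum()
        for j in range(len(vocab)):
            if total and dense[i, j]:
                expected[i, j] = dense[i, j] / total * math.log2(n / df[j])
    np.testing.assert_allclose(tm.matrix.toarray(), expected, atol=1e-12)
    assert (tm.matrix.toarray() >= 0).all()


def test_tfidf_zero_token_document_row_is_zero():
    tm = tfidf(build_matrix([["a"], [], ["b"]]))
    assert tm.matrix.toarray()[1].sum() == 0


# ---------------------------------------------------------------- pruning

def _corpus_with_df(n_docs, df_map):
    """Docs of one shared token, with extra tokens planted at given df."""
    docs = [["common"] for _ in range(n_docs)]
    for tok, df in df_map.items():
        for i in range(df):
            docs[i].append(tok)
    return docs


def test_prune_threshold_is_inclusive_ceil():
    docs = _corpus_with_df(10_000, {"rare4": 4, "edge5": 5})
    tm = prune_sparse(build_matrix(docs), min_doc_fraction=0.0005)
    assert "rare4" not in tm.tokens
    assert "edge5" in tm.tokens and "common" in tm.tokens


def test_prune_zero_fraction_is_identity():
    tm = build_matrix([["a", "b"], ["c"]])
    pruned = prune_sparse(tm, min_doc_fraction=0.0)
    assert pruned.tokens == tm.tokens
    np.testing.assert_array_equal(pruned.matrix.toarray(), tm.matrix.toarray())


def test_prune_all_columns_is_an_error():
    with pytest.raises(ValueError, match="min_doc_fraction"):
        prune_sparse(build_matrix([["a"], ["b"]]), min_doc_fraction=1.0)


def test_prune_preserves_surviving_dfs_and_rows(small_corpus):
    _, texts, _ = small_corpus
    docs = [ngrams(normalize(t)) for t in list(texts.values())[:300]]
    tm = build_matrix(docs)
    pruned = prune_sparse(tm, min_doc_fraction=0.01)
    assert pruned.matrix.shape[0] == tm.matrix.shape[0]
    assert set(pruned.tokens) == {
        t for t, df in zip(tm.tokens, tm.df) if df >= math.ceil(0.01 * tm.n_documents)
    }
    recomputed = np.asarray((pruned.matrix > 0).sum(axis=0)).ravel()
    np.testing.assert_array_equal(recomputed, pruned.df)


# -------------------------------------------------- end-to-end equivalence

def naive_reference_tfidf(texts, min_doc_fraction):
    """Dict-of-dicts reimplementation of the whole preparation chain."""
    streams = [ngrams(normalize(t)) for t in texts]
    n = len(streams)
    df: dict[str, int] = {}
    for s in streams:
        for t in set(s):
            df[t] = df.get(t, 0) + 1
    kept = sorted(t for t, d in df.items() if d >= math.ceil(min_doc_fraction * n))
    rows = []
    for s in streams:
        total = len(s)
        row = {}
        for t in kept:
            c = sum(1 for x in s if x == t)
            row[t] = (c / total) * math.log2(n / df[t]) if total and c else 0.0
        rows.append(row)
    return kept, rows


@pytest.mark.parametrize("min_doc_fraction", [0.0, 0.05])
def test_end_to_end_equivalence_on_small_corpora(small_corpus, min_doc_fraction):
    _, texts, _ = small_corpus
    sample = list(texts.values())[:50]
    streams = [ngrams(normalize(t)) for t in sample]
    tm = tfidf(prune_sparse(build_matrix(streams), min_doc_fraction))
    kept, rows = naive_reference_tfidf(sample, min_doc_fraction)
    assert tm.tokens == kept
    dense = tm.matrix.toarray()
    for i, row in enumerate(rows):
        np.testing.assert_allclose(
            dense[i], [row[t] for t in kept], atol=1e-12
        )
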
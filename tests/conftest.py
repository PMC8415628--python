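"""Shared fixtures: synthetic corpora, a linearly separable toy problem, and
the (expensive, session-scoped) end-to-end recovery runs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from dcas import (
    ForestParams,
    GeneratorConfig,
    OracleAnnotator,
    generate_corpus,
    run_pipeline,
    train_cv,
)
from dcas.text_prep import prepare_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """n=2,000 default-parameter corpus with its texts and latent truth."""
    corpus = generate_corpus(GeneratorConfig(n_narratives=2000, seed=7))
    texts = {n.id: n.text for n in corpus}
    truth = {n.id: n.true_label for n in corpus}
    return corpus, texts, truth


@pytest.fixture(scope="session")
def corpus_50k():
    """Large default-parameter corpus for covariate-moment checks."""
    return generate_corpus(GeneratorConfig(n_narratives=50_000, seed=3))


def _separable_texts(n_per_class: int = 20, seed: int = 5):
    """Texts where the token 'cessat' (stem of 'cessation') appears iff the
    document is positive.  Every noise word appears once in every document
    (so its TF-IDF weight is near zero) and only the marker separates the
    classes."""
    rng = np.random.default_rng(seed)
    noise = [
        "patient", "history", "family", "residence", "note", "evening",
        "found", "firearm", "wound", "report", "county", "record",
    ]
    texts, labels = {}, {}
    for i in range(2 * n_per_class):
        words = list(rng.permutation(noise))
        positive = i < n_per_class
        if positive:
            at = int(rng.integers(0, len(words)))
            words[at:at] = ["cessation", "cessation"]
        doc_id = f"t{i:03d}"
        texts[doc_id] = " ".join(words)
        labels[doc_id] = "DCAS" if positive else "non-DCAS"
    return texts, labels


@pytest.fixture(scope="session")
def separable_toy():
    texts, labels = _separable_texts()
    tm = prepare_corpus(
        list(texts.values()), list(texts.keys()), min_doc_fraction=0.1
    )
    return tm, labels


@pytest.fixture(scope="session")
def separable_fit(separable_toy):
    tm, labels = separable_toy
    return train_cv(tm, labels, ForestParams(seed=0))


@pytest.fixture(scope="session")
def e2e_runs():
    """Ten seeded end-to-end pipeline runs at n=20,000, prevalence 0.5%,
    keyword_free_rate 0.2, oracle annotation — the study-scale recovery
    experiment shared by the pipeline and acceptance tests."""
    n, prevalence = 20_000, 0.005
    runs = []
    for seed in range(10):
        corpus = generate_corpus(
            GeneratorConfig(
                n_narratives=n, prevalence=prevalence, keyword_free_rate=0.2, seed=seed
            )
        )
        texts = {x.id: x.text for x in corpus}
        truth = {x.id: x.true_label for x in corpus}
        tm = prepare_corpus(list(texts.values()), list(texts.keys()))
        res = run_pipeline(
            texts, OracleAnnotator(truth, rng=seed), seed=seed, token_matrix=tm
        )
        true_n = sum(1 for v in truth.values() if v == "DCAS")
        est = res.prevalence.total_positive
        lo, hi = stats.binom.ppf([0.025, 0.975], n, max(est, 1) / n)
        # round-1 probability-bin composition among the then-unlabeled
        bin_rates = []
        from dcas import AnnotationPlan, assign_bins

        bins = assign_bins(res.round1_probs, AnnotationPlan())
        for ids in bins:
            pos = sum(1 for i in ids if truth[i] == "DCAS")
            bin_rates.append((pos, len(ids)))
        runs.append(
            {
                "seed": seed,
                "n": n,
                "true": true_n,
                "estimate": est,
                "covered": bool(lo <= true_n <= hi),
                "bin_rates": bin_rates,
                "confusion": res.confusion,
                "metrics": res.metric_set,
            }
        )
    return runs
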
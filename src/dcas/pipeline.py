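"""End-to-end orchestration of the seven-step estimation procedure.

1. keyword-screen the corpus and annotate a stratified seed sample;
2. prepare the corpus-wide pruned TF-IDF matrix;
3. train the first forest on the seed labels;
4. bin the unlabeled narratives by predicted probability, annotate a
   stratified batch, and merge into an expanded labeled set;
5. train the second forest on the expanded labels;
6. score the remaining unlabeled narratives and review those >= 0.5;
7. key-phrase sweep the < 0.5 remainder, then summarize: confusion matrix
   under the sweep-completeness assumption, metrics, and the frequency
   estimate.

The annotator is an interface (ids -> labels); synthetic runs plug in
:class:`~dcas.iterative_annotation.OracleAnnotator`.  All randomness derives
from one integer seed, so a (seed, plans) manifest replays every
intermediate artifact exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .estimation_eval import (
    ConfusionSummary,
    MetricSet,
    PrevalenceEstimate,
    estimate_prevalence,
    finalize_cases,
    metrics,
)
from .iterative_annotation import (
    AnnotationPlan,
    LabeledSet,
    assign_bins,
    draw_batch,
    merge,
)
from .keyword_screen import (
    DEFAULT_KEYWORDS,
    KeyPhraseList,
    SeedSamplePlan,
    bin_corpus,
    default_keyphrases,
    draw_seed_sample,
    keyphrase_sweep,
)
from .rare_case_classifier import ClassifierFit, ForestParams, predict_prob, train_cv
from .text_prep import TokenMatrix, prepare_corpus

__all__ = ["PipelineResult", "run_pipeline"]

Annotator = Callable[[Iterable[str]], Mapping[str, str]]


@dataclass
class PipelineResult:
    """Everything the procedure produced, round by round."""

    labeled: LabeledSet
    fit_round1: ClassifierFit
    fit_round2: ClassifierFit
    round1_probs: dict[str, float] = field(repr=False)
    round2_probs: dict[str, float] = field(repr=False)
    review_labels: dict[str, str] = field(repr=False)
    sweep_hits: list[tuple[str, str]]
    confusion: ConfusionSummary
    metric_set: MetricSet
    prevalence: PrevalenceEstimate
    final_case_ids: list[str]

    @property
    def flagged_ids(self) -> list[str]:
        return sorted(self.review_labels)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    texts: Mapping[str, str],
    annotator: Annotator,
    *,
    seed: int = 0,
    keywords=DEFAULT_KEYWORDS,
    seed_plan: SeedSamplePlan | None = None,
    annotation_plan: AnnotationPlan | None = None,
    forest_params: ForestParams | None = None,
    keyphrases: KeyPhraseList | None = None,
    min_doc_fraction: float = 0.0005,
    threshold: float = 0.5,
    token_matrix: TokenMatrix | None = None,
) -> PipelineResult:
    """Run the full procedure over ``texts`` (narrative id -> raw text).

    ``forest_params.seed`` is ignored: forest and sampling seeds derive from
    ``seed``.  Pass a precomputed ``token_matrix`` (as from
    :func:`~dcas.text_prep.prepare_corpus` over the same ids) to skip text
    preparation.
    """
    ss_seed, ss_batch, ss_f1, ss_f2 = np.random.SeedSequence(seed).spawn(4)
    seed_plan = seed_plan or SeedSamplePlan()
    annotation_plan = annotation_plan or AnnotationPlan()
    base_params = forest_params or ForestParams()
    keyphrases = keyphrases or default_keyphrases()

    # step 1: keyword screen and seed annotation round
    binning = bin_corpus(texts, keywords)
    seed_worklist = draw_seed_sample(binning, seed_plan, np.random.default_rng(ss_seed))
    seed_labels = dict(annotator([i for i, _ in seed_worklist]))
    labeled = LabeledSet.from_labels(seed_labels, "seed-keyword", round_index=0)

    # step 2: corpus-wide document-term matrix
    if token_matrix is None:
        token_matrix = prepare_corpus(
            list(texts.values()), list(texts.keys()), min_doc_fraction=min_doc_fraction
        )

    # step 3: first classifier
    from dataclasses import replace

    fit1 = train_cv(
        token_matrix.rows(labeled.ids),
        {i: labeled.records[i].label for i in labeled.ids},
        replace(base_params, seed=_child_seed(ss_f1)),
    )

    # step 4: probability-binned annotation round
    unlabeled = [i for i in texts if i not in labeled]
    round1_probs = predict_prob(fit1, token_matrix.rows(unlabeled))
    bins = assign_bins(round1_probs, annotation_plan)
    batch = draw_batch(
        bins, annotation_plan, labeled.ids, np.random.default_rng(ss_batch)
    )
    batch_labels = dict(annotator([i for i, _ in batch]))
    labeled = merge(
        labeled, LabeledSet.from_labels(batch_labels, "bin-annotation", round_index=1)
    )

    # step 5: second classifier on the expanded labeled set
    fit2 = train_cv(
        token_matrix.rows(labeled.ids),
        {i: labeled.records[i].label for i in labeled.ids},
        replace(base_params, seed=_child_seed(ss_f2)),
    )

    # step 6: score the remainder and review the flagged
    unlabeled = [i for i in texts if i not in labeled]
    round2_probs = predict_prob(fit2, token_matrix.rows(unlabeled))
    flagged = sorted(i for i, p in round2_probs.items() if p >= threshold)
    review_labels = dict(annotator(flagged))

    # step 7: key-phrase sweep of the unflagged remainder, then summarize
    unflagged_texts = {
        i: texts[i] for i, p in round2_probs.items() if p < threshold
    }
    sweep_hits = keyphrase_sweep(unflagged_texts, keyphrases)
    confusion, final_cases = finalize_cases(
        round2_probs,
        review_labels,
        [i for i, _ in sweep_hits],
        threshold=threshold,
        labeled_positive_ids=labeled.positive_ids,
    )
    prevalence = estimate_prevalence(
        labeled_positives=labeled.n_positive,
        confirmed_flagged_positives=confusion.tp,
        sweep_recoveries=len(sweep_hits),
        denominator=len(texts),
    )
    return PipelineResult(
        labeled=labeled,
        fit_round1=fit1,
        fit_round2=fit2,
        round1_probs=round1_probs,
        round2_probs=round2_probs,
        review_labels=review_labels,
        sweep_hits=sweep_hits,
        confusion=confusion,
        metric_set=metrics(confusion),
        prevalence=prevalence,
        final_case_ids=final_cases,
    )
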
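"""Final case determination, confusion metrics under the sweep-completeness
assumption, prevalence estimation, and the Poisson time trend.

After the second classifier pass, narratives scoring >= 0.5 are manually
reviewed (true vs. false positives) and a key-phrase sweep of the < 0.5
remainder recovers missed cases.  Treating the sweep as complete — every
unflagged, unswept narrative is a true negative — yields a full confusion
matrix and a frequency estimate that the design makes a slight
underestimate (the sweep cannot be exhaustive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionSummary",
    "MetricSet",
    "PrevalenceEstimate",
    "TrendFit",
    "finalize_cases",
    "metrics",
    "estimate_prevalence",
    "poisson_trend",
]


@dataclass
class ConfusionSummary:
    """TP/FP from flagged-case review, FN from the sweep, TN by assumption."""

    tp: int
    fp: int
    fn: int
    tn: int
    assumption: str = "sweep-complete"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def n_unflagged(self) -> int:
        return self.fn + self.tn


@dataclass
class MetricSet:
    """Classification metrics; a metric whose denominator is zero is absent
    (None), never reported as zero."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in vars(self).items()
        }


def metrics(cs: ConfusionSummary) -> MetricSet:
    """Sensitivity, specificity, precision, NPV and F1 (harmonic mean of
    sensitivity and precision) from a confusion summary."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    sens = ratio(cs.tp, cs.tp + cs.fn)
    spec = ratio(cs.tn, cs.tn + cs.fp)
    prec = ratio(cs.tp, cs.tp + cs.fp)
    npv = ratio(cs.tn, cs.tn + cs.fn)
    f1 = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2 * sens * prec / (sens + prec)
    return MetricSet(sensitivity=sens, specificity=spec, precision=prec, npv=npv, f1=f1)


def finalize_cases(
    probabilities: Mapping[str, float],
    review_labels: Mapping[str, str],
    sweep_ids: Iterable[str],
    *,
    threshold: float = 0.5,
    labeled_positive_ids: Iterable[str] = (),
    sweep_recall: float = 1.0,
) -> tuple[ConfusionSummary, list[str]]:
    """Combine threshold review and sweep into the final case determination.

    ``probabilities`` score the unlabeled narratives; ids with probability
    >= ``threshold`` are flagged and must each carry a review label
    (DCAS / non-DCAS); ``sweep_ids`` are the key-phrase hits among the
    unflagged.  Under the sweep-completeness assumption FN = |sweep_ids| and
    the remaining unflagged are TN.  Set ``sweep_recall`` < 1 for the
    sensitivity-analysis mode that scales FN by 1/recall.

    Returns the confusion summary and the final case id list:
    labeled positives + review-confirmed flagged + sweep recoveries.
    """
    if not 0 < sweep_recall <= 1:
        raise ValueError("sweep_recall must be in (0, 1]")
    flagged = {i for i, p in probabilities.items() if p >= threshold}
    unflagged = {i for i in probabilities if i not in flagged}

    missing_review = sorted(flagged - set(review_labels))
    if missing_review:
        raise ValueError(
            f"flagged narratives missing a review label: {missing_review[:5]}"
            f"{'...' if len(missing_review) > 5 else ''}"
        )
    sweep = list(dict.fromkeys(sweep_ids))
    bad_sweep = sorted(set(sweep) & flagged)
    if bad_sweep:
        raise ValueError(f"sweep ids must be unflagged; got flagged ids {bad_sweep[:5]}")
    outside = sorted(set(sweep) - unflagged)
    if outside:
        raise ValueError(f"sweep ids not among the scored narratives: {outside[:5]}")

    confirmed = [i for i in sorted(flagged) if review_labels[i] == "DCAS"]
    tp = len(confirmed)
    fp = len(flagged) - tp
    fn = len(sweep)
    if sweep_recall < 1:
        fn = int(round(fn / sweep_recall))
    tn = len(unflagged) - fn
    cs = ConfusionSummary(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        assumption=(
            "sweep-complete" if sweep_recall == 1 else f"sweep-recall={sweep_recall}"
        ),
    )
    final_cases = list(dict.fromkeys([*labeled_positive_ids, *confirmed, *sweep]))
    return cs, final_cases


@dataclass
class PrevalenceEstimate:
    """Component counts and the resulting frequency estimate."""

    labeled_positives: int
    confirmed_flagged_positives: int
    sweep_recoveries: int
    denominator: int

    def __post_init__(self) -> None:
        if min(
            self.labeled_positives,
            self.confirmed_flagged_positives,
            self.sweep_recoveries,
        ) < 0:
            raise ValueError("component counts must be >= 0")
        if self.denominator <= 0:
            raise ValueError("denominator must be > 0")

    @property
    def total_positive(self) -> int:
        return (
            self.labeled_positives
            + self.confirmed_flagged_positives
            + self.sweep_recoveries
        )

    @property
    def proportion(self) -> float:
        return self.total_positive / self.denominator


def estimate_prevalence(
    labeled_positives: int,
    confirmed_flagged_positives: int,
    sweep_recoveries: int,
    denominator: int,
) -> PrevalenceEstimate:
    """Total identified cases over the analytic denominator, with the
    three-route component breakdown retained for reporting."""
    return PrevalenceEstimate(
        labeled_positives=labeled_positives,
        confirmed_flagged_positives=confirmed_flagged_positives,
        sweep_recoveries=sweep_recoveries,
        denominator=denominator,
    )


@dataclass
class TrendFit:
    """Log-linear Poisson trend of annual case counts."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    pvalue: float
    method: str = "poisson-glm-irls"
    states: tuple[str, ...] | None = None


def poisson_trend(
    counts_by_year: Mapping[int, int],
    states: Sequence[str] | None = None,
) -> TrendFit:
    """Poisson regression of annual case counts on calendar year.

    log E[count_y] = intercept + slope * t, with t the 0-based year index;
    fitted by IRLS; Wald p-value for the slope.  ``states`` only records the
    state restriction applied upstream when aggregating counts.
    """
    years = sorted(counts_by_year)
    if len(years) < 2:
        raise ValueError("need counts for at least 2 distinct years")
    counts = np.array([counts_by_year[y] for y in years], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    if counts.sum() == 0:
        raise ValueError("all-zero counts; no trend is estimable")

    import statsmodels.api as sm

    t = np.array(years, dtype=float) - years[0]
    X = sm.add_constant(t)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        pvalue=float(fit.pvalues[1]),
        states=None if states is None else tuple(states),
    )
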
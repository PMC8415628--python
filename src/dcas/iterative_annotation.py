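"""Classifier-guided annotation loop: probability binning, stratified batch
draws, labeled-set merging, and the oracle annotator used on synthetic runs.

After the first classifier pass, unlabeled narratives are binned by
predicted case probability and a fixed per-bin batch (default
20/20/30/20/20 over the five 0.2-wide bins) is drawn for manual review.
Sampling across the probability range, with extra weight on the uncertain
middle bin, both finds positives the seed keywords missed and sharpens the
decision boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("dcas")

__all__ = [
    "AnnotationPlan",
    "LabelRecord",
    "LabeledSet",
    "OracleAnnotator",
    "assign_bins",
    "draw_batch",
    "merge",
]

PROVENANCES = ("seed-keyword", "bin-annotation", "threshold-review", "sweep")


@dataclass
class AnnotationPlan:
    """Probability bin edges and per-bin draw counts.

    Bins are lower-inclusive, upper-exclusive, except the top bin which is
    closed at 1.0 (a probability of exactly 0.8 falls in the top bin of the
    default plan; 0.7999 falls in the fourth).
    """

    edges: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    counts: tuple[int, ...] = (20, 20, 30, 20, 20)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0 or any(
            a >= b for a, b in zip(e, e[1:])
        ):
            raise ValueError("edges must increase strictly from 0 to 1")
        if len(self.counts) != len(e) - 1:
            raise ValueError("need one draw count per bin")
        if any(c < 0 for c in self.counts):
            raise ValueError("draw counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def assign_bins(
    probabilities: Mapping[str, float], plan: AnnotationPlan | None = None
) -> list[list[str]]:
    """Partition scored ids into the plan's probability bins (low to high)."""
    plan = plan or AnnotationPlan()
    edges = np.asarray(plan.edges)
    bins: list[list[str]] = [[] for _ in range(plan.n_bins)]
    for doc_id, p in probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {doc_id!r} outside [0, 1]: {p!r}")
        idx = min(int(np.searchsorted(edges, p, side="right")) - 1, plan.n_bins - 1)
        bins[idx].append(doc_id)
    return bins


def draw_batch(
    bins: Sequence[Sequence[str]],
    plan: AnnotationPlan | None = None,
    already_labeled: Iterable[str] = (),
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, int]]:
    """Stratified annotation worklist: (id, bin index) pairs.

    Per-bin without-replacement draws of min(requested, available), never
    revisiting already-labeled ids; shortfalls are logged; reproducible
    given the rng seed.
    """
    plan = plan or AnnotationPlan()
    if len(bins) != plan.n_bins:
        raise ValueError("bins do not match the plan")
    rng = np.random.default_rng(rng)
    exclude = set(already_labeled)
    out: list[tuple[str, int]] = []
    for b, (ids, want) in enumerate(zip(bins, plan.counts)):
        avail = sorted(i for i in ids if i not in exclude)
        take = min(want, len(avail))
        if take < want:
            logger.warning(
                "bin %d holds %d unlabeled narratives; requested %d", b, len(avail), want
            )
        if take:
            picked = rng.choice(len(avail), size=take, replace=False)
            out.extend((avail[i], b) for i in sorted(picked))
    return out


@dataclass(frozen=True)
class LabelRecord:
    label: str  # "DCAS" | "non-DCAS"
    provenance: str  # one of PROVENANCES
    round_index: int = 0
    annotator: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("DCAS", "non-DCAS"):
            raise ValueError(f"label must be DCAS/non-DCAS, got {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )


@dataclass
class LabeledSet:
    """Narrative id -> label with provenance and round bookkeeping."""

    records: dict[str, LabelRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self.records

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    @property
    def positive_ids(self) -> list[str]:
        return [i for i, r in self.records.items() if r.label == "DCAS"]

    @property
    def n_positive(self) -> int:
        return len(self.positive_ids)

    @classmethod
    def from_labels(
        cls,
        labels: Mapping[str, str],
        provenance: str,
        round_index: int = 0,
        annotator: str = "",
    ) -> "LabeledSet":
        return cls(
            {
                i: LabelRecord(l, provenance, round_index, annotator)
                for i, l in labels.items()
            }
        )


def merge(base: LabeledSet, new: LabeledSet) -> LabeledSet:
    """Union of two labeled sets, keyed by id, provenance preserved.

    A shared id with an identical label keeps the base record (idempotent);
    a shared id with conflicting labels is a hard error listing the ids —
    never a silent overwrite.
    """
    conflicts = [
        i
        for i, r in new.records.items()
        if i in base.records and base.records[i].label != r.label
    ]
    if conflicts:
        raise ValueError(f"conflicting labels for ids: {sorted(conflicts)}")
    merged = dict(base.records)
    for i, r in new.records.items():
        merged.setdefault(i, r)
    return LabeledSet(merged)


class OracleAnnotator:
    """Annotator interface backed by the generator's latent truth.

    Returns the true label for each requested id, flipped with probability
    ``error_rate`` to emulate imperfect human review.  The same interface as
    a worklist-CSV/labels-CSV human round, so pipelines are testable
    end-to-end.
    """

    def __init__(
        self,
        truth: Mapping[str, str],
        error_rate: float = 0.0,
        rng: np.random.Generator | int | None = None,
        tag: str = "oracle",
    ) -> None:
        if not 0 <= error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        self.truth = dict(truth)
        self.error_rate = error_rate
        self.rng = np.random.default_rng(rng)
        self.tag = tag

    def __call__(self, ids: Iterable[str]) -> dict[str, str]:
        out = {}
        for i in ids:
            label = self.truth[i]
            if self.error_rate and self.rng.random() < self.error_rate:
                label = "DCAS" if label == "non-DCAS" else "non-DCAS"
            out[i] = label
        return out
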
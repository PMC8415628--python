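"""Seeded generator of registry-style death narratives with known latent
driving-cessation labels.

The real corpus this emulates — coroner/medical-examiner narratives attached
to a violent-death registry — is restricted, so every downstream stage is
exercised on synthetic narratives whose truth is known.  The generator
emulates the features that matter to the pipeline:

* a rare positive class ("DCAS", driving-cessation-associated suicide) at
  configurable prevalence (default 0.5%);
* four overlapping positive themes (functional impairment, car accident,
  substance use, employment loss) drawn independently per theme conditioned
  on at least one;
* positives that sometimes phrase cessation without any of the four seed
  keywords (drive / license / vision / DMV), and negatives that sometimes
  contain a seed keyword spuriously ("driver's seat", "driveway",
  "television", ...);
* class- and theme-conditional demographic covariates (sex, age, race,
  education, marital status, health/crisis/ideation flags, county rurality).

Narrative text is sentence-slot templated (opener + theme clauses +
cessation clause + fillers) from versioned phrase pools shipped as package
data; 2–6 sentences per narrative.  Identical (config, seed) yields a
byte-identical corpus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "THEMES",
    "RACES",
    "MARITAL_STATUSES",
    "EARLY_REPORTING_STATES",
    "ClassDemographics",
    "GeneratorConfig",
    "Narrative",
    "generate_corpus",
    "render_narrative",
    "sample_covariates",
    "load_phrase_pools",
    "corpus_to_frame",
    "truth_to_frame",
    "write_corpus_csv",
]

THEMES: tuple[str, ...] = ("functional", "accident", "substance", "employment")

RACES: tuple[str, ...] = (
    "White",
    "Black or African American",
    "Asian/Pacific Islander",
    "American Indian/Alaska native",
    "Other/unknown",
)

MARITAL_STATUSES: tuple[str, ...] = (
    "Married/civil union/domestic partnership",
    "Divorced",
    "Widowed",
    "Single or never married",
    "Unknown or missing",
)

_RACE_ADJECTIVE = {
    "White": "white",
    "Black or African American": "black",
    "Asian/Pacific Islander": "asian",
    "American Indian/Alaska native": "american indian",
    "Other/unknown": "",
}

#: The 16 registry states reporting since 2005, used for trend analyses.
EARLY_REPORTING_STATES: tuple[str, ...] = (
    "AK", "CO", "GA", "KY", "MD", "MA", "NJ", "NM",
    "NC", "OK", "OR", "RI", "SC", "UT", "VA", "WI",
)

_LATE_STATES: tuple[str, ...] = ("AZ", "CA", "MI", "OH")

MIN_AGE = 55


def _check_fraction(value: float, name: str, closed: bool = True) -> None:
    lo_ok = 0 <= value if closed else 0 < value
    hi_ok = value <= 1 if closed else value < 1
    if not (lo_ok and hi_ok):
        bounds = "[0, 1]" if closed else "(0, 1)"
        raise ValueError(f"{name} must be in {bounds}, got {value!r}")


def _check_probs(probs: Mapping[str, float], categories: Sequence[str], name: str) -> None:
    if set(probs) != set(categories):
        raise ValueError(f"{name} must have exactly the categories {categories}")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} probabilities must be >= 0")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must sum to 1 (got {sum(probs.values())!r})")


@dataclass
class ClassDemographics:
    """Covariate distributions for one class (case or non-case).

    Age mean/SD are the target moments of the age-55-truncated distribution
    (ages below 55 are excluded from the sampling frame): the generator
    calibrates the pre-truncation normal location so the truncated mean hits
    ``age_mean``.
    """

    male_fraction: float
    age_mean: float
    age_sd: float
    race_probs: dict[str, float]
    education_mean: float
    education_sd: float
    marital_probs: dict[str, float]
    physical_health_rate: float
    mental_health_rate: float
    crisis_rate: float
    ideation_disclosed_rate: float
    ideation_history_rate: float
    rucc_mean: float
    rucc_sd: float
    suicide_fraction: float

    def validate(self, prefix: str) -> None:
        for f in (
            "male_fraction",
            "physical_health_rate",
            "mental_health_rate",
            "crisis_rate",
            "ideation_disclosed_rate",
            "ideation_history_rate",
            "suicide_fraction",
        ):
            _check_fraction(getattr(self, f), f"{prefix}.{f}")
        if self.age_mean <= MIN_AGE:
            raise ValueError(f"{prefix}.age_mean must exceed {MIN_AGE}")
        for f in ("age_sd", "education_sd", "rucc_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{prefix}.{f} must be > 0")
        _check_probs(self.race_probs, RACES, f"{prefix}.race_probs")
        _check_probs(self.marital_probs, MARITAL_STATUSES, f"{prefix}.marital_probs")


def _default_case_demographics() -> ClassDemographics:
    return ClassDemographics(
        male_fraction=0.849,
        age_mean=71.2,
        age_sd=11.6,
        race_probs=dict(zip(RACES, (0.957, 0.026, 0.007, 0.003, 0.007))),
        education_mean=12.2,
        education_sd=2.71,
        marital_probs=dict(zip(MARITAL_STATUSES, (0.361, 0.282, 0.243, 0.098, 0.016))),
        physical_health_rate=0.554,
        mental_health_rate=0.426,
        crisis_rate=0.456,
        ideation_disclosed_rate=0.25,
        ideation_history_rate=0.24,
        rucc_mean=3.04,
        rucc_sd=1.44,
        suicide_fraction=0.967,
    )


def _default_noncase_demographics() -> ClassDemographics:
    return ClassDemographics(
        male_fraction=0.771,
        age_mean=66.6,
        age_sd=9.86,
        race_probs=dict(zip(RACES, (0.9194, 0.049, 0.0137, 0.0045, 0.0134))),
        education_mean=12.9,
        education_sd=2.90,
        marital_probs=dict(zip(MARITAL_STATUSES, (0.427, 0.288, 0.150, 0.119, 0.016))),
        physical_health_rate=0.388,
        mental_health_rate=0.415,
        crisis_rate=0.211,
        ideation_disclosed_rate=0.22,
        ideation_history_rate=0.20,
        rucc_mean=2.94,
        rucc_sd=1.52,
        suicide_fraction=0.896,
    )


def _default_theme_weights() -> dict[str, float]:
    # proportional to observed theme counts 157 / 43 / 68 / 26 among 305 cases
    return {
        "functional": 157 / 305,
        "accident": 43 / 305,
        "substance": 68 / 305,
        "employment": 26 / 305,
    }


def _default_theme_ages() -> dict[str, tuple[float, float]]:
    return {
        "functional": (75.5, 10.8),
        "accident": (72.6, 11.4),
        "substance": (63.2, 7.64),
        "employment": (60.3, 3.92),
    }


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic corpus.

    ``theme_weights`` are per-theme Bernoulli marginals, drawn independently
    and conditioned on at least one theme per positive; theme co-occurrence
    is induced by the marginals.  ``theme_age_overrides`` replace the class
    age distribution for positives carrying that theme (when several themes
    are present the youngest-mean theme wins, reflecting that substance- and
    employment-related cessation dominates younger cases).
    """

    n_narratives: int = 10_000
    prevalence: float = 0.005
    theme_weights: dict[str, float] = field(default_factory=_default_theme_weights)
    keyword_free_rate: float = 0.2
    spurious_keyword_rate: float = 0.01
    case_demographics: ClassDemographics = field(default_factory=_default_case_demographics)
    noncase_demographics: ClassDemographics = field(default_factory=_default_noncase_demographics)
    theme_age_overrides: dict[str, tuple[float, float]] = field(default_factory=_default_theme_ages)
    year_range: tuple[int, int] = (2003, 2017)
    states: tuple[str, ...] = EARLY_REPORTING_STATES + _LATE_STATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_narratives < 1:
            raise ValueError("n_narratives must be >= 1")
        _check_fraction(self.prevalence, "prevalence", closed=False)
        _check_fraction(self.keyword_free_rate, "keyword_free_rate")
        _check_fraction(self.spurious_keyword_rate, "spurious_keyword_rate")
        if set(self.theme_weights) != set(THEMES):
            raise ValueError(f"theme_weights must have exactly the themes {THEMES}")
        for theme, w in self.theme_weights.items():
            _check_fraction(w, f"theme_weights[{theme}]")
        if all(w == 0 for w in self.theme_weights.values()):
            raise ValueError("theme_weights must not be all zero")
        for theme in self.theme_age_overrides:
            if theme not in THEMES:
                raise ValueError(f"theme_age_overrides has unknown theme {theme!r}")
        self.case_demographics.validate("case_demographics")
        self.noncase_demographics.validate("noncase_demographics")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")
        if not self.states:
            raise ValueError("states must be non-empty")


@dataclass
class Narrative:
    """One synthetic registry record: free text, coded covariates, and the
    latent truth (label + themes) used only for evaluation."""

    id: str
    text: str
    manner: str  # "suicide" | "undetermined"
    year: int
    state: str
    sex: str
    age: int
    race: str
    education_years: int
    marital_status: str
    physical_health_flag: bool
    mental_health_flag: bool
    crisis_flag: bool
    ideation_disclosed_flag: bool
    ideation_history_flag: bool
    rucc: int
    true_label: str  # "DCAS" | "non-DCAS"
    themes: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def load_phrase_pools() -> dict:
    raw = yaml.safe_load(
        resources.files("dcas.data").joinpath("phrase_pools.yaml").read_text("utf-8")
    )
    return raw


@lru_cache(maxsize=256)
def _truncated_loc(target_mean: float, sd: float, lower: float = MIN_AGE) -> float:
    """Pre-truncation normal location whose lower-truncated mean equals
    ``target_mean``.  The truncated mean mu + sd*phi(a)/(1-Phi(a)) with
    a = (lower-mu)/sd is strictly increasing in mu and tends to ``lower`` as
    mu -> -inf, so a root exists for any target above the bound."""

    def truncated_mean(mu: float) -> float:
        a = (lower - mu) / sd
        return mu + sd * stats.norm.pdf(a) / stats.norm.sf(a)

    return optimize.brentq(
        lambda mu: truncated_mean(mu) - target_mean,
        lower - 30 * sd,
        target_mean + sd,
        xtol=1e-10,
    )


def _draw_truncated_age(mean: float, sd: float, rng: np.random.Generator) -> int:
    loc = _truncated_loc(mean, sd)
    while True:
        x = rng.normal(loc, sd)
        if x >= MIN_AGE:
            return int(round(x))


def _categorical(probs: Mapping[str, float], categories: Sequence[str],
                 rng: np.random.Generator) -> str:
    p = np.array([probs[c] for c in categories], dtype=float)
    return categories[rng.choice(len(categories), p=p / p.sum())]


def sample_covariates(
    label: str,
    themes: Sequence[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict:
    """Draw coded covariates for one decedent.

    Distributions are class-conditional, with per-theme age overrides for
    positives; ages are truncated at 55 (the sampling frame's age floor).
    """
    if label == "DCAS":
        demo = config.case_demographics
    elif label == "non-DCAS":
        demo = config.noncase_demographics
    else:
        raise ValueError(f"unknown label {label!r}")
    if themes and label != "DCAS":
        raise ValueError("themes are only defined for DCAS narratives")

    age_mean, age_sd = demo.age_mean, demo.age_sd
    overridden = [t for t in themes if t in config.theme_age_overrides]
    if overridden:
        age_mean, age_sd = min(
            (config.theme_age_overrides[t] for t in overridden), key=lambda ms: ms[0]
        )

    sex = "Male" if rng.random() < demo.male_fraction else "Female"
    age = _draw_truncated_age(age_mean, age_sd, rng)
    race = _categorical(demo.race_probs, RACES, rng)
    education = int(round(np.clip(rng.normal(demo.education_mean, demo.education_sd), 0, 20)))
    marital = _categorical(demo.marital_probs, MARITAL_STATUSES, rng)
    return {
        "sex": sex,
        "age": age,
        "race": race,
        "education_years": education,
        "marital_status": marital,
        "physical_health_flag": bool(rng.random() < demo.physical_health_rate),
        "mental_health_flag": bool(rng.random() < demo.mental_health_rate),
        "crisis_flag": bool(rng.random() < demo.crisis_rate),
        "ideation_disclosed_flag": bool(rng.random() < demo.ideation_disclosed_rate),
        "ideation_history_flag": bool(rng.random() < demo.ideation_history_rate),
        "rucc": int(round(np.clip(rng.normal(demo.rucc_mean, demo.rucc_sd), 1, 9))),
        "manner": "suicide" if rng.random() < demo.suicide_fraction else "undetermined",
        "year": int(rng.integers(config.year_range[0], config.year_range[1] + 1)),
        "state": str(config.states[rng.integers(len(config.states))]),
    }


def _pick(pool: Sequence[str], rng: np.random.Generator) -> str:
    return pool[rng.integers(len(pool))]


_VERB_INITIAL = frozenset(
    "was had could felt worried feared kept drank struggled depended "
    "worked relied lost left suffered failed".split()
)


def _with_subject(sentence: str, male: bool, rng: np.random.Generator) -> str:
    """Registry narratives alternate between telegraphic verb-initial
    sentences and explicit subjects; prefix verb-initial templates with
    'The victim' or a pronoun at random (both classes, so the subject word
    carries no label signal)."""
    if sentence.split(" ", 1)[0] not in _VERB_INITIAL:
        return sentence
    u = rng.random()
    if u < 1 / 3:
        return "the victim " + sentence
    if u < 2 / 3:
        return ("he " if male else "she ") + sentence
    return sentence


def _fill(template: str, slots: Mapping[str, str]) -> str:
    return template.format(**slots)


MAX_SENTENCES = 6


def render_narrative(
    label: str,
    themes: Sequence[str],
    covariates: Mapping[str, object],
    rng: np.random.Generator,
    *,
    keyword_free_rate: float = 0.2,
    spurious_keyword_rate: float = 0.01,
) -> str:
    """Render one narrative (2–6 sentences) from the template pools.

    Positives realize each of their themes with one theme-pool sentence and
    carry exactly one cessation clause, drawn from the keyword-bearing pool
    with probability 1 - keyword_free_rate, else from the keyword-free pool.
    Negatives are opener + fillers, with a spuriously keyword-bearing
    sentence at rate spurious_keyword_rate.
    """
    pools = load_phrase_pools()
    for t in themes:
        if t not in THEMES:
            raise ValueError(f"unknown theme {t!r}")

    male = covariates["sex"] == "Male"
    slots = {
        "he": "he" if male else "she",
        "his": "his" if male else "her",
        "him": "him" if male else "her",
    }
    race_adj = _RACE_ADJECTIVE[str(covariates["race"])]
    person = " ".join(x for x in (race_adj, "male" if male else "female") if x)
    opener = (
        f"{covariates['age']} year old {person} was found "
        f"{_pick(pools['openers']['found_states'], rng)} "
        f"{_fill(_pick(pools['openers']['locations'], rng), slots)} "
        f"{_pick(pools['openers']['causes'], rng)}"
    )

    body: list[str] = []
    if label == "DCAS":
        for theme in [t for t in THEMES if t in themes]:
            body.append(_fill(_pick(pools["themes"][theme], rng), slots))
        pool_name = (
            "cessation_keyword_free"
            if rng.random() < keyword_free_rate
            else "cessation_keyword"
        )
        body.append(_fill(_pick(pools[pool_name], rng), slots))
        room = MAX_SENTENCES - 1 - len(body)
    else:
        room = MAX_SENTENCES - 1
        if rng.random() < spurious_keyword_rate:
            body.append(_fill(_pick(pools["spurious_keyword"], rng), slots))
            room -= 1
    n_filler = int(rng.integers(1 if not body else 0, max(room, 1) + 1))
    n_filler = min(n_filler, room)
    filler_pool = list(pools["filler"])
    for idx in rng.choice(len(filler_pool), size=n_filler, replace=False):
        body.append(_fill(filler_pool[idx], slots))

    sentences = [opener] + [_with_subject(s, male, rng) for s in body]
    return ". ".join(s[0].upper() + s[1:] for s in sentences) + "."


def _draw_themes(config: GeneratorConfig, rng: np.random.Generator) -> tuple[str, ...]:
    weights = [config.theme_weights[t] for t in THEMES]
    while True:
        mask = rng.random(len(THEMES)) < np.array(weights)
        if mask.any():
            return tuple(t for t, m in zip(THEMES, mask) if m)


def generate_corpus(config: GeneratorConfig) -> list[Narrative]:
    """Generate the full synthetic corpus.

    The positive count is Binomial(n_narratives, prevalence); positives get
    a non-empty theme set, theme-consistent text, and case-conditional
    covariates.  Identical config (including seed) gives a byte-identical
    corpus.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_narratives
    n_pos = int(rng.binomial(n, config.prevalence))
    pos_idx = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()

    width = max(6, len(str(n)))
    corpus: list[Narrative] = []
    for i in range(n):
        label = "DCAS" if i in pos_idx else "non-DCAS"
        themes = _draw_themes(config, rng) if label == "DCAS" else ()
        cov = sample_covariates(label, themes, config, rng)
        text = render_narrative(
            label,
            themes,
            cov,
            rng,
            keyword_free_rate=config.keyword_free_rate,
            spurious_keyword_rate=config.spurious_keyword_rate,
        )
        corpus.append(
            Narrative(
                id=f"N{i:0{width}d}",
                text=text,
                true_label=label,
                themes=themes,
                **cov,
            )
        )
    return corpus


def corpus_to_frame(corpus: Sequence[Narrative]):
    """Corpus as a pandas DataFrame (without the latent truth columns)."""
    import pandas as pd

    rows = []
    for nar in corpus:
        d = asdict(nar)
        d.pop("true_label")
        d.pop("themes")
        rows.append(d)
    return pd.DataFrame(rows)


def truth_to_frame(corpus: Sequence[Narrative]):
    """Latent-truth sidecar: id, true_label, semicolon-joined themes."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [n.id for n in corpus],
            "true_label": [n.true_label for n in corpus],
            "themes": [";".join(n.themes) for n in corpus],
        }
    )


def write_corpus_csv(corpus: Sequence[Narrative], corpus_path, truth_path=None) -> None:
    """Write the corpus as UTF-8 CSV (text quoted), truth as a sidecar CSV."""
    frame = corpus_to_frame(corpus)
    frame.to_csv(corpus_path, index=False, quoting=csv.QUOTE_NONNUMERIC)
    if truth_path is not None:
        truth_to_frame(corpus).to_csv(truth_path, index=False)
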
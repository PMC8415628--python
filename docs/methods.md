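# Methods

`dcas` implements a classifier-guided procedure for estimating the frequency
of a rare circumstance — driving cessation associated suicide (DCAS) — among
free-text death-registry narratives, together with the cohort statistics used
to characterize identified cases. Because the registry narratives the method
is designed for are restricted-access, the package ships a synthetic corpus
generator with known latent truth, and every stage is specified, tested, and
exercised end-to-end on synthetic data.

## The estimation procedure

The target quantity is the number (and proportion) of registry decedents
whose narrative explicitly describes driving cessation: inability to drive,
avoidance of driving, pressure to stop driving, or declining driving ability.
At ~0.5% prevalence a simple random annotation sample is hopeless (a
200-narrative sample would contain roughly one case), so labeling is
concentrated where cases are likely:

1. **Keyword seed round.** All narratives are screened for four keywords
   ("drive", "license", "vision", "DMV"; case-insensitive substring match, so
   "driver" hits "drive"). Narratives are binned by the exact matched subset.
   Large single-keyword bins contribute a fixed random draw (60 total,
   allocated proportionally with largest-remainder rounding); all other
   keyword bins are reviewed exhaustively; a fixed draw (34) from the
   no-match bin anchors the base rate. Annotation of this sample yields the
   seed labeled set with a workable case/non-case balance (~1:3).
2. **Text preparation.** Lowercase; punctuation replaced by spaces
   (standalone numbers are kept — ages carry signal); a pinned English
   stopword snapshot removed; Porter stemming; unigrams plus adjacent
   bigrams formed on the post-stopword, post-stem sequence; counts assembled
   into a sparse document-term matrix; TF-IDF weighting
   `tf(d,t)/|d| * log2(N/df(t))`; terms with document frequency below
   `ceil(0.0005 * N)` pruned (inclusive retain). The TF-IDF dialect is
   pinned deliberately so results are reproducible across environments; it
   is not scikit-learn's default variant. The vocabulary is fitted on the
   full corpus (labeled + unlabeled), matching the procedure's order of
   operations.
3. **First forest.** A 1,500-tree random forest (sqrt-p candidate features
   per split, no class weighting) is cross-validated with stratified 5-fold
   out-of-fold probabilities and refit on all labeled rows. Out-of-fold
   metrics at threshold 0.5 are the honest per-round performance report.
4. **Probability-bin annotation round.** Unlabeled narratives are binned by
   predicted probability into [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8),
   [0.8,1.0] (lower-inclusive; top bin closed) and 20/20/30/20/20 narratives
   are drawn for annotation — extra weight on the uncertain middle bin.
   New labels are merged with full provenance; conflicting labels for an id
   are a hard error, never an overwrite.
5. **Second forest** on the expanded labeled set, same settings.
6. **Threshold review.** Remaining unlabeled narratives scoring >= 0.5 are
   "flagged" and each is reviewed, partitioning them into confirmed true
   positives and false positives.
7. **Key-phrase sweep.** The < 0.5 remainder is searched with a list of
   specific cessation phrases (literal, case-insensitive, with `*` as a
   short word gap). Hits are counted as false negatives of the classifier.

**Sweep-completeness assumption.** Treating the sweep as exhaustive makes
every unflagged, unswept narrative a true negative, which closes the
confusion matrix: TP/FP from review, FN = sweep hits, TN = the rest. The
final estimate is `labeled positives + confirmed flagged + sweep
recoveries`, a deliberate *slight underestimate* because no phrase list is
exhaustive. A sensitivity-analysis mode (`sweep_recall < 1` in
`finalize_cases`) scales FN by 1/recall; it is off by default. Metrics whose
denominator is zero are reported as absent, never as zero.

## Cohort statistics

Identified cases are compared with non-cases variable by variable, with the
test chosen per variable in a spec (never auto-detected): chi-square with
Yates continuity correction for 2x2 tables, exact Fisher for sparse R x C,
Welch t, or Mann-Whitney U. Missing/unknown categories are retained as
explicit levels. The Yates default reproduces the conventional reporting of
registry tables at this scale. For R x C Fisher tests the p-value is
computed by exact enumeration over tables with the observed margins when the
enumeration space is small (<= 2e5 tables) and otherwise by seeded Monte
Carlo sampling from the fixed-margin null (19,999 resamples, the approach of
R's `simulate.p.value`), so large registry-scale tables remain tractable and
reproducible.

Odds-ratio homogeneity across strata (e.g. the physical-health association
across age groups) uses the Breslow-Day test around the Mantel-Haenszel
common odds ratio (statsmodels; Tarone adjustment selectable). Time trends
in annual case counts use a log-linear Poisson GLM fitted by IRLS, with the
0-based calendar-year index as the only covariate and no offset, restricted
to the early-reporting registry states; the slope's Wald p-value is
reported.

## The synthetic corpus generator

The generator emulates the features of coroner/medical-examiner narratives
that this pipeline is sensitive to, and nothing more:

* **Rarity.** Positive count ~ Binomial(n, prevalence), default prevalence
  0.005.
* **Themes.** Positives carry one or more of four themes (functional
  impairment, car accident, substance use, employment loss), drawn as
  independent Bernoulli with marginals proportional to the observed theme
  mix among cases (157/43/68/26 of 305), conditioned on at least one theme.
  Pairwise co-occurrence is therefore induced by the marginals rather than
  being a separate knob.
* **Lexical structure.** Sentence-slot templates (opener + one sentence per
  theme + one cessation clause + fillers; 2–6 sentences). The cessation
  clause comes from a keyword-bearing pool with probability
  `1 - keyword_free_rate` (default 0.2) and otherwise from a keyword-free
  pool ("no longer had any means of transportation", ...). Negatives carry a
  spuriously keyword-bearing sentence ("found in the driver's seat",
  "the television was still on") at rate `spurious_keyword_rate` (default
  0.01, matching the ~1% keyword hit rate a registry-scale screen produces).
  Verb-initial sentences are prefixed with "The victim"/a pronoun at random
  in both classes so no subject word carries label signal. Phrase pools are
  versioned package data; seed keywords appear only in the two pools meant
  to carry them (a property the test suite pins).
* **Covariates.** Class-conditional parametric draws with defaults taken
  from the observed case and non-case margins (e.g. 84.9% male, mean age
  71.2 among cases) plus per-theme age overrides (substance-theme cases are
  younger, mean 63.2). Ages are truncated at 55 — the sampling frame's age
  floor — and the configured mean is the mean of the *truncated*
  distribution: the generator solves for the pre-truncation normal location
  (Brent root-find on the truncated-normal mean), because naive truncation
  of N(63.2, 7.64) at 55 would inflate the mean to ~65.2. When a positive
  carries several themes the youngest-mean theme's age distribution wins.
  Covariates are conditionally independent given class and theme; the
  generator does not model covariate–text mutual information beyond the
  theme sentences.
* **Determinism.** One integer seed; identical configuration gives a
  byte-identical corpus.

The default key-phrase list for the sweep is a documented reconstruction
from commonly used cessation phrasings; it intentionally does not cover
every generator phrasing (two of the ten keyword-free variants are
uncovered), so the sweep-complete estimate stays a mild underestimate, as
the method expects on real data.

**What passing tests show — and don't.** Synthetic narratives are templated:
vocabulary is small, phrasing heterogeneity is bounded, and the classifier's
cross-validated F1 (~0.9) is far higher than is achievable on real
registry text. Passing the recovery tests demonstrates that the pipeline's
machinery (screening, featurization, classifier-guided annotation, sweep,
bookkeeping) is correct and that the estimate behaves as designed under
known truth — not that real-data performance will match.

## Numerical and design choices

* Stemming is the classic single-pass Porter (1980) algorithm, implemented
  in-package with a memoised lookup. Porter is not idempotent
  ("licenses" -> "licens", but re-stemming gives "licen"), so stemming is
  applied exactly once; the idempotence property holds for (and is tested
  on) the rest of the normalization pipeline.
* Sparse-term pruning uses the inclusive-retain reading
  (`df >= ceil(fraction * N)`); the row set and surviving document
  frequencies are unchanged by pruning, and TF denominators are the
  original per-document token totals, so TF-IDF and pruning commute.
* Prediction requires the exact training vocabulary; a permuted column
  order is realigned silently, anything else is an error naming the
  offending tokens.
* Forest seeds, sampling seeds and the annotator's seed all derive from one
  pipeline seed via `SeedSequence` spawning; a (seed, plans) manifest
  replays every intermediate artifact exactly.
* Over-requests in any stratified draw are capped at the stratum size with
  a logged warning rather than an error, since bin sizes are
  data-dependent.
* Degenerate inputs fail loudly: empty corpora, single-class training
  labels, folds exceeding the minority class, zero-margin tables, single
  strata, all-zero count series, probabilities outside [0, 1].

## Problem sizes used by the test suite and acceptance script

The recovery experiment runs the full pipeline on ten seeded corpora of
20,000 narratives at 0.5% prevalence with `keyword_free_rate = 0.2` and an
error-free oracle annotator; the estimate is required to cover the latent
case count within its 95% binomial envelope in at least 8 of 10 runs, with
a non-positive mean bias. Breslow-Day null calibration uses 1,000
replicates (two strata of 500, common OR 2.0); Poisson slope recovery uses
200 replicates of a 15-year series with slope 0.10. `scripts/acceptance.py`
runs one full pipeline at the same corpus scale and recomputes every
reported quantity from scratch.

## Known limitations

* The generator produces templated, low-entropy text; classifier metrics on
  it are optimistic relative to real narratives by construction.
* The shipped key-phrase list is a reconstruction, not the original study's
  supplementary list; real analyses should supply their own.
* The sweep-completeness assumption is untestable on real data; the package
  only quantifies its consequences under configurable sweep recall.
* Covariate draws are conditionally independent given class/theme; joint
  covariate structure (age x marital status, say) is not modeled beyond
  what the class and theme conditioning induces.
* The Poisson trend model has no exposure offset; it models counts, not
  rates, which matches a registry with a stable reporting base but not one
  with changing coverage.
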
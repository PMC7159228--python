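# Methods

## Problem and model

`dilipred` predicts whether a small molecule is likely to accumulate
hepatobiliary-disorder reports in a spontaneous adverse-event reporting
system, from numeric molecular descriptors alone. The pipeline has two
halves: a pharmacovigilance half that turns raw report lines into labeled
drug cohorts, and a machine-learning half that learns a descriptor-based
classifier from those cohorts.

### Disproportionality analysis

Reports are reduced to (primary-suspect drug, event) pairs — every event in
a report is attributed to that report's single primary-suspect drug — and
consolidated into a count matrix. For a drug against a target event class
(in the motivating use case, the MedDRA System Organ Class "hepatobiliary
disorder"), the 2×2 contingency table with cells a (drug & event), b (drug &
other events), c (other drugs & event), d (neither) gives the Relative
Reporting Ratio

    RRR = a·N / ((a+c)·(a+b)),   N = a+b+c+d,

the ratio of the observed pair count to its expectation under row-column
independence. Significance comes from the Fisher exact test with margins
fixed. Sidedness is configurable; the default is one-sided (greater),
because the positive-labeling rule already demands enrichment (RRR > 1), and
a two-sided variant is available by flag. No multiple-testing correction is
applied by default — the labeling rule is stated on raw p-values — but a
Benjamini-Hochberg q-value can be attached.

Degenerate tables (zero drug or event margin) raise an explicit error
rather than silently reporting 0/0 as zero.

### Cohort rules

* **Positive**: ≥ `min_reports` (default 13) target-event reports, RRR
  strictly > 1, p strictly < 0.05. The report floor is inclusive; the other
  two are strict.
* **Negative**: exactly zero target-event reports and at least
  `min_market_years` (default 10) years on the market, so that the absence
  of reports is informative rather than an artifact of recency. The
  market-years table is user-supplied input; the package takes no position
  on whether it is derived from patent or approval dates.

The rules are mutually exclusive by construction. All rule-satisfying drugs
are returned; any further subsetting is left to the caller.

### Descriptor preprocessing

The modeling half is descriptor-agnostic: it takes a compounds × named
numeric descriptors table. An optional backend computes RDKit's 2D
descriptor panel from SMILES; this is a documented stand-in for commercial
panels, not a reproduction of any of them. Preprocessing:

* drop descriptors with zero variance on the fitting rows (these cannot be
  scaled) and exact duplicate columns (first name in column order wins);
* impute remaining missing values by the fitting-set median — chosen for
  robustness and determinism;
* standardize each retained descriptor to mean 0, sd 1 (ddof = 0, so the
  fitting-set variance is exactly 1). Margin-based classifiers are
  scale-sensitive, so standardization defaults on; it can be disabled.

The fitted parameters are frozen in `ScalingParams` and reapplied verbatim
at prediction time; applying them to the fitting set reproduces the
preprocessed matrix bit for bit.

### Balanced-trial ensemble

With n₊ positives and n₋ negatives (n₋ ≥ n₊ in the motivating data, e.g.
155/164), each of `n_trials` (default 500) trials:

1. draws n₊ negatives without replacement (undersampling; if positives are
   the majority they are undersampled instead, with a warning);
2. holds out ⌈0.1·class size⌉ of each class, trains on the remaining 90%;
3. ranks features by recursive elimination on the training rows: fit a
   linear SVM with penalty `cost`, score features by squared weight, drop
   the lowest block down to the next schedule size, repeat. The default
   schedule halves the surviving count down to 10 with the target `top`
   inserted; survivors of the last step are ordered by the final fit's
   importances. The kernel defaults to linear — required for weight-based
   ranking and interpretable; an rbf variant with permutation-importance
   ranking is selectable;
4. keeps the `top` ranked features, refits, and scores the held-out 10%
   with libsvm's Platt-scaled probabilities;
5. records AUC, the Youden-J-optimal decision probability (classification
   is positive iff probability strictly exceeds the threshold; ties in J go
   to the smallest candidate threshold), and confusion metrics at that
   threshold.

The (cost, top) grid (defaults cost ∈ {0.01, 0.1, 1, 10, 100}, top ∈ {5,
10, 15, 20, 30, 50, 100, 200, 400}) is scored by the arithmetic mean of
each metric over valid trials; the RFE ranking is computed once per (trial,
cost) and shared across top values, i.e. the same splits are reused across
the whole grid. Ties in mean AUC break toward smaller top, then smaller
cost (parsimony). Trials whose held-out set is single-class have no defined
AUC; they are flagged and excluded from that cell's averages with a logged
count, and a cell with no valid trials is marked missing and can never win.
A metric with an empty denominator (e.g. PPV with no predicted positives)
is excluded from its mean rather than counted as zero. The whole grid
search is bit-identical under a fixed master seed: every trial split,
ranking and classifier seed derives from (seed, trial, cost, top) indices.

### Consensus and the final model

Feature selection varies across trials, so the deployable feature set is
chosen by frequency: count, over all trials at the winning (cost, top), how
often each descriptor was selected; rank by count, break ties by better
mean within-trial rank and then name; keep the top `top`. The final
classifier is refit on the **full labeled pool** (all positives plus all
negatives — the data never states a canonical final training draw, and
using everything with inverse-class-frequency weighting approximates the
balanced objective the trials optimized) restricted to the consensus
features, and its decision threshold is the mean per-trial Youden-J
probability at the winning cell.

The model is serialized as plain JSON (weights or support vectors,
intercept, Platt sigmoid A/B, scaling parameters) plus a feature-list text
file. Prediction after loading uses a native decision-function + Platt
path. One numerical subtlety: libsvm does not expose the Platt sigmoid
directly — even in the binary case it runs the Wu-Lin-Weng pairwise
coupling iteration with stopping tolerance 0.005/k, which perturbs the
sigmoid by up to ~2.5·10⁻³. The native path replicates that iteration, and
the orientation of the internal decision value (which depends on the class
order libsvm encountered) is validated against the fitted classifier at
save time, so save/load round trips preserve predictions to < 10⁻¹².

## Synthetic data

* **Report streams**: each report draws a drug from a weight vector
  (uniform by default) and one event from that drug's event distribution;
  planted (drug, event) pairs have the event probability multiplied by a
  relative-risk factor ≥ 1 and renormalized. The generator returns the
  exact expected count of every planted cell alongside the realized counts,
  so disproportionality statistics can be checked against ground truth.
  Defaults: 50 drugs, 30 events, 20 000 reports, one pair planted at
  relative risk 8. Not emulated: MedDRA vocabulary structure, report
  demographics, case-version duplication, multi-drug reports.
* **Descriptor tables**: features have unit marginal variance and
  equicorrelation ρ (default 0.3) within blocks of 10, mimicking redundant
  descriptor panels; a chosen number of informative features — spread
  across distinct blocks — is mean-shifted by a standardized effect size in
  the positive class; values can be masked missing at random. Defaults
  mirror the motivating cohort geometry: 155 positives, 164 negatives, 818
  features, 15 informative at effect size 1. Real descriptor distributions
  are heavier-tailed and their correlation is not block-structured, so
  passing tests demonstrate correct mechanics and statistical calibration,
  not field performance on real compounds.

## Problem sizes used in tests and acceptance

The test suite and `scripts/acceptance.py` run a reduced desk-scale
profile chosen to exercise every code path at tight runtimes: 200 features
with 155+155 compounds and 100 trials for planted-feature recovery, 50
trials for null calibration on permuted labels, 20 trials for the separable
limit, and 100 seeded 20k-report simulations for signal-detection power.
The Fisher implementation is verified against an exact rational enumeration
oracle over every 2×2 table with margins ≤ 12.

## Known limitations

* Real FAERS ingestion subtleties — legacy/new file eras, case-version
  deduplication, role-code vagaries — are out of scope; the two supported
  dialects carry the five fields the method consumes. Reports are
  aggregated as given, without case deduplication.
* Exact-match drug-name normalization drops misspelled or dose-annotated
  names by design; coverage depends entirely on the supplied synonym table.
* The probability model is libsvm's Platt scaling fit during training;
  no further recalibration is attempted.
* With strongly separable data the Youden-J threshold sits far from 0.5
  (any threshold between the classes is optimal and the smallest candidate
  is taken), so thresholds are only comparable across models trained on
  similar difficulty.
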
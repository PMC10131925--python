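# Methods

This package re-implements, as a tested pipeline over synthetic data, two
machine-learning experiments on patient-navigation (PN) tracking logs: a
single-label experiment comparing data-preparation strategies, topic
featurization of navigator notes and five classifiers, and a multi-label
experiment that harmonizes two incompatible site codebooks, augments the
demographics with travel information, and evaluates a fixed nine-layer
1-D convolutional network.  The original study data are privacy-protected
navigation records and are not recomputable here; every operation that
produced the original numbers is implemented and validated on synthetic
cohorts with known ground truth, and the one analysis that *is* exactly
recomputable — the confusion-row composition and grouped-confidence
arithmetic, which depends only on printed prediction-row counts — is
reproduced to the digit.

## The data model

A tracking log is a pair of CSV tables.  The demographics table carries
one row per patient (age, occupation, marital status, education, English
level, origin, year of arrival, zip code, household size, nativity,
income range).  The encounter table carries one row per navigation
interaction (preferred/all languages, service type, channel, action taken
and its length in minutes, free-text navigator comments, and zero or more
SDoH codes from a 22-category taxonomy plus the wildcard `none` and the
write-in `other`).

Missing handling follows the original protocol: numeric blanks take the
column mean, categorical blanks take the most common observed value, and
encounters whose comments or SDoH codes were never recorded are dropped
from strategy inputs rather than imputed.  Two choices the protocol
leaves open are fixed deterministically: mode ties resolve to the
lexicographically smallest value, and imputation statistics are computed
on the full dataset (not per CV fold).  The latter mirrors the original
procedure but is a known, mild leakage channel: fold-wise test rows
contribute to the means/modes used to fill blanks.  Topic models, one-hot
dictionaries and feature scaling, by contrast, are fitted inside each
training fold by default.

The site-A taxonomy ships with 22 substantive categories.  The source
codebook's printed list is partially reconstructable; two slots
(`employment`, `case_management`) are illustrative fill-ins and the whole
codebook — like the site-B alias map — is plain data a user can replace.

## The synthetic cohort generator

The generator is the testbed's definition of "truth", so its defaults are
fixed once and document what they emulate:

- **Cohort size** 330 patients (site A) and 478 (site B), the sizes of
  the navigation programs being emulated.
- **Encounter counts** per patient are negative-binomial with mean 16.94
  and SD 13.06 — the moments reported for the combined cohort — giving
  the overdispersion real navigation logs show (many brief navigations, a
  long tail of intensive ones).
- **SDoH assignment** is multi-label per encounter: each category fires
  as an independent Bernoulli whose log-odds are a base-rate logit plus
  `signal_strength` times planted demographic shifts and topic-mixture
  shifts.  The default base rates make language/interpreter dominant
  (0.60 per encounter), mirroring the heavy class imbalance of a
  limited-English cohort; an encounter where nothing fires records
  `none`.
- **Notes** are bag-of-words samples: a Dirichlet(0.3) topic mixture per
  encounter, words drawn from small per-topic vocabularies, length
  Poisson with mean 12.  This is sufficient structure for LDA to recover
  topics; no grammar, code-switching or bilingual text is modeled — real
  navigator notes are bilingual and telegraphic, so passing tests here
  say nothing about tokenization robustness on such text.
- **Site B** differs exactly where the second study did: two-level
  `generic:specific` SDoH codes, exactly one code plus an action per
  encounter, a 3-level employment variable, and no note text; the
  wildcard `none` dominates its code distribution.
- **Missingness** is injected per column at small rates (2–8%) after the
  ground truth is recorded.

Everything is a pure function of `(config, seed)`; identical seeds give
byte-identical logs.

## Experiment 1

**Preparation strategies.** Six rules convert a patient's longitudinal,
multi-label encounter history into single-label instances.  Each
encounter is first reduced to its *salient* SDoH — the recorded code with
the highest corpus-wide frequency, ties lexicographic.  S1 scans a
patient's encounters in date order up to and including the first whose
salient SDoH is not language/interpreter; that code labels the patient
and the scanned window is aggregated (numeric fields mean, categorical
mode, note texts concatenated).  A patient whose encounters are all
language-salient is labeled language/interpreter from the first encounter
alone.  S2 drops language-labeled S1 instances; S3 makes every encounter
an instance labeled with its own salient code; S4 is S3 without language;
S5/S6 are S1/S2 with encounter-derived features removed.  Whether the
"leading up to" window includes the triggering encounter is genuinely
ambiguous; the default includes it (its note presumably discusses the
labeled barrier) and the exclusive reading is selectable.

**Topic features.** Notes are lowercased, punctuation-stripped,
whitespace-tokenized and fed to latent Dirichlet allocation with
symmetric priors and a fixed seed; each document becomes k probabilities
(k ∈ {5, 10, 15, 20, 25, 30}; no data-driven k selection by design).
Empty or fully out-of-vocabulary notes map to the uniform vector — no
information, no bias.  The LDA iteration budget defaults to 500; the
analysis drivers use 50, which is converged for these small vocabularies,
and fitted fold models are shared across the five classifiers of a grid
cell (fold membership does not depend on the classifier).

**The grid.** 4 note strategies × 6 topic counts × 5 classifiers plus
2 demographic strategies × 5 classifiers = 130 configurations.  The five
classifiers (logistic regression, random forest, support vector machine,
a one-hidden-layer neural network, Gaussian naive Bayes) use standard
library defaults, recorded in code.  Each configuration is scored by
10-fold cross-validated plain accuracy; folds are stratified where every
class has at least 10 members, and for the per-encounter strategies
(S3/S4) folds are grouped by patient by default, since repeated
demographics across a patient's encounters would otherwise leak between
train and test.  Ungrouped folds are available and are optimistic.

**Confusion-row analysis.** Pooled held-out predictions form a count
matrix with rows = predicted class and columns = true class (the
orientation of the original narration).  `row_composition` reports each
prediction row's true-class makeup; `grouped_confidence(row, m)` is the
share of the row covered by the predicted class plus its m−1 largest
co-occurring true classes — the device used to identify clusters of
co-confused SDoHs.  From the published row counts these reproduce
79.2% (137/173) language true positives, a 95.4% language+social+fear
cluster, 64% fear accuracy with a 21/22 top-4 cluster, 63%/88% for
social support, and 56%/85% for insurance.  (21/22 is 95.45%, printed as
96% in the source — a rounding artifact of the original text; the
package reports the exact fraction.)

## Experiment 2

**Harmonization.** Site-B codes map to the unified (site-A) taxonomy:
a specific code with a direct correspondence wins, otherwise the generic
parent's correspondence applies, otherwise `other`.  Only demographics
shared by both sites survive; values recode toward the richer codebook
(site-B's 3-level employment joins site-A's occupation categories);
non-ASCII (foreign-language) entries become `none`; unspecified codes
become `chose not to answer`/`other` where those exist, else `none`;
numeric blanks take column means; patients with zero encounters are
excluded.  Per patient, the three most frequent barriers and the three
most frequent interventions are kept (ties by first occurrence, then
lexicographic).

**Intensity bins.** Encounter counts bin into L/M/H/VH with thresholds
(3, 16, 29): below 3 is L, [3, 16) M, [16, 29] H, above 29 VH — the
boundary reading that matches "<3", "between 3 and 16", ">29".  The
fixed thresholds are the default (`paper` mode); `derived` mode
recomputes round(mean−sd, mean, mean+sd) from the cohort, and degenerate
zero-spread counts raise rather than silently producing one bin.

**Travel augmentation.** Nearest hospital, distance (km), drive and
transit minutes are looked up by zip code through a provider interface.
No live map service is ever called: the repository ships a fixture
provider (exact tuples from a CSV) and a synthetic provider (haversine
distances on deterministic pseudo-coordinates, drive time at 40 km/h
plus 5 minutes, transit at 2.2× drive, transit absent for a
deterministic subset of zips).  Absent transit times take the mean of
observed ones, as in the original procedure.

**The network.** Nine layers, fixed: Conv1D (10 filters, kernel 3,
ReLU) over the feature vector as a length-n sequence with one channel;
MaxPool1D (pool 2, stride 2); Flatten; then three (Dropout 0.25, Dense)
pairs with widths 3C, 2C, C for C classes, the last sigmoid.  Loss is
mean binary cross-entropy, so each class is scored independently;
predictions threshold the sigmoid outputs at 0.5.  The network is
implemented directly on numpy (explicit forward/backward passes,
inverted dropout, Adam), deterministic under a fixed seed, and
`verify_architecture` audits the live model against this layer list.

Training defaults are 100 epochs, batch 16, Adam at 3e-3.  The batch
size and step were chosen for optimization reliability: with larger
batches at 1e-3 the conv+pool front end — which sees edge features of
the sequence through only a single pooled unit — intermittently failed
to learn rules planted on first-position features.  Inputs are
standardized per training fold.

Evaluation is 10-fold cross-validation accumulating per-class
correct/incorrect counts (correct + incorrect = n for every class).
Per-class accuracy is the reported metric; with a dominant `none` class
this is an optimistic number for rare classes, which is precisely the
bias the per-class breakdown is meant to expose.  Intensity (L/M/H/VH)
is predicted from demographic columns with a support vector classifier,
and attribute–SDoH relationships are Pearson product-moment correlations
(identical to point-biserial for binary/numeric pairs), with
zero-variance columns reported as undefined rather than dropped.

## Problem sizes and numerical choices

The shipped analyses and checks run at desk scale, chosen once: the
default simulated cohorts are 330/478 patients; the grid driver defaults
to the patient-level strategies at k=15 only (the full 130-cell grid,
including the much larger per-encounter instance tables of S3/S4, is a
flag away); signal-recovery
checks use 1000-patient cohorts with the planted links scaled by 3 and a
label-permutation null on the same folds; the CNN recovery check uses
1500 instances whose labels are deterministic functions of three binary
features.  Mode and salience ties are lexicographic everywhere;
encounter order is by recorded date with file order breaking ties; all
stochastic steps (generation, fold shuffling, LDA, forest and network
initialization, dropout) are seeded.

## Known limitations

- Synthetic notes are monolingual token streams; real navigator notes
  are bilingual/code-switched and may defeat the whitespace tokenizer.
- The site-B alias map and parts of the site-A codebook are
  illustrative; users harmonizing real logs must supply their own.
- Per-class accuracy on imbalanced multi-label targets overstates
  performance on rare classes; sensitivity/recall per class is the
  sterner metric and is derivable from the confusion outputs.
- Full-dataset imputation (kept for fidelity) leaks fold information
  slightly; the effect is small relative to the class imbalance but is
  not zero.
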
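# Methods

This note records the models, conventions and numerical choices behind
`pepagg`, and what its synthetic benchmarks do and do not establish.

## The signal: deprotection-peak broadening

Every coupling cycle on a flow synthesizer removes an Fmoc group, and
the removal by-product produces one UV absorbance peak. On-resin
aggregation — β-sheet formation between resin-bound chains — slows
reagent access and broadens this peak. The package quantifies a step's
aggregation state by the **aggregation factor**

AF = Wⁿ − Hⁿ, with Wⁿ = 100·FWHM_n/FWHM₁ and Hⁿ = 100·h_n/h₁,

both normalised to the first coupling of the same synthesis. Reading
the width term as the full width at half maximum makes AF a pure
broadening measure: a step whose peak broadens by more than 20%
relative to the first coupling (at unchanged height) has AF > 20, the
calling threshold. The comparison is strict (`AF > 20`); the boundary
convention is configurable but strict is the default because the
threshold is defined as an exceedance.

Peak metrics are extracted without any fitting: the baseline is the
median of the outer 5% of samples (robust, parameter-light), the height
is the maximum above baseline, and the FWHM comes from linear
interpolation of the two half-maximum crossings flanking the maximum.
Malformed peaks (no excursion above baseline, fewer than two crossings)
raise an error carrying the offending step index rather than producing
a silent number.

His and Cys couplings require a reactor temperature change that
broadens the peak for reasons unrelated to aggregation, so their
(height, FWHM) pairs are replaced by linear interpolation between the
nearest non-special neighbouring steps before AF is computed; leading
or trailing runs copy the nearest valid step. Interpolating the raw
metrics rather than the AF keeps interpolated steps reference-consistent.
The reference is step 1 *after* interpolation.

## Curation and label framings

Records are filtered in a fixed order: drop any sequence containing a
non-canonical symbol, drop sequences shorter than 5 residues, truncate
longer sequences to the C-terminal 20 residues (the first 20 synthesis
steps — synthesis runs C→N and aggregation is resin-proximal), then
drop exact duplicates keeping the first occurrence. If truncation
removes the onset step, the retained fragment never aggregated and is
relabelled non-aggregating: labels describe the modelled fragment.

Stepwise framing expands each record into per-prefix rows. By default a
prefix is aggregating iff it reaches the onset (aggregation is
irreversible within a synthesis). The windowed variant labels only
steps within `[onset − w_before, onset + w_after]` as positive and
*drops* steps beyond the window, because the post-onset tail is
uninformative once every later step is positive by construction.

## Representations

All vectors index residues alphabetically (A C D E F G H I K L M N P Q
R S T V W Y). Positional encodings (tokens, one-hot, per-residue Morgan
fingerprints at radius 3 / 128 bits) are assembled in synthesis order,
so feature block *i* always describes synthesis step *i* and aligns
with stepwise labels; the encoder functions themselves are
direction-agnostic and encode the string they are given. Fingerprints
default to the free amino-acid structures; a table of the
side-chain-protected Fmoc building blocks ships alongside because the
protected species are what the resin actually sees — which table is
right depends on the question, so both are provided and the choice is
explicit in the encoder config. The composition vector divides residue
counts by length (order-invariant, sums to 1); dipeptide counts are the
400 ordered adjacent pairs read N→C.

## Cross-validation harness

Fivefold CV uses a seeded random permutation without stratification;
each fold is the test set once and the mean ± sd of the five test
accuracies is reported (balanced accuracy is logged alongside). In the
stepwise framing, folds are drawn at the *sequence* level so no peptide
contributes prefixes to both sides of a split, and sequence-level
accuracy calls a peptide aggregating iff any of its prefixes longer
than 6 residues — the shortest chain that can form secondary
structure — is predicted positive. The model grid (XGBoost, random
forest, k-NN, Gaussian process) runs with library-default
hyperparameters, mirroring the protocol of the study it reproduces.

The shuffling control replaces every sequence by a reproducible uniform
permutation of itself (deterministic in record id and seed; composition
preserved exactly) and reruns the grid, pairing each cell with its
original accuracy. Composition features are permutation-invariant, so
their deltas are exactly zero by construction — that identity is a
correctness check, not a finding.

## Synthetic benchmark

The generator defines the package's study conditions.

**Sequences** are drawn composition-first: per-peptide residue weights
from a symmetric Dirichlet with concentration 0.5 (real peptides use a
skewed subset of the alphabet; this gives ~7–9 distinct residues in a
15-mer), counts multinomial at a uniform random length in 8–20,
placement uniformly random.

**Labels** follow p = σ(β·c + b) on the realised composition, flipped
with probability 0.05 (`label_noise`). The default β puts Ser, Ile,
Val, Thr at +2 and Phe, Asp, Tyr, Arg at −2 — the strongest promoters
and reducers — with Gln, Leu at +1 and Cys, His, Pro at −1 as
secondary contributors, all other residues neutral. With bias 0 this
yields ≈49% aggregating and a Bayes accuracy of ≈0.59, deliberately in
the accuracy regime real AFPS datasets occupy. A positional variant
drives labels from the proximal-minus-distal half-composition contrast
instead; it is the negative control for shuffling experiments (whole-
sequence composition is then uninformative) and defaults off.

**Traces** are Gaussian peaks (baseline height 1 a.u., FWHM 8 s,
sampled at 240 points over a window wide enough that the outer 5% of
samples stay at baseline even for a maximally broadened peak). From the
planted onset step onward — the onset step itself included, so the
onset is the first broadened peak — FWHM multiplies by 1.25 per step,
saturating at 4× baseline, and height decays by 10% per step; Gaussian
absorbance noise (default sd 0.01) is added. The broadening dynamics
are phenomenological placeholders chosen to exercise the threshold, not
estimates of real AFPS behaviour. Onsets for aggregating records are
drawn uniformly from steps 5–15 (the empirically observed window),
clipped to the sequence. Because real labels come *from* the analyzer,
the generator only plants onsets the analyzer can call exactly: His/Cys
interpolation erases broadening confined to a trailing H/C run and
bleeds an onset backwards across an adjacent run, so the sampled onset
is moved to the nearest step whose residue and predecessor are both
non-special (never step 1, the reference).

**Bayes accuracy.** For a composition c the optimal decision attains
max(q, 1−q) with q = (1−ε)p + ε(1−p); this is exact per composition
and averaged by Monte Carlo (10⁵ draws) over the generator's own
composition law. It is the ceiling the CV harness is calibrated
against.

## Attribution

Per-residue contributions are exact TreeSHAP values (log-odds scale)
from XGBoost's built-in `pred_contribs`, averaged over an ensemble of
models trained on 50 seeded random 80/20 splits; a single small-data
tree fit yields noisy Shapley values and the ensemble averages that
noise away. The split models default to the same additive regularised
boosting as the recommender members — deep default trees attribute so
noisily on small composition datasets that neutral residues crowd into
the extremes of the ranking — except for dipeptide attribution, where
the 400 count features are sparse and the additive config's
`min_child_weight` would veto splits on rare motifs; there the models
keep library defaults. SHAP values are computed on all samples per split by
default (maximising coverage of the proportion grid; a held-out-only
flag exists). A residue's headline contribution is its mean SHAP over
samples where it is present — absent residues carry no evidence — and
the ranking breaks ties alphabetically. Contribution curves bin mean
SHAP by observed proportion (quantile bins), so they are defined only
where data exist. Local accuracy (contributions plus base value equal
the model margin) holds to float32 rounding (~1e-6 relative) and is
asserted in the tests at 1e-5.

Because composition features live on the simplex, a neutral residue's
conditional contribution is not exactly zero (raising its fraction
displaces mass from the others), and attribution questions are only
well-posed when the planted effects are strong enough to dominate that
displacement at the benchmark sample size. The attribution benchmark
therefore plants ±5 log-odds on the promoter/reducer quartets — the
smallest magnitude at which an exact-model oracle (unregularised
logistic regression on the planted data, an estimator independent of
the SHAP path) identifies the quartets reliably at n = 1000 — and then
requires the SHAP ensemble to match that capability.

## Recommender

The ensemble trains each of 100 XGBoost members on a seeded random 80%
subsample (seeds derived as master + i; a single-class subsample is
re-drawn with the next derived seed and logged). The prediction for a
sequence is the fraction of members voting "aggregating"; the verdict
threshold is a strict majority (> 0.5).

Members default to depth-1 (additive) boosting with mild regularisation
(`min_child_weight=10, reg_lambda=10, 300 trees, learning rate 0.1`)
rather than library defaults: aggregation propensity on composition
vectors is additive per residue, additive members match that structure,
and deep default trees produce spurious local non-monotonicities —
substitutions that lower the true logit but raise some members'
predictions — that corrupt counterfactual ranking. Members are also
*sign-consistent* by default: a pilot logistic fit on the training data
learns each feature's direction (mean-centred coefficients, since only
contrasts are identified on the simplex) and every member trains under
the matching monotone constraint. A member then agrees with its own
global trend everywhere, which makes counterfactual substitution scores
provably non-increasing in the learned directions; without the
constraint roughly 1% of candidates show spurious reversals regardless
of ensemble size. Both choices are one argument away
(`member_params={}`, `sign_consistent=False`).

Substitution advice models the pseudoproline building block: Ser and
Thr can be coupled as proline-like dipeptide derivatives that disrupt
β-sheet formation and revert to the native residue on deprotection. In
composition space this is surrogated as transferring the residue's
count to Pro. A composition model is position-blind, so candidate
positions (resin-proximal window 2–12, inclusive, 1-based from the C
terminus) are scored on the growing-chain prefixes that actually
contain them: for every synthesis prefix of length ≥ 6 including the
position, the ensemble vote is computed for the original and the
substituted sequence, and the score is the drop in the worst-case
(maximum) prefix vote. Candidates are ranked by score, ties going to
the position closer to the resin, where substitution acts earliest.
The candidate *set* depends only on sequence, window and replaceable
residues; scores only order it.

## What the benchmarks show — and what they do not

The synthetic experiments validate machinery, not chemistry: that the
analyzer recovers planted onsets exactly at zero noise and ≥95% at 2%
detector noise; that the CV harness tracks the planted Bayes ceiling
within 3 points at n = 2000 (using the additive gradient-boosted
learner and averaging over 3 benchmark replicates — deep default trees
sit several points below the ceiling at this signal strength, which is
a statement about default-tree statistical efficiency, not about the
data); that the SHAP ensemble recovers planted signs and quartets; and
that recommended substitutions never raise the worst-case prefix vote
under a planted strong Ser/Thr-vs-Pro contrast. Real traces have
asymmetric, drifting, overlapping peaks; real aggregation depends on
temperature, resin and protecting groups; and real composition effects
are far weaker than the planted quartets. Passing these benchmarks
therefore says the pipeline is correct and calibrated, not that its
real-data accuracy exceeds the ~60% the underlying signal supports.

Problem sizes used by the reproduction script (`scripts/acceptance.py`)
are the package's chosen benchmark conditions: 539 records for the
merge check, 200 planted traces per noise level, n = 2000 for the
shuffle and calibration experiments, 20 repeats of 50-split SHAP
ensembles at n = 1000, and 20 seeds of 25-member ensembles at n = 500
for recommender monotonicity.

## Known limitations

* Peaks are single Gaussians; no multi-peak deconvolution, tailing or
  drift, and no coupling-peak (as opposed to deprotection-peak)
  analysis.
* Non-canonical amino acids are out of scope end to end; pseudoproline
  chemistry enters only through its composition-space surrogate, and
  the dipeptide nature of the building block (it also caps the
  preceding residue) is not modelled.
* The protected-monomer fingerprint table describes the standard
  Fmoc/t-Bu protection scheme only.
* Source provenance is carried on every record but not used to weight
  training.
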
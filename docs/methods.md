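# Methods

## Problem framing

A proteinase cleavage site is a peptide bond between two consecutive
residues (P1 at 1-based position `p`, P1' at `p+1`). Prediction is cast
as binary classification of candidate bonds, each represented by an
even-size window `W = 2k` covering protein positions `p−k+1 … p+k`, so
that window sites `k` and `k+1` hold the bond residues (sites 11 and 12
for `W = 22`). Positions outside the protein are filled with the
complement symbol `X`; an `X` residue contributes zero to all 32 of its
features. The number of leading/trailing `X` equals
`max(0, k−p) + max(0, p+k−L)` for a length-`L` protein.

Positive windows are the annotated bonds; negative windows are sampled
uniformly without replacement from the pooled non-cleavage bonds of the
whole protein set, targeting an exact 3:1 negative:positive ratio
globally (per-protein allocation is not fixed — pooling is what makes
the global ratio exact). Train/test splitting is at protein level, so no
protein contributes windows to both sides; `evaluate_holdout` enforces
this and raises on overlap.

## Feature encoding

32 features per residue in fixed order: PSSM (20), disorder (1), Atchley
factors (5), solvent accessibility (2), secondary structure (3), site
frequency (1). Decisions taken where the encoding admits variants:

* **PSSM scores** are used raw (PSI-BLAST log-odds integers), with no
  sigmoid squashing; the reader consumes the standard ASCII matrix
  dialect and uses the first 20 score columns in the canonical order
  `ARNDCQEGHILKMFPSTWYV` (so `AA11_pssm_20` is conservation against
  valine at site 11).
* **Atchley factors** are the published five-factor solution embedded as
  an immutable 20×5 table, ordered (polarity, secondary structure,
  molecular volume, codon diversity, electrostatic charge).
* **Site frequency** is a lookup into a `W×21` table (20 amino acids +
  `X`) of symbol frequencies per window site, estimated from the
  training-positive windows. By default the table is built once from all
  training positives before cross-validation — matching the classical
  protocol — which leaks a small amount of label information into CV
  folds; `CleavageSiteModel.from_windows(..., freq_table=...)` accepts a
  fold-safe table for the leakage-free variant. The `X` override (zero,
  not the table entry) keeps padding inert.
* Input sequences with non-standard letters (B, Z, U, O, J, X) are
  rejected at parse time; an explicit `map_nonstandard` option coerces
  them to `X`, which encodes as zeros.

## Feature ranking (mRMR)

Mutual information is estimated by the discrete plug-in formula in bits
after binning each continuous feature into three states at thresholds
`mean ± α·sd` (α = 1 by default; both α and the log base are explicit in
the API so sensitivity can be explored). One-hot columns pass through as
binary states; zero-variance columns collapse to one state and get
relevance 0, ranking last. The mRMR criterion is the additive
(difference) form — relevance minus mean redundancy against the selected
set — not the quotient form. All ties break on the lower original column
index, making rankings exactly reproducible.

## IFS and model

Prefixes `S_i = {f_1 … f_i}` of the mRMR ranking are scored with
stratified 5-fold cross-validation (stratification chosen because the
3:1 class imbalance makes unstratified folds unstable at this scale;
fold assignment is window-level). The forest uses 100 bootstrap trees by
default (stable at desk scale; the classical toolkit-default of 10 is
one config field away), `m_try = ⌊log2 M⌋+1`, fully grown unpruned
trees, and majority vote with exact ties resolved to the positive class.
The optimal set is the prefix with maximal MCC, smallest prefix on ties
(parsimony). `run_ifs` accepts `max_prefix`, `step` or an explicit
prefix grid for coarse scans; capped runs are prefix-consistent with
uncapped runs because each prefix is evaluated independently under the
same fold seed. A zero factor in the MCC denominator yields MCC = 0 with
a warning; an undefined Sn/Sp is reported as NaN rather than silently
zeroed.

## Synthetic corpus

The generator emulates the study conditions of a curated cleavage-site
corpus so every stage runs without downloads:

* Proteins are drawn from a uniform background over the 20 amino acids
  (uniformity keeps the null calibration analytic; an empirical
  background is configurable). Lengths are uniform on 60–300 residues.
* Each planted bond overwrites its window-frame neighbourhood with motif
  emissions: by default site 11 (P1) is enriched for R/D and site 12
  (P1') for S/A/G, with mixing strength 0.85 — the effective emission is
  `strength·motif + (1−strength)·background`, so strength 0 is an exact
  null. The defaults echo the dominant P1 arginine/aspartate and P1'
  serine/alanine/glycine preferences of real protease specificity data,
  and were fixed once to give separability in the range of published
  cleavage-site predictors (MCC ≈ 0.6–0.9 depending on scale).
* Synthetic providers: PSSM rows are rounded Gaussian noise (sd 1) with
  +4 on the residue's own column, so profile argmax tracks sequence
  identity as a real profile's would; disorder is uniform noise (no
  signal, mirroring its marginal role); secondary structure is
  categorical (H/E/O at 0.35/0.20/0.45) with strand probability 0.5 in
  the four residues around each bond, and accessibility is buried with
  probability 0.5 background / 0.8 at the bond — the strand and burial
  skews reported for real cleavage sites.
* `default_scenario(seed)` reproduces the full corpus geometry exactly:
  371 training proteins carrying 578 positive windows with 1734 sampled
  negatives, 88 test proteins with 134/402 — site counts are allocated
  per split so the written S1-style sample tables round-trip to those
  counts. Every quantity derives from the one seed; re-runs are
  byte-identical.

What the generator does **not** emulate: residue composition bias and
homology structure within the protein set, protease-family-specific
extended specificity (only two sites carry sequence signal), correlated
errors of real PSSM/disorder/structure predictors, and annotation noise.
Passing tests therefore demonstrate that the pipeline recovers a planted
signal of realistic geometry and strength — not that it attains any
particular accuracy on real proteomes.

## Problem sizes and numerical choices

The packaged analyses use the full corpus geometry (2312 training
windows × 704 features) with mRMR over all features and an IFS scan that
is dense for the first 30 prefixes and progressively coarser to 200 —
the curve is near its plateau well before that, and the scan grid is a
package default, not a statement about the true optimum's location.
Random forests run single-threaded with fixed seeds; all randomness
flows from explicit `numpy` generators. MI uses exact bincount joint
tables (no pseudo-counts); 0·log 0 terms are dropped.

## Known limitations

* The frequency feature's default train-then-CV protocol is mildly
  optimistic in cross-validation (the holdout evaluation is unaffected
  since the table comes from training positives only).
* Discretisation at mean ± sd is a pragmatic default; heavily skewed
  features may deserve quantile binning.
* Negative sampling imposes no minimum distance from true sites, so a
  negative window can overlap a positive's context; this matches the
  classical protocol but slightly hardens the task.
* The random-forest stage is intentionally plain: no class weighting,
  probability calibration or threshold tuning.
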
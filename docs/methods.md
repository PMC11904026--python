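# Methods

This note documents the models, parameter choices and numerical
conventions behind `lofcast`, what the synthetic generators do and do
not emulate, and the known limitations.

## Coordinates and notation

All residue numbering is 1-based on the reference protein — the long
MCT8 isoform (NP_006508.1), with codon 1 the initiator Met of
NM_006517.3. Variants are written `D498N` or `p.Asp498Asn`; cDNA
notation is rejected because transcript-to-protein mapping is out of
scope. Alignment columns map 1:1 to reference positions after A2M
filtering (lowercase insert columns deleted, `.` treated as gap), so
the reference row is always ungapped. `X` and other ambiguity codes are
tolerated in homolog rows and treated as gaps in all statistics.

## Sequence reweighting

Redundancy in the homolog set is corrected by identity clustering: each
row's weight is 1/(number of rows within θ normalized identity of it,
itself included), with pairwise identity = matches / columns where both
rows are non-gap. The default θ = 0.2 (i.e. clustering at 80%
identity) is the convention of the evolutionary-model family this
follows; Neff = Σ weights is the effective sample size. The computation
is deterministic and is cross-checked against an explicit per-pair
brute-force oracle in the tests.

## The alignment VAE and the evolutionary index

The generative model is a variational autoencoder over one-hot encoded
sequences (21 categories per column: 20 amino acids + gap):

* encoder: two tanh layers (default 64 → 32) to a diagonal-Gaussian
  latent (default 16 dimensions);
* decoder: the mirror image, ending in independent per-column 21-way
  categorical logits;
* objective: the sequence-weighted negative ELBO (reconstruction
  cross-entropy + KL to the standard normal prior, KL weight 1), with
  Adam (lr 1e-3), minibatch 128, default 300 epochs.

It is implemented directly in numpy with a hand-written backward pass
(verified against finite differences in the tests). All parameter
initialisation, batch shuffling and latent sampling derive from
explicit seeds, so training and scoring are bit-reproducible.
`VAEConfig.reduced()` (latent 8, hidden 48→24, 120 epochs) is the
desk-scale configuration used for the synthetic validation studies; at
those sizes a model trains in a few seconds on one CPU.

The evolutionary index of variant v is

    index(v) = mean over ensemble members of [ELBO(x_wt) − ELBO(x_mut)]

with the ELBO of each sequence averaged over 200 latent samples
(reduced config: 50). The sampling seed is derived from
(variant, base seed) and the same latent draws are used for the
wild-type and mutant sequence (common random numbers), which removes
most Monte-Carlo variance from the difference. A wt→wt substitution
short-circuits to exactly 0. Ten independently seeded models are
ensembled by default; per-model seeds come from spawning a
`SeedSequence` on the base seed.

The latent-free limit — a per-column categorical model with Laplace
pseudocount 0.1 — is packaged as `site_independent_results`. There the
index collapses analytically to the column log-frequency ratio
log f(wt) − log f(mut), which the tests use as a closed-form oracle and
for the re-rooting antisymmetry property.

## Conservation scores

Four per-position scores, all in [0, 1], higher = more conserved:
normalized entropy 1 − H/ln 20 on weighted, gap-excluded column
frequencies; Jensen–Shannon divergence to a uniform amino-acid
background, normalized by ln 2; the entropy score scaled by the non-gap
weight fraction; and a pass-through for externally computed grades.
These are documented stand-ins for server-computed Bayesian
conservation grades, which the classifier consumes as numbers; the
inference behind such grades is deliberately not re-implemented.

## Structural features

Surface areas use the Shrake–Rupley construction with a deterministic
Fibonacci-lattice point set (default 960 points/atom, probe 1.4 Å) and
a documented element radius table (C 1.70, N 1.55, O 1.52, S 1.80,
I 1.98, H 1.20, P 1.80 Å; unknown elements 1.70 Å with a warning).
Doubling the point count moves toy-fixture totals by <1%, and the
estimator is validated against closed-form single/two-sphere solutions
and a dense latitude–longitude grid oracle.

Interface areas are SASA differences: buried(res) = SASA(protein
alone) − SASA(protein + partner), clipped at zero, hence always
bounded by the residue's free SASA. The membrane partner is a
dummy-sphere lattice (spacing 2 Å, radius 1.8 Å) filling the slab
between two z-planes, by default ±15 Å around the bilayer midplane — a
typical half-thickness; all of it configurable. The substrate-channel
area is operationalized as the surface revealed by deleting the docked
substrate, i.e. the ligand interface area on the wild-type model.

Substrate distance supports `mean` (the classifier's "mean distance to
substrate") and `min` over all residue-atom × ligand-atom pairs. The
substrate-interaction flag uses a 4.5 Å any-atom cut-off (the original
criterion is not published; the value is the common heavy-atom contact
convention and is overridable). The alpha-helix flag derives from the
topology map (TMD segments are helices in this fold). Per-position
structural features broadcast to all 19 substitutions at a position,
because structures are wild-type models.

## Functional labels

Relative activity = 100 × (variant − background)/(WT − background),
clipped at ≥0, with the empty-vector control as background when present
(else 0; background handling is not published). Training labels:
pathogenic ⇔ activity < 50 (strictly; 50 itself is benign),
moderate/severe ⇔ activity < 10. Clinical LoF classes per assay
scheme: COS-1 severe <20, moderate 20–40, mild 40–75 (T3) / 40–65
(T4); JEG-3 severe <5, moderate 5–10, mild 10–50 (T3) / 10–40 (T4);
fibroblasts severe <50, mild 50–75. All interval boundaries are closed
on the milder side (activity < threshold falls in the more severe
class); the source thresholds are written as "<20%", "20–40%" without
resolving the boundary, so this convention is fixed here and tested as
a partition of the activity axis. Truncations before residue 575 are
assigned 0% activity without assay data. Training labels default to
the JEG-3/T4 scheme, overridable.

## The cascade

Both stages are penalized logistic regressions fitted with saga to
tolerance 1e-6 on per-stage standardized features (population variance;
zero-variance columns keep scale 1 with a warning; binary flags are
standardized like any column). Stage 1: C = 1, pure L2. Stage 2:
C = 10, elastic net with l1_ratio = 0.4, fitted only on pathogenic
(activity < 50) variants. The class-probability threshold is 0.5 at
both stages; the reported probability of a call is the predicted-class
probability of the deciding stage, so a prediction batch always
partitions into benign + mild + moderate/severe.

Feature selection is recursive elimination with a logistic estimator:
drop the smallest |coefficient| one feature at a time, ties broken
toward the earlier column (documented for reproducibility); the full
elimination order is returned. Hyperparameter grids are scored by mean
inner-CV f1, ties broken toward stronger regularization.

Cross-validation is 10-fold stratified by default, with an alternative
position-grouped scheme in which no residue position appears in both
train and test of any fold — the guard against the model merely
memorizing conserved sites. Standardization and RFE are refit inside
each training fold (a global-fit mode exists behind a flag for
comparison, since the original pipeline's leakage control is not
described). AUC uses the rank formulation and is checked against a
brute-force pairwise-concordance oracle with ties counted 0.5; AUPRC is
average precision; folds whose test set is single-class have their AUC
flagged and excluded from the mean. Permutation importance is the mean
AUC drop over seeded column permutations.

## Synthetic data: what it does and does not show

The alignment generator emits sequences column-wise: consensus with
probability equal to the planted conservation strength, otherwise an
alternative residue (uniform over the other 19 by default), with
optional cluster structure via shared ancestral alternatives.
Conservation-1 columns are invariant by construction. It has no true
phylogeny, no indel process and no covariation between columns — so
passing tests show the index resolves per-column constraint, not that
it captures epistasis in real homolog sets.

The table generator draws standard-normal features and produces
activity in two steps: a1 = 100·σ(−(Xβ₁ + ε₁)) decides pathogenicity
at the 50% cut-off; pathogenic rows then get activity
50·σ(−(Xβ₂ + b₂ + ε₂)), which decides severity at 10%. Noise is
Gaussian (sd 1); coefficient magnitudes are drawn in [0.6, 1.4] with
random signs so every planted feature stays genuinely informative; the
stage-2 intercept 1.386 (= logit 0.8) centres the mild/severe split.
The default scenario (480 × 134, 9 + 22 informative columns named after
the canonical feature lists, seed 42) yields roughly 49/25/26%
benign/mild/moderate-severe and is constructed to be strongly
separable: cross-validated AUCs near 0.97 measure recovery of planted
structure, not expected performance on real variants, where features
are correlated, labels noisy, and effects weaker.

Validation studies run at deliberately small problem sizes — 300 × 40
alignments, 3-model ensembles, the reduced VAE config, 50 RFE
replicates at 400 × 23 — chosen so the full suite completes in well
under a minute per study on one CPU.

## Design choices where the design was open

* The published feature table has 134 columns while the raw registry
  (91 substitution matrices + 4 conservation scores + 37 structural
  features × 3 models) would give 206; which were dropped or merged is
  not stated. The assembly registry therefore supports arbitrary
  subsets, and the canonical 9- and 22-column lists are shipped
  verbatim as ordered configurations.
* The homolog set behind the published evolutionary model is not
  specified ("optimized" is all that is stated); the alignment is a
  runtime input and the architecture defaults above are explicit
  stand-ins.
* The severity classes are named mild vs moderate/severe following the
  classifier-design figure; an alternative naming (moderate vs severe
  pathogenic) appears elsewhere in the source material.
* The landscape's "probability of correct prediction" glyph size is
  rendered as the deciding stage's predicted-class probability; no
  formula is published.
* The enumeration region for a full landscape is a required argument:
  8151 = 429 × 19 implies a 429-position span, but the published
  per-class counts (5183 + 2987 = 8170) and the alanine-scan window
  (Pro169–His575, 407 positions) are mutually inconsistent, so no
  default span is hard-coded.

## Limitations

* The VAE is site-factorized at the decoder output given the latent;
  long-range covariation is captured only through the 16-dimensional
  bottleneck.
* Structure features are computed on wild-type models; mutant-specific
  structural change enters only through ingested ddG columns.
* The cascade is linear in its standardized features by design (the
  coefficients are the interpretable object); no calibration of the
  probability outputs is performed.
* Real-data performance claims require the real feature table
  (alignment, structure models, external predictor outputs), which this
  package consumes but does not fabricate.
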
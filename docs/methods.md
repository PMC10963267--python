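# Methods

## The measurement model

A deep-screening flow cell carries clonal DNA clusters, each tagged by a
random 28-mer UMI and displayed in situ as protein.  Scans of the cell during
an antigen titration and a wash series yield, per cluster, a fluorescence
intensity on a binding channel (T) and on a normalization channel (C) where
every cluster carries a common label.  Because a single cluster read-out is
noisy, each clone is laid down at ≥ 12 replicate positions and all analysis
is per-UMI.

The package models the binding channel with two forward curves:

* equilibrium occupancy at antigen concentration *x*:
  `R = F_max / (1 + K_D^app / x) + F_min`.  `F_max` is the clone's saturating
  amplitude (scaled by its display efficiency), `F_min` the baseline.
* wash-phase decay, biphasic because clusters in the crowded flow-cell
  environment compete for rebinding:
  `R = R_1 e^{-k_d1 (t - t_0)} + (R_0 - R_1) e^{-k_d2 (t - t_0)}` with the
  label convention `k_d1 ≥ k_d2` enforced after fitting.

Orthogonal bio-layer interferometry validation uses the standard 1:1 model
with observed association rate `k_obs = k_a C + k_d`, plateau
`R_max / (1 + k_d/(k_a C))`, single-exponential dissociation continued from
the association end point, and `K_D = k_d / k_a`.  Cell-based inhibition uses
the four-parameter logistic in log concentration.

## Synthetic data: what it emulates and what it does not

The simulator generates the full experiment from a truth table so every
downstream stage can be checked against planted ground truth:

* clone K_Ds log-uniform over a configurable range (default 0.1 nM – 1 µM);
  display efficiencies uniform on [0.5, 1]; a configurable fraction of
  non-binders whose maximal signal (1 % of F_max) sits below background;
  biphasic rates log-uniform over [1e-3, 1e-2] and [1e-5, 1e-4] /s — ranges
  chosen so the fast phase is partly decayed and the slow phase clearly
  resolved at 5–120-minute wash reads.
* cluster layout on a jittered grid that guarantees a pairwise spacing floor
  (default 6 px); default tile 512×512 px at desk scale rather than full-scan
  geometry, which only changes throughput.
* images as amplitude-scaled Gaussian spots (σ = 1 px, clusters being roughly
  a micron wide at this sampling) over a flat or low-order-polynomial gain
  field in [0.7, 1.3], plus additive Gaussian noise, 16-bit clipped.  The
  default background (100 counts) and noise level are plumbing choices — the
  real instrument's background statistics are not modelled.
* the normalization channel renders every cluster at one common value with
  the same noise model; binding analysis uses raw T-channel intensities by
  default, since no normalization formula is part of the procedure being
  implemented (a T/C ratio mode exists for exploration).

Not emulated: bridge amplification, transcription/display efficiency
variation over time, base calling, chromatic aberration, focus drift,
cross-talk.  Passing tests therefore demonstrate correctness of the analysis
chain under its own forward model, not robustness to every instrument
artefact.

## Quantification chain and its numerical choices

1. **Illumination correction** subtracts a disk-25 morphological opening from
   the tile; features narrower than the disk survive up to local background.
2. **Peak detection** marks pixels equal to their 3×3 grey-dilation and
   strictly above a threshold (default 600, an instrument-tuned constant kept
   configurable).  The equality test is exact, so plateaus emit every plateau
   pixel — duplicates are tolerated by the alignment stage.  The threshold is
   applied after correction.
3. **Alignment** rasterizes detected peaks and sequencing coordinates to
   binary 1-px occupancy images and registers them by FFT phase correlation;
   a per-128×128-sub-tile refinement produces the offset map, with sub-tiles
   holding fewer than 10 points (an unstated free parameter) inheriting the
   global offset.  The admissible local shift is capped at subtile/8 because
   circular FFT correlation on near-periodic point lattices otherwise
   selects wrapped aliases of the true shift.
4. **Photometry** rounds the offset-corrected centre to the nearest integer
   pixel, multiplies the 9×9 window element-wise with the amplitude-1
   Gaussian kernel `exp(-d²/2σ²)`, σ = 0.5 px, and sums.  The kernel is
   deliberately not unit-normalized — the constant cancels in all relative
   comparisons.  Windows that leave the image flag the cluster *rejected*
   rather than zero, and rejected clusters count against the 12-replicate
   requirement.

A property of this procedure worth knowing: for a spot placed at sub-pixel
coordinates the integer-window weighted sum varies with the sub-pixel phase
by up to ~17 % peak-to-peak (4 % rms at σ_spot = 1, σ_kernel = 0.5).  This is
inherent to fixed-window weighted photometry, not an implementation defect;
replicate averaging over ≥ 12 clusters randomizes the phase and suppresses
it.  The round-trip test that demands < 1 % spread therefore uses
integer-snapped placement to isolate the photometric chain, and a separate
test verifies rank preservation at sub-pixel placement for signals spaced
30 % apart.

## Aggregation

UMIs with ≥ 12 clusters that were never rejected in any condition are
retained.  Within each UMI × condition × channel the replicates pass through
raw (unscaled) MAD rejection — keep `|v − median| ≤ k·MAD`, default `k = 3`,
a conventional cutoff documented as a free parameter; when MAD = 0 only
values equal to the median survive.  For `k ≥ 1` the filter provably keeps at
least half the replicates.  Summaries are mean, median, sample sd (n−1) and
sem = sd/√n.  CDR consensus is whole-read plurality over ≥ 3 reads with ties
dropped; per-position voting exists behind a flag but can fabricate chimeric
sequences, so it is off by default.  Genotype and phenotype join inner on the
UMI; an optional collapse mode merges UMIs sharing a consensus CDR and
records abundance.

## Curve fitting

All fits are unweighted least squares on raw intensities
(`scipy.optimize.curve_fit` / `least_squares`).  Equilibrium and rate
constants are optimized as log10 parameters, which enforces positivity and
conditions the pM–µM dynamic range; bounds are log10 K_D ∈ [−15, 3] and
log10 k ∈ [−12, 2], with estimates pinned at a bound reported as
non-converged (flat titrations, no measurable decay).  Initialization:
F_min = min(FI), F_max = span, K_D at the geometric mean of the
concentration range; dissociation starts from rates 1e-2 / 1e-4 /s with half
the amplitude in the fast phase.  These choices make noiseless forward-model
recovery deterministic and exact to optimizer tolerance.  The BLI
association and dissociation phases are fit jointly with shared
(k_a, k_d, R_max) and hard Y_0 continuity at the phase boundary.  Missing or
non-finite conditions are dropped pairwise.

Measured on 200 synthetic clones (K_D log-uniform 0.1 nM–1 µM, 7-point
titration 100 pM–100 nM, 2 % multiplicative noise): median |Δlog10 K_D|
≈ 0.03–0.04 and Spearman ≈ 0.99 against truth (see
`scripts/acceptance.py`).  Clones with K_D well above the highest tested
concentration are weakly identified — their fitted values carry most of the
tail error, which is a property of the titration design, not the optimizer.

## Hit calling

Hits are rows whose per-UMI mean FI at a named condition is ≥ fold × the
library mean (fold 2.0, or 1.5 once assay noise is characterized); the
boundary is inclusive and the library mean includes hit rows (global mean).
Three-way class bins for classifier training: non-hit ≤ 150, high-hit ≥ 250,
chosen so the reference parent clone (FI 190.05 at the 5-minute wash) sits
centred in the low-hit band.  Binary calls against a reference use
fold × reference FI.  All boundary inclusivities are fixed and documented so
behaviour is deterministic.

## Sequence space and selection

Amino acids are indexed alphabetically (A=0 … Y=19, then `*`=20, `X`=21) and
written as 5-bit MSB-first blocks; the compressed encoding covers the whole
alphabet including stop and unknown while keeping PCA inputs dense.  Mutant
enumeration is exhaustive for Hamming orders 1–3 and seeded
rejection-sampling without replacement for orders 4–5, where the candidate
space (C(L,k)·19^k) dwarfs any practical cap so collisions are rare.  The
random arm takes all singles plus ≤ 1,000 sampled mutants per edit distance
2–5 per seed; the ML arm filters scored candidates at high-hit probability
≥ 0.9 (strict `<` removed), assigns each candidate to its nearest seed,
samples up to 1,000 per seed per distance 2–5, and excludes anything already in
the random arm — so the two pools are disjoint by construction.  The
candidate-set size per seed is exposed as a parameter rather than fixed.

## Models and training

The transformer is a standard post-norm BERT stack: learned token and
position embeddings (vocabulary 25 = 20 residues + PAD/MASK/UNK/CLS/SEP —
the exact special-token composition is a design choice), multi-head
self-attention with padding masked at the score level, GELU feed-forward,
and an MLM head (dense → Tanh → dense → LayerNorm → GELU → per-position
vocabulary projection).  At width 768, feed-forward 3072, 12 blocks × 12
heads and 150 positions it counts 86,390,809 trainable parameters (verified
against independent shape accounting).  Classification pools the last block
by the mean over non-pad positions — the only shape-consistent reading of a
"mean across the vocabulary vector" — into dense-128 → ReLU → 3 logits.

The MLP baseline embeds the 21-long CDR3 into 64 dimensions (24-token
vocabulary, a value forced by the published layer shapes and totals),
flattens, applies bias-free 1344→32 and 32→64 linear layers each with GELU
and LayerNorm, and a biased head: 46,979 parameters with 3 logits, 46,849
with the scalar soft-target head (targets 0.0 / 0.5 / 1.0).

Masking selects each residue position with p = 0.15 and replaces it with
[MASK] (80 %), a random residue (10 %) or leaves it (10 %); special tokens
are never selected and labels exist exactly at selected positions.
Training uses Adam (lr 1e-4, β = (0.9, 0.999), ε = 1e-8, no weight decay), a
seeded 90:10 split, cross-entropy with inverse-class-frequency weights by
default, and retains the checkpoint with the lowest validation loss.
Corpus-scale MLM pre-training is out of scope; `pretrain_smoke` runs the
identical objective at desk scale to validate the loop.

Everything runs on a package-internal numpy reverse-mode autodiff core
(`_nn.py`): float32, single-threaded, fully seeded, supporting exactly the
operations these two architectures need.  It favours auditability over
speed; the desk-scale configurations used in tests (2 blocks, width 64)
train in seconds.

### The planted-motif evaluation

The end-to-end ML check plants a 3-residue motif that confers high binding
(full motif → FI ≈ 320, two of three → ≈ 190, fewer → ≤ 90, σ = 10 noise) in
a 15-residue CDR, fine-tunes the reduced transformer on ~1,800 labelled
sequences, and asks selection to complete the motif from a seed carrying two
of its three residues.  Random mutation completes it at the base rate
(~0.4–0.6 % of the random arm); ML-guided selection concentrates motif
carriers to ~60–100 % of its arm, an enrichment of two orders of magnitude —
far above the 3-fold floor the check requires.  This shows the selection loop is
wired correctly; it does not certify performance on real antibody
landscapes, which are not three-residue step functions.

## Pipeline sizes and determinism

The demo screen uses 50 clones × 12 replicates on one 512×512 tile, the
4-point titration plus 7 wash reads (22 images) — about 40 s on one CPU; the
characterized-panel benchmark uses 5 clones spanning 15 pM–320 nM at the
7-point titration and recovers the rank order exactly at low noise.  All
randomness in every module descends from explicit integer seeds through
numpy seed sequences; identical config + seed reproduces byte-identical
tables, which the test suite asserts.

## Known limitations

* Sub-pixel photometric phase sensitivity (above) bounds per-cluster
  accuracy at a few per cent; per-UMI averaging is the mitigation, as in the
  real assay design.
* Equilibrium fits extrapolate poorly beyond the top titration point;
  apparent K_Ds above ~10× the highest concentration should be treated as
  censored (the rank-correlation helper accepts censored bounds).
* The biphasic dissociation fit is a phenomenological description of
  competition/rebinding in the flow cell, not a mechanistic model.
* Whole-read consensus requires an exact plurality winner; at high read
  error and low read depth it drops UMIs rather than guessing.
* The autodiff core has no GPU path and is unsuitable for corpus-scale
  pre-training by design.
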
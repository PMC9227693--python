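# Methods

`metabarcode` implements a five-stage analysis that turns heterogeneous
published metabolomics reports into a "tumor barcode" of reliably altered
metabolites, propagates drug-target information over a metabolite–protein
network, predicts synergistic drug combinations, and evaluates plate-level
synergy. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Bayesian vote counting

Quantitative effect sizes (fold changes, odds ratios) from small
metabolomics studies are too heterogeneous to pool, so evidence is reduced
to votes: each study reports a metabolite up (+1) or down (−1) in tumor
versus control for one sample type (blood, tissue, feces). For a
metabolite mentioned by `n` studies with `x` of them in the majority
direction, the per-study probability θ of reporting the disordered
direction gets a flat Unif(0,1) prior, giving the Beta(x+1, n−x+1)
posterior with mean (x+1)/(n+2). Evidence is summarised by the posterior
odds

    BF = P(θ > 1/2 | x, n) / P(θ < 1/2 | x, n),

computed from the regularized incomplete Beta function (no quadrature),
signed by the majority direction. Conventions:

- **Frequency screen**: only metabolites reported by ≥ 3 independent
  studies (inclusive) are evaluated; the overall screen pools sample
  types (`tally_votes(records, None)`), while barcodes are per sample
  type. A multi-platform study votes once.
- **Strict threshold**: a barcode entry needs |BF| > 3 strictly. A single
  unanimous study gives BF = 3 exactly and is excluded; three unanimous
  studies give BF = 15. A tied tally has direction 0 and |BF| = 1.
- **Sign-test comparator**: exact binomial tail at p = ½, one-sided in
  the observed majority direction by default. One-sidedness is the only
  reading under which detection of unanimous reports first becomes
  possible at n = 5 (p = 0.03125; n = 4 gives 0.0625), which matches the
  small-sample behaviour the method is designed around; a two-sided flag
  exists. Ties are kept and break toward non-significance.
- **Bar intensity**: |BF| clipped at 100 and rescaled to [0, 1]; purely a
  rendering choice.

The power/calibration simulation draws x ~ Binomial(n, θ) per replicate,
estimates sign-test power as the fraction of one-sided p < 0.05, and
compares the mean posterior expectation with its analytic value
(nθ + 1)/(n + 2). Grid: θ ∈ {0.6, 0.7, 0.8, 0.9}, n ∈ {5, 8, 10, 12},
50,000 replicates (Monte-Carlo SE ≤ 0.0022 on a proportion), checked
against the exact binomial tail of the realized critical region.

## Metabolite–protein network and random walk with restart

Chemical–protein edges (STITCH-style) around the tissue-barcode
metabolites are merged with protein–protein edges (STRING-style) into one
weighted undirected graph. Database scores on the 0–999 scale are
rescaled to [0, 1] and used as edge weights (a score threshold and a
binarize option exist; default keeps weights). Connected components
containing no barcode metabolite are dropped, as are isolated nodes.
Node order is fixed (metabolites then proteins, each lexicographic) so
every downstream matrix is reproducible bit-for-bit.

A drug or drug pair is encoded as a uniform seed distribution P₀ over its
(union of) protein targets present in the network; metabolites propagate
but are never seeds. The walk

    P_t = (1 − λ) Wᵀ P_{t−1} + λ P₀,   W_ij = A_ij / Σ_k A_ik

is solved either in closed form, P = λ(I − (1 − λ)Wᵀ)⁻¹P₀ — the fixed
point of the recursion — or by iterating to an L1 step below 1e−10. The
two routes agree to < 1e−8 (L1) on random graphs up to N = 500, and both
conserve probability mass because Wᵀ is column-stochastic. At the default
λ = 0.5 the commonly-quoted alternative closed form (1 − λ)(I − λWᵀ)⁻¹P₀
coincides numerically, so the choice of fixed-point form cannot affect
results at the default; we treat the recursion as the definition. λ is a
hyperparameter of the prediction stage, not re-tuned here.

## Synergy prediction

The predictor matrix has one RWR profile per combination (rows sum to 1,
columns in network node order); (a, b) and (b, a) are identical by
construction because the seed is the union of target sets. Cell line is
metadata, not a feature, by default. Training uses a stratified 80/20
split (⌈0.8n⌉ training rows), 10-fold cross-validated grid search
minimising CV error = 1 − accuracy (log-loss available), ties resolved
toward the simplest model (fewer trees, then shallower). Two interchangeable
backends sit behind one fit/score contract: a random forest
(bagged trees; grid over `max_features`) and gradient-boosted trees
(grid over rounds and depth, learning rate 0.1). Candidate sensitizers of
a backbone drug are scored as (backbone, candidate) pairs through the same
featurization; a candidate is "supported by both families" when it ranks
in the top 10 of both rankings (the agreement criterion needs a k; 10 is
the default and configurable).

## Plate synergy statistics

From optical density at 490 nm: survival = mean OD_treatment / mean
OD_control and inhibition E = 1 − survival (the `standard` convention;
a `printed` convention reading the same ratio as 1 − survival is kept
behind a flag for fidelity to sources that typeset it that way, since
taken literally it inverts the biology). "Blank" is read as the vehicle
control, not a cell-free blank; no blank-subtraction step is applied.
Two read-outs per dose pair:

- **Combination index** Q = E_combo / (E_a + E_b − E_a·E_b), observed
  combined inhibition over its Bliss expectation. Q = 1 is exact
  additivity; Q ≥ 1.15 (inclusive) is the synergy cut.
- **Bliss t-test** on per-well log survival y_ij: contrast
  ȳ₁ + ȳ₂ − ȳ₃ (zero in expectation exactly when survival multiplies),
  pooled variance over the three treated groups, df = Σnᵢ − 3, two-sided
  Student-t p. The three-group pooled-variance contrast is the unique
  standard form consistent with that df and contrast; it is cross-checked
  in the tests against an OLS group-means contrast.

The verdict requires Q ≥ 1.15 AND p < 0.05 AND t > 0: a two-sided p alone
cannot distinguish synergy from antagonism.

The t statistic treats the control-normalizing constant log(mean control
OD) as fixed: it cancels from within-group variances but enters the
contrast once, so a noisy control inflates the realized type-I error
(≈ 0.08 with 6 noisy control wells at σ = 0.05). The calibration
simulation therefore uses an exactly-known control (noiseless control
wells), the regime in which the null distribution is exactly Student-t;
with that design the type-I error over 2,000 plates is 0.05 within
Monte-Carlo error. Bench users with few control wells should expect the
documented inflation.

## Synthetic data: what it emulates, and what it does not

All inputs are generated with known ground truth; every generator is a
pure function of its seed and emits a machine-readable truth table.

- **Literature library.** The default plan mirrors the curated corpus the
  method targets: 39 studies (19 blood: 1332 cases / 1870 controls;
  20 tissue: 495/495), 330 metabolites, 254 at overall frequency ≥ 3,
  50 blood and 43 tissue metabolites at per-type frequency ≥ 3, with
  planted vote patterns producing 28 up + 6 down barcode entries in
  tissue and 15 up + 12 down in blood, and 21 metabolite ids shared
  between the two frequent sets. Stochastic rows draw each report as the
  true direction with probability θ — exactly the Bernoulli success the
  posterior models, which makes posterior-mean recovery a sharp test.
  Not emulated: platform-specific signal, name ambiguity beyond a simple
  alias map, correlated reporting between studies.
- **Network.** Desk scale: 10 metabolites × 3 chemical–protein links plus
  an Erdős–Rényi protein layer (110 proteins, mean degree 4), weights
  U(0.4, 1), regenerated until cleanup leaves one connected component —
  large enough for non-trivial propagation, small enough for dense
  oracles. Real interactome topology (hubs, modularity) is not emulated,
  so classifier accuracies here say nothing about accuracy on real
  database extracts.
- **Combinations.** 541 unordered pairs of 60 drugs (2–6 targets each).
  The hidden rule is a positive weight vector supported on a 12-protein
  hub set; drugs target either the hub or its complement (fraction
  √½ ≈ 0.71 on the hub so both-hub pairs are about half of all pairs),
  labels are "score > median" then flipped at rate 0.1. The hub
  construction is what makes the planted rule recoverable: scores
  separate at the median instead of forming a continuum there, so the
  10%-flip noise is the binding error source and held-out accuracy
  above 0.8 is achievable by design for any competent learner.
- **Plates.** OD_well = base × rate × exp(ε), ε ~ N(0, σ²), default
  σ = 0.05 and 6 wells per group; Bliss-null mode sets the combination
  survival to the product of single-agent survivals; planted synergy
  multiplies it by 0.7 (power > 0.9 at these settings, measured 0.99+).

## Problem sizes and tolerances

Defaults used by the tests, the analysis scripts, and
`scripts/acceptance.py`, chosen as the package's study conditions:
50,000 replicates for power/calibration (band 3 MC SE; calibration band
0.01); 200 random graphs up to N = 500 for the dual-route RWR check at
L1 < 1e−8, with a first-principles dense solve on N ≤ 6; the 541 × 120
prediction benchmark with 10-fold CV and a 20-permutation label null
(band [0.4, 0.6]); 2,000 null plates for type-I (band 0.05 ± 0.01,
~2 MC SE) and 400 plates for verdict power. Degenerate inputs: zero
votes, all-absent seeds, inert single agents, and zero pooled variance
each raise or warn explicitly rather than returning silent values.

## Known limitations

- Vote counting discards effect sizes by design; the BF measures
  consistency of direction, not magnitude.
- The uniform prior and the > 3 posterior-odds cut are conventions;
  results near the cut (e.g. frequency-3 tallies at 2–1) move if either
  changes.
- Network assembly trusts the input edge lists; no confidence
  recomputation, no directionality, no signs.
- The classifier harness ranks candidates within the training
  distribution of target sets; it cannot extrapolate to drugs whose
  targets fall outside the network.
- Real-data identities (which drugs, which metabolites) are outside the
  package's synthetic validation surface.
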
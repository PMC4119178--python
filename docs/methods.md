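# Methods

## Inputs and coordinate conventions

The package consumes, per protein: an NCBI PSI-BLAST ASCII PSSM (log-odds
similarity scores and weighted observed residue percentages, column order
read from the file's own header), a predicted-RSA track as a plain
two-column `position<TAB>value` table with values in [0, 1] (a 0–100 scale
can be declared and is divided by 100), and mutation tokens in one-letter
`WT<pos>MUT` form. Coordinates are 1-based throughout, matching mutation
nomenclature; the single 0-based conversion happens at the profile
boundary. Mutations are validated against the profile (position in range,
wild type matches the sequence); synonymous tokens are rejected at parse
time rather than silently scored zero, and mutations at undetermined (X)
positions are refused. RSA predictors' native output formats are not
parsed; any predictor's per-residue values can be converted to the
two-column table with a one-line awk/pandas step.

## Feature definitions

*Similarity score* SS(i, a) is the PSSM log-odds value for amino acid a at
position i. The observed-percentage block is also retained, so the
alternative reading (percentages as scores) remains switchable, but
log-odds is the default and the one used everywhere.

*Shannon entropy* is computed from the PSSM's weighted observed
percentages (the profile search's sequence-weighted column estimates),
normalized per position, in bits; an all-zero percentage row — emitted at
positions with no aligned homologs — falls back to the maximal log2 20 ≈
4.32 bits. `zsEntropy21` standardizes a position's entropy against the
21-residue window centered on it (10 residues each side, center included,
clipped at the termini); the sample (n−1) standard deviation is used, and
a zero-spread window yields z = 0. Including the center keeps the
statistic defined at termini; a switch excludes it. The Z-score is
invariant to the entropy's logarithm base, asserted in tests.
`varPredRSA21` is the sample variance of the RSA track over the same
window; a width-1 window is defined as 0.

*Residue size* is the Zamyatnin volume (Å³; Gly 60.1 minimum, Trp 227.8
maximum), min–max normalized to [0, 1] so the `ss_Abs_dSize` product
|Δsize|·|ΔSS| is scale-free. The |ΔSS| weight keeps the feature
one-sided and nonnegative; a signed-weight variant exists behind a flag.
Leucine and isoleucine share a volume, so L↔I swaps score 0 on this
feature regardless of their score gap.

## Feature selection

F = |x̄_n − x̄_d| / (σ_n + σ_d) with sample standard deviations; a
zero-spread pair with equal means scores 0, with unequal means +inf
(always kept). The inclusion procedure drops candidates with |F| < 0.4,
orders survivors by descending |F| (lexicographic tie-break), and admits
greedily unless |r| against an already-admitted feature reaches 0.8. The
greedy order is a reconstruction — the original procedure is not fully
specified — chosen because it reproduces both documented outcomes: the
five final features survive together (their largest internal |r| is 0.73),
and raw entropy (|F| = 0.66) is excluded through its −0.82 correlation
with `Abs_dSS`. Correlations are pooled over both classes by default;
within-class averaging is available via flag. An optional exhaustive
subset search (≤ 15 candidates) maximizing cross-validated LDA MCC mirrors
the model-driven selection stage.

## Classifiers

**LDA.** Features are z-scaled by training statistics stored on the model.
The direction is w ∝ S⁻¹(μ_del − μ_ben) with pooled within-class
covariance; a ridge ε = 1e-6·trace(S)/d keeps S invertible under
collinearity. The threshold sits at the midpoint of the projected class
means; the reported score is the logistic of the signed margin, so higher
always means deleterious. Standardization makes predictions invariant to
affine rescaling of any input feature.

**Network.** 5-10-5-2 fully connected, logistic sigmoid everywhere,
sum-of-squares loss against one-hot targets (output node 0 = deleterious),
weights initialized uniformly in [−0.5, 0.5] from the seed — the defaults
of the classic simulator era for this architecture. Training is full-batch
StdBP (fixed learning rate, default 0.2) or Rprop with the canonical
constants η+ = 1.2, η− = 0.5, Δ0 = 0.1, Δmax = 50, Δmin = 1e-6, including
weight backtracking on sign flips when the epoch error grew. Step sizes
are clamped to [Δmin, Δmax] every epoch (asserted from the training log).
After each epoch the validation MCC at threshold 0.5 is recorded and the
best snapshot is returned; default budget 300 epochs with patience 100.
The prediction score is o_del/(o_del + o_ben) (0.5 when both outputs
vanish); ties at exactly 0.5 classify deleterious, the recall-favoring
convention. Training is bit-reproducible given the seed.

## Validation protocol

Stratified 5-fold cross-validation (stratification is necessary: 73
negatives over 5 folds make unstratified splits unstable). Within each
fold a further stratified 20% of the training portion is withdrawn as a
validation subset; candidate models (default 10 random restarts for the
network, one fit for LDA) compete on validation MCC and the winner is
scored on the fold's untouched test portion. Summaries report mean ± sd
(sample sd, labeled as such) per metric. The final single model is the
fold winner with maximal test MCC, ties broken by the smallest
|MCC_val − MCC_test| gap — "best generalization" made operational. Fold
test sets partition the data; validation subsets never touch their fold's
test set (asserted).

Metrics: Q2/R/P in percent, MCC in [−1, 1]; MCC with a zero marginal is 0,
undefined recall/precision are NaN, never silently 0. ROC is a descending
threshold sweep over unique scores with trapezoid AUC, which equals the
Mann-Whitney pairwise statistic with half-credit ties — the identity the
tests use as an oracle. Method comparison correlates raw scores pairwise
(rows a method did not score are dropped pairwise with counts reported)
and tallies calls and unanimity.

## Synthetic data

The generator emulates the class structure the classifier exploits, not
CYP biology. The **direct** path draws class-conditional Gaussian feature
vectors: with equal within-class sd, a mean shift of 2·F·sd realizes a
target F-score exactly in expectation; defaults use the five published
F-scores (0.73/0.61/0.49/0.47/0.45) with the published signs (deleterious:
larger score gaps, more negative entropy Z, more buried, flatter local
RSA) and a 197:73 deleterious:benign split. The **profiles** path emits
real inputs — an ASCII PSSM whose per-position residue distributions are
Dirichlet draws (dominant-residue concentration 30 at deleterious sites,
uniform concentration 1 elsewhere), log-odds round(2·log2(p/0.05)) clamped
to [−10, 13] to mimic the integer range of profile search output, and an
RSA track of moving-average-smoothed uniform noise (correlation length 10
residues). Designated sites sit on a jittered grid (one per equal block;
the auto panel length allots 22 residues per site, so 21-residue windows
rarely mix classes) and positions within 10 residues of a site take that
site's class burial level — buried 0.12 ± 0.03 for deleterious, exposed
0.65 ± 0.12 for benign — nearest site winning. Deleterious mutations take
the most-penalized substitution at their site, benign the least-penalized.

What passing these tests shows: the pipeline recovers configured class
separations and learns separable structure reproducibly. What it does not
show: performance on real CYP variants, which depends on homolog
availability, RSA-predictor error structure, and label noise that the
generator deliberately does not model (no phylogenetic correlation between
positions, no shared-protein effects, no mislabeled variants).

## Problem sizes and numerics

The bundled checks run at desk scale: parameter recovery at n = 2000 over
10 seeds; cross-validation sanity on the 270-vector TS270-shaped set with
5 (separable) or 2 (permutation-null) network restarts per fold; oracle
equivalences at 1e-12 on 100–300-point tracks. The "separable" construction
doubles the published F separations (separation_scale = 2), since the
published separations themselves imply an irreducible class overlap
(Mahalanobis distance ≈ 2.5) that caps MCC well below 1 for any
classifier. Reproduction of the published headline numbers themselves
(retrained MCC 0.70, AUC 0.909, a perfect CS30 sweep) requires the
original variant catalogues, profile searches against a reduced sequence
database, and an external RSA predictor, and is out of scope.

## Known limitations

- The PSSM parser accepts only the standard 44-field ASCII layout; wrapped
  or localized variants are rejected with the offending line number.
- The feature set is fixed at the five sequence features; structural or
  physico-chemical candidates beyond residue volume are not computed.
- The network trainer is full-batch; datasets far beyond ~10⁴ vectors
  would want mini-batching, which this problem never needs.
- `compare_methods` assumes externally aligned score tables; it does not
  map mutation identifiers across methods.
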
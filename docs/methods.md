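# Methods

## Problem setting

A decoy set is a pool of predicted 3D models of one protein. The package
estimates each decoy's quality — its GDT-TS to the (unknown) native — well
enough to rank the pool and select the best models. Two families of
estimators are combined: consensus scores computed from the pool geometry
alone (CGDT, PSPS) and single-model scores computed from one structure at a
time. The combination operates on decoy *pairs* and aggregates pairwise
decisions into a tournament score.

## GDT-TS and consensus GDT

GDT-TS between two equal-length Cα traces is the mean over distance cutoffs
{1, 2, 4, 8} Å of P_d, the largest fraction of residues that a rigid
superposition brings within d of their counterparts. Finding P_d exactly is
combinatorial; the package uses:

* **chains of ≤ 12 residues** — exact search: a Kabsch fit on *every*
  residue subset of size ≥ 3 (vectorized over subsets), inliers counted
  under each fit;
* **longer chains** — an LGA-style heuristic: Kabsch fits seeded from
  contiguous fragments of lengths 3/5/7 (starts strided by L/10 beyond 30
  residues) plus the full chain, refined per cutoff by alternating
  "superpose on inliers / recompute inliers" to a fixed point (≤ 10
  rounds), then an extension pass that refits on distance-ordered prefixes
  of the best seeds. All refinements run as one batched weighted-Kabsch
  stack (matmul + batched 3×3 SVD), which keeps a 60-residue pair near 10 ms.

P_d is clamped non-decreasing in d (any superposition achieving fraction f
at cutoff d achieves ≥ f at a larger cutoff). The search is deterministic;
the heuristic is a lower bound on the exact value and matches the exhaustive
oracle on 10-residue pairs in the test suite. Pairs of structures with
different residue numbering are restricted to the common residue-number
intersection first (≥ 4 residues required); fractions use the common count
as denominator.

CGDT of decoy i is the mean of its pairwise GDT-TS to all other pool
members. The pair matrix is computed once per unordered pair and mirrored.

## Structural alphabet and PSPS

Residue position i (1-based, 3 ≤ i ≤ L−1) of a Cα trace is described by the
angle triplet of atoms (i−2, i−1, i, i+1): bend at i−1, dihedral of the
four atoms (standard sign convention; right-handed helices give τ ≈ +50°),
bend at i. A decoy of length L yields L−3 triplets.

Triplets are clustered into K = 17 states by a full-covariance Gaussian
mixture. Because τ is circular, fitting and assignment operate on the
embedding (θ₁, sin τ, cos τ, θ₂), which removes the ±180° seam; component
means map back to angles via atan2. Assignment is the hard argmax of the
weighted component densities, ties to the lowest state index. EM
(scikit-learn, 3 initializations, reg_covar 1e−4) is deterministic given the
seed; refits require ≥ 10·K pooled triplets.

The published parameters of the original 17-state alphabet are not
available, so the package ships an alphabet fitted on a synthetic library of
40 helix/strand/coil traces (`scripts/build_assets.py` regenerates it
deterministically), and `fit_state_model` retrains on any structure
collection. PSPS is a *consensus* score — only the relative agreement of a
decoy with the pool matters — so rankings are robust to the exact alphabet;
an alphabet trained on real structures can be dropped in as a JSON file.

Given state sequences for the whole pool, the position-specific frequency
matrix (PSFM) holds f(s, pos) = (# decoys in state s at pos)/n; every column
sums to 1. A decoy's PSPS is Σ_pos f(c_pos, pos) ∈ (0, L−3]; the pool mean
of PSPS equals Σ_pos Σ_s f(s,pos)² (asserted in tests).

## Feature panels

A panel holds five higher-is-better columns per decoy set, default order
(OPUS-Ca, RW, DDFire, PSPS, CGDT). The three single-model slots accept any
externally computed score table (two-column TSV); energies declared
lower-is-better are negated on entry. Without external tables the slots are
filled by the built-in stand-in potential: a Cα distance-bin log-odds
pseudo-energy, −Σ_pairs log(observed_bin_freq / reference_bin_freq) over
residue pairs with sequence separation ≥ 3 and distance < 15 Å (0.5 Å
bins), with observed frequencies from the synthetic reference library and a
uniform-sphere (∝ r²-shell) reference state. The three slots use different
binnings/separations so their information is not identical. The stand-in is
a self-contained single-model score in its own right, not a reimplementation
of any published potential.

Columns are z-scored within the decoy set before pair differencing: the nets
otherwise see energies and GDT fractions on wildly different scales. The
flag is recorded in the model file.

## Pairwise two-stage combination

For each unordered decoy pair (i, j), taken once in lexicographic order, the
input is Δx = f(i) − f(j) (5-vector of z-scored column differences). Two
classifiers with identical architecture — 5 inputs, one hidden layer of 3
sigmoid units, sigmoid output — act in sequence:

* **model 1 (significance)**: target |ΔGDT| > 0.025. Trained with
  inverse-frequency class weights (tight pools are dominated by near-ties).
* **model 2 (winner)**: target sign(ΔGDT); pairs with |ΔGDT| < 0.01 are
  removed from its training data so near-ties do not teach noise.

A pair contributes a win only when model 1 fires (probability > 0.5) and
model 2 picks a side; non-significant pairs award nothing. A decoy's score
is its win count (0 … N−1); Σ scores = number of decided pairs. Final
rankings break count ties by CGDT, then id.

The pairwise formulation logically requires model 1 to be even and model 2
odd in Δx. Both properties are enforced twice: training data is augmented
with mirrored pairs (−Δx, mirrored label), and predictions are exactly
symmetrized — p₁(Δx) ← (p₁(Δx)+p₁(−Δx))/2 and p₂(Δx) ← (p₂(Δx)+1−p₂(−Δx))/2
— so decision(i,j) and decision(j,i) can never disagree and a zero
difference vector is always "no decision".

Training: full-batch L-BFGS on weighted cross-entropy with L2 penalty 1e−4,
max 300 iterations, 3 deterministic random restarts (best training loss
kept). The nets have 22 parameters; L-BFGS is fast and reproducible at this
size, which is why it was preferred over epoch-based SGD with a validation
split. All constants (cutoffs 0.025/0.01, feature order, z-score flag,
weights) are serialized in the model JSON.

Leave-one-out protocol: with T targets, each decoy set is scored by models
trained on the pairs pooled from the other T−1 sets, and per-target metrics
(GDT1, avgGDT5, Pearson, Spearman) are averaged.

## Evaluation metrics

GDT1 = true GDT of the top-ranked decoy; avgGDT5 = mean true GDT of the top
five (all N if N < 5); Pearson on raw scores; Spearman with average-rank tie
handling. A constant score vector has no defined correlation and reports 0.
Top-k selection uses the same tie-break as the tournament ranking.
Cross-correlation tables average per-target Spearman matrices; ablation
reruns the leave-one-out evaluation with each feature column removed once.

## Synthetic benchmark generator

`synth_native` builds self-avoiding Cα traces from alternating ideal-helix
segments (rise 1.5 Å, radius 2.3 Å, 100°/residue) and extended zigzag
segments joined with small random bends; all virtual bonds lie in
[3.7, 3.9] Å and non-adjacent atoms are > 3 Å apart. The strand carries a
small aperiodic z-pleat so inter-atomic distances do not land on exact
histogram bin edges. `synth_decoys` adds chain-smoothed Gaussian noise
(moving average of iid displacements, window 5, rescaled to the requested
per-atom σ) — smoothing keeps local geometry protein-like so the structural
alphabet stays meaningful. Default noise levels (0.5, 1, 2, 3, 5, 8) Å are
cycled over decoys, spanning true GDT from ≈ 0.97 down to ≈ 0.2, a spread
comparable to real model pools that contain reasonably good decoys. An
optional majority cluster (fraction, spread) draws part of the pool around
one shared perturbed centre, reproducing the regime where consensus scoring
excels. True GDT is computed with the package's own gdt_ts, keeping
generator and evaluator consistent. `synth_scores` produces feature columns
with a target Spearman ρ to the truth via a Gaussian copula (Pearson
2·sin(πρ/6) on normal scores); ρ = ±1 short-circuits to exact (anti-)ranks.

What the generator does *not* emulate: systematically correlated errors
across decoys (prediction methods produce related wrong folds), incomplete
models, or sequence-dependent error profiles. Because decoy errors are
independent here, consensus GDT is close to a sufficient statistic and
reaches Spearman ≈ 0.99 on the default benchmark — far above what it
achieves on real pools — so passing tests demonstrate that the combination
machinery recovers and merges the information present, not that it would
match any particular published benchmark number.

## Problem sizes used in the shipped experiments

The headline leave-one-out experiment uses 20 targets × 40 decoys × 60
residues; the ablation study 10 seeds × 4 targets × 16 decoys with purely
score-based panels (one informative ρ = 0.6 column, four ρ = 0 columns);
the consensus-regime study 6 majority-cluster targets × 24 decoys; the
acceptance script 10 targets × 24 decoys × 50 residues. These sizes give
stable averages while keeping a full run on one CPU in minutes.

## Numerical choices and edge cases

* Kabsch superpositions exclude reflections (det +1 enforced); degenerate
  (collinear) point sets return one of the optimal transforms.
* GDT of bitwise-identical coordinate arrays short-circuits to 1.
* Angle triplets raise on coincident consecutive atoms and on collinear
  windows (undefined dihedral), naming the position.
* PSFM columns are validated to sum to 1 ± 1e−9; state models validate
  weight normalization and covariance positive-definiteness via Cholesky.
* Score tables reject NaN/±inf, duplicate ids and non-numeric rows by name.
* Decoy sets with inconsistent residue numbering are restricted to the
  common intersection; < 4 common residues is an error.
* All randomness flows from explicit integer seeds; every generator output
  and every training run is a pure function of its seed.

## Known limitations

* The GDT search is a deterministic heuristic beyond 12 residues; absolute
  values can sit a fraction of a percent below the combinatorial optimum
  (and below what the LGA program would report), uniformly across a pool,
  which leaves rankings essentially untouched.
* The bundled structural alphabet is trained on synthetic traces; PSPS
  rankings are insensitive to this, but the state labels themselves are not
  comparable to any published alphabet.
* The stand-in potential is intentionally simple (Cα-only, distance bins);
  it is a placeholder for real single-model scores, which should be supplied
  as external tables when available.
* Winning counts are integers, so very large pools of near-identical decoys
  produce many ties; the CGDT tie-break resolves ordering but Spearman is
  computed on the raw counts.
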
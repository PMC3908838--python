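# Methods

## Problem

A shotgun-proteomics database search assigns each MS/MS spectrum a best-matching
peptide, yielding peptide-spectrum matches (PSMs) of which a large fraction are
wrong. Searching a reversed/shuffled *decoy* database alongside the real
*target* database produces known-incorrect matches that calibrate error rates,
but the target PSMs themselves carry unreliable labels: a target hit may be
right or wrong. `fcranker` scores each target PSM with the possibility of its
being correct, combining two complementary lines of evidence:

1. a **classifier margin** — a kernel SVM trained to separate targets from
   decoys, where each target's influence is tempered by its current weight;
2. **cluster cohesion** — a silhouette index measuring whether the PSM sits
   inside the compact cloud of good targets and away from the decoys.

Neither alone suffices: a PSM can sit far on the correct side of the decision
boundary yet far from every other good target (an outlier), or nestle among
good targets with a near-zero margin. The score blends both.

## Model components

### Fuzzy linear-programming SVM

The discriminant is `f(x) = Σ_j α_j y_j k(x_j, x) + b` with the Gaussian kernel
`k(x, x') = exp(−‖x−x'‖²/(2σ²))`, σ = 2.0. Instead of the usual quadratic
program, the coefficients solve a linear program that maximises a margin
variable `r` against weight-scaled slacks:

    min −r + c Σ_i θ_i ξ_i
    s.t. y_i f(x_i) ≥ r − ξ_i,  −1 ≤ α_j ≤ 1,  ξ_i ≥ 0,  r ≥ 0,  b free,

with c = 1.0. The weight θ_i ∈ [0, 1] is the current possibility that target
i's +1 label is correct; decoys are pinned at θ = 1 since their −1 labels hold
by construction. A misclassified target with small θ costs little, so suspect
labels barely distort the boundary. With θ ≡ 1 the model reduces to the plain
LP-SVM.

The LP is always feasible (the zero solution) and is bounded in the intended
regime: raising `r` by one unit forces every slack up by one, costing
`c Σ θ_i ≥ c·|decoys|`; tilting `b` toward one class instead costs twice the
θ-mass of the other class, so boundedness needs each class's θ-mass to exceed
`1/(2c)`. At c = 1 with decoys at θ = 1 the decoy side is always safe; a
degenerate run that drives the total target mass below 0.5 would make the LP
unbounded and raises a hard error rather than returning nonsense. The solver
is HiGHS (dual simplex) via `scipy.optimize.linprog`; multiple optima are
possible in degenerate instances, so tests compare objectives and constraint
residuals, never raw coefficients.

**Large-scale reduction.** The kernel matrix is dense; for large collections a
random subset Ω′ of its columns (fraction `column_fraction`) replaces the full
expansion — only |Ω′| α-variables remain while constraints still cover all
samples. The column set is drawn once per run from the master seed.

### Fuzzy silhouette and separation

For the two groups Ω₁ (current good targets) and Ω₋₁ (decoys), every PSM gets

    β_i^k = Σ_{j∈Ω_k, j≠i} θ_j d(x_i,x_j) / Σ_{j∈Ω_k, j≠i} θ_j,
    s_i   = (β_i^{−1} − β_i^1) / max{β_i^{−1}, β_i^1} ∈ [−1, 1],

with Euclidean distance on the same weighted, normalised features the SVM
sees — one geometry keeps the two evidence channels commensurable. Down-
weighted targets pull less on the averages, so a contaminating bad target
inside Ω₁ stops distorting cohesion as its θ falls. With unit weights and two
groups this is exactly the classic silhouette. The separation statistic

    sep = (s̄₁ − s̄₋₁)/2

(half the gap between group-average silhouettes) serves two roles: the mixing
weight between classifier and clustering evidence, and the stopping statistic.
With `rho < 1` each group's reference set is a seeded subsample redrawn every
iteration, cutting the distance work from l² to about ρ·l².

Singleton groups have no within-group distance; their own silhouette is 0 by
the usual convention (with a warning). A group whose θ-mass is zero is a hard
error — the loop has degenerated.

### Scores and weights

    score(i) = (1 − sep)·φ(f(x_i)) + sep·ψ(s_i)
    φ(f) = (2/π)·sign(f − f₀)·atan((|f − f₀|/f_max)^{1/4})
    ψ(s) = (s − s₀)/s_max

where f_max and s_max are the largest deviations among target PSMs, recomputed
each iteration, and f₀ = s₀ = 0 (the decision boundary and the neutral
silhouette — the natural "uncertain" points; both configurable). The 1/4
exponent flattens φ near the threshold so that mid-range margins retain
distinct weights; the extreme target maps to ±0.5 (φ) and 1 (ψ). When sep is
small (early iterations, classifier barely validated by geometry) the score
leans on φ; as the good set separates, the silhouette takes over. sep is
clamped to [0, 1] inside the mix — a slightly negative early sep must not
invert the meaning of the silhouette term — while the raw value drives the
stop rule and the trace. Weights update as θ_i = max{score(i), 0} for targets,
1 for decoys.

## The iteration

Starting with Ω₁ = all targets and θ ≡ 1:

1. fit the weighted LP-SVM, evaluate f everywhere;
2. keep the top n% of Ω₁ by f (n = 70);
3. compute fuzzy silhouettes against the pruned Ω₁ and the decoys;
4. keep the top n% of the pruned set by s (net 49% retention per iteration
   before promotion);
5. promote any discarded target whose f is at least the mean f of the
   retained set (ties inclusive) — the result is the next good set Ω₁;
6. compute sep over the *promoted* good set, then scores and new θ;
7. stop when sep ≥ 0.25, when |Ω₁| ≤ 0.03·|targets| (the good set collapsed —
   reported distinctly; interpretation is the user's), or at the iteration cap
   (100 by default; a safety net absent from the underlying procedure).

The order of steps 5–6 matters: averaging sep over the subset that was just
selected *for* high silhouette would inflate it by construction — a selection
bias strong enough to push structureless data over the stopping threshold in
a non-trivial fraction of runs. Averaging over the promoted set, whose
members were re-admitted on classifier evidence alone, removes that bias;
on featureless null data the loop then collapses without ever declaring
separation, while planted-signal behaviour is unchanged.

Top-n% counts use the ceiling with a minimum of one, so rounding alone can
never empty the good set; boundary ties keep the lower original index so the
selection is deterministic. All randomness (column sampling, per-iteration
silhouette subsamples) derives from one master seed; identical input and seed
give bit-identical results.

## Preprocessing

Features are the six SEQUEST-style attributes: `xcorr`, `delta_cn`, `ions`,
`sprank`, `calc_neutral_pep_mass`, and the digest-conformity category coded
full = 2, half = 1, none = 0. Each column is z-scored with the population
(1/N) variance over **all** PSMs, targets and decoys jointly — the model sees
both classes, and joint scaling treats them symmetrically — then multiplied by
an importance weight: 2.0 for `xcorr`, `delta_cn` and `digest_type`, 1.0
otherwise. Constant columns become all-zero rather than erroring, so
degenerate inputs pass through preprocessing.

## Target-decoy evaluation

At a score threshold t, with FP = accepted decoys and TP + FP = accepted
targets, the estimated false discovery rate is FDR = 2·FP/(FP + TP) — the
decoy count estimates half of the incorrect accepted matches under the
equal-likelihood assumption for incorrect hits. `select_at_fdr` scans every
distinct observed score descending and returns the most permissive threshold
accepting at least one target within the level; accepting nothing trivially
has FDR 0, so an empty selection is reported with a warning instead of being
declared a success. FDR values are reported as computed, not monotonised into
q-values. ROC points enumerate TPR/FPR at every distinct threshold; AUC is the
trapezoidal area with the curve anchored at (0,0) and (1,1).

## Synthetic study conditions

The generator encodes the premise the method relies on: search output is a
three-population mixture — correct targets (compact cluster), incorrect
targets, and decoys — with the last two sharing one distribution, because a
random wrong match cannot tell which database it hit. Populations are
spherical Gaussians in a 5-dimensional latent space mapped by monotone affine
maps onto plausible attribute ranges (z-scoring undoes the maps, so the
geometry survives preprocessing); the digest category is drawn per class —
correct targets mostly fully digested, incorrect matches mostly non-specific,
mirroring the composition of real SEQUEST target/decoy sets. The mean shift
between correct and incorrect populations (default 3.0 within-group standard
deviations) points mostly along the `xcorr` axis (direction ∝ (0.9, 0.218,
0.218, 0.218, 0.218)), since that attribute carries the bulk of the signal in
practice.

Named conditions: `default` (300 targets of which 1/3 correct, 300 decoys,
shift 3.0), `hard` (shift 1.0), and `null` — the no-signal calibration
control, with zero shift **and** a single constant digest category. The
constant category matters: a shared non-degenerate categorical feature at
weight 2.0 creates well-separated modes in feature space, and the loop can
legitimately find a target subcluster (e.g. the rare fully-digested stratum)
geometrically separated from the decoy average even though targets and decoys
are exchangeable. That is real cluster structure, not hallucinated signal —
but the null condition exists to verify that *featureless* data cannot reach
the separation threshold, so it must contain no structure at all. Under the
null, scores carry no information about the arbitrary truth labels (AUC ≈
0.5) and the loop ends by good-set collapse or the iteration cap.

What the generator does **not** emulate: heavy-tailed and correlated
search-score distributions, charge-state strata, retention-time structure,
shared peptides across spectra, and target/decoy size imbalance. Passing tests
therefore demonstrate the algorithm's mechanics and calibration under its own
assumptions, not end-to-end performance on real LC-MS/MS searches.

## Problem sizes and numerics

The test-suite and acceptance runs use 600-PSM collections (300/300) across
five seeds — large enough for stable silhouette and LP behaviour, small enough
for interactive runs; the dense-kernel LP at this size solves in about a
second. The reduced modes are exercised at `column_fraction = 0.2` and
`rho = 0.2`. LP tolerances are the solver defaults (~1e-8); test comparisons
use 1e-6 where a solver is involved and exact arithmetic elsewhere. The
two-point closed form (one target, one decoy, ‖Δx‖ = 2, σ = 2: r = 1 −
e^{−1/2}, b = 0 by symmetry) anchors the LP assembly; an independently
assembled LP solved by interior point cross-checks random instances.

## Known limitations

- Scores are possibilities, not calibrated posteriors; no
  probability-of-correctness claim is made.
- The doubled-decoy FDR formula assumes equal-size target and decoy databases;
  it is applied as stated regardless of the actual ratio.
- Protein-level inference, spectrum processing and native search-engine
  output parsing are out of scope; input is the tab-separated PSM table
  described in the README.
- With extremely adversarial weights (total target θ-mass below 1/(2c)) the
  LP is unbounded and the run fails loudly rather than silently.
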
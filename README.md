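# fcranker

Confidence rescoring of peptide-spectrum matches (PSMs) from shotgun-proteomics
database searches, for anyone who has a SEQUEST-style target/decoy search
result and wants to know *which* target hits to trust and at what error rate.

A database search labels every target PSM +1, but a large fraction of those
labels are wrong. `fcranker` treats each target's label as uncertain and
iterates two models against the known-incorrect decoys:

- a **fuzzy linear-programming SVM** — maximise a margin `r` subject to
  `y_i f(x_i) ≥ r − ξ_i` with slack costs scaled by per-target weights
  `θ_i ∈ [0, 1]` (decoys pinned at θ = 1), solved as an LP with
  `−1 ≤ α_j ≤ 1` and an RBF kernel;
- a **fuzzy silhouette index** — the θ-weighted two-group silhouette
  `s_i = (β_i^{−1} − β_i^1)/max{β_i^{−1}, β_i^1}` measuring whether a PSM sits
  inside the good-target cloud and away from the decoys.

Each iteration prunes the good-target set to the top 70% by margin and then by
silhouette, blends the two signals into a score
`score(i) = (1 − sep)·φ(f(x_i)) + sep·ψ(s_i)` with the separation statistic
`sep = (s̄₁ − s̄₋₁)/2` as mixing weight, refreshes the weights
`θ_i = max{score(i), 0}`, and stops once `sep ≥ 0.25`. Accepted sets are then
chosen by target-decoy false-discovery-rate control, `FDR = 2·FP/(FP + TP)`.
See `docs/methods.md` for the full model account.

## Worked example

```python
from fcranker import FCRanker, generate, scenario

# 600 simulated PSMs: 300 targets (100 planted-correct), 300 decoys
coll = generate(scenario("default", seed=1))
results = FCRanker(coll, seed=1).fit()
print(results.summary())
```

```
FC-Ranker results
==================================================
PSMs:              600 (300 targets, 300 decoys)
Iterations:        2
Termination:       sep_reached
Final sep:         0.4683
|Omega_1| (good):  73
--------------------------------------------------
Acceptance at FDR <= 0.05:
  threshold:       -0.0449
  targets (TP+FP): 127
  decoys (FP):     3
  TP estimate:     124
  FDR estimate:    0.0472
```

The loop declared separation after two iterations: the good-set average
silhouette rose while the decoy average fell until their half-gap `sep`
cleared 0.25. At the 5% FDR level the score threshold −0.0449 accepts 127
target PSMs of which an estimated 124 are correct (3 accepted decoys estimate
the contamination). Per-iteration diagnostics live in `results.trace`;
per-PSM scores, weights, margins and silhouettes in `results.to_frame()`.

The same pipeline from the shell:

```sh
fcranker simulate --scenario default --seed 1 --output synth.tsv
fcranker run --input synth.tsv --output scores.tsv --trace trace.tsv --seed 1
fcranker evaluate --scores scores.tsv --level 0.05 --report report.tsv --truth
```

## Input format

A tab-separated table with header columns `psm_id`, `spectrum_ref`,
`peptide` (optional), `is_decoy` (0/1; or use `--decoy-prefix DECOY_` with a
`protein` column), `xcorr`, `delta_cn`, `ions`, `sprank`,
`calc_neutral_pep_mass`, `digest_type` (`full`/`half`/`none` or 2/1/0), and
optionally `truth` for simulated data. Features are z-scored jointly over
targets and decoys and weighted (2.0 for `xcorr`, `delta_cn`, `digest_type`)
before modelling.

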
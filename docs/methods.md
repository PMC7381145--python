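# Methods

## Model and procedure

`snetropy` scores one case sample at a time against a reference background
over a fixed interaction network, in six steps:

1. **Template network.** A STRING-style weighted edge list is filtered to
   edges with confidence strictly greater than `min_confidence` (default
   0.7, matching the usual "high confidence" STRING cutoff). Integer scores
   on 0–999 are auto-detected (any score > 1) and divided by 1000, so both
   raw STRING dumps and pre-normalized files are accepted. Self-loops are
   dropped, duplicate pairs collapse to their maximum score (this keeps the
   filter monotone in the threshold), and isolated nodes are removed.
   Network genes not present in the expression matrix are dropped rather
   than imputed — an unmeasured gene carries no state information and any
   imputation rule would be arbitrary.
2. **Segmentation.** The graph is cut into Q local (ego) networks, one per
   node: the center plus its first-order neighbors, neighbors ordered
   lexicographically for reproducibility.
3. **Background.** Per gene, a Gaussian `N(μ_g, σ_g²)` is fitted from the
   reference samples (sample mean; SD with the n−1 denominator; at least two
   references required).
4. **Deviation states.** A case value is a deviation (state 1) when it falls
   outside the central `1 − α` interval of its background,
   `|x − μ| > z_{1−α/2}·σ`. The tail mass α defaults to 0.05 and is a config
   knob; the interval is two-sided because up- and down-regulation are
   treated symmetrically. A gene with σ = 0 has a point-mass background, so
   any departure from its mean counts as deviating; this convention also
   avoids dividing by zero in a z-score. No multiple-testing correction is
   applied across genes — the state function is deliberately per-gene, and
   the α-rate of false states is part of the method's calibration (see the
   null-calibration test). Expression values are used as provided; supply
   log/normalized matrices if that is your background of interest.
5. **Entropy.** Within a local network the states are normalized to a
   probability vector and scored by scaled Shannon entropy
   `Hⁿ = −1/(m+1) Σ p_i ln p_i` (natural log; the base only rescales all
   scores uniformly and cannot move the curve's peak). When no member
   deviates the normalization would divide by zero; the all-zero vector is
   treated as a sentinel with `Hⁿ = 0` — no deviation means no perturbation
   signal. Since states are binary, `Hⁿ = ln(k)/(m+1)` for k ≥ 1 deviating
   members, giving the bound `Hⁿ ≤ ln(m+1)/(m+1)` with equality iff the
   whole local network deviates.
6. **Global score and verdict.** Per sample, the L = ⌈top_fraction·Q⌉
   largest local scores are summed (top_fraction default 0.05; the ceiling
   guarantees L ≥ 1; ties at the cutoff break lexicographically). Per-stage
   means of the per-sample scores form the stage curve; the critical stage
   is its argmax (earliest stage on exact ties). Because "sharp peak" needs
   a quantitative reading, the verdict also reports
   `signal_ratio = peak / median(other stage means)` (infinite when that
   median is 0) and flags `no_signal` when the ratio is below 2: a curve
   whose peak is less than twice the typical stage level is not an
   early-warning spike.

Per-stage aggregation uses the mean of per-sample scores; stages are an
ordered categorical axis and no interpolation between stages is done.

## The simulator

The synthetic generator emulates the canonical DNB validation setting: a
16-node regulatory network whose steady state loses stability at a known
control-parameter value, sampled along a parameter sweep.

* **Topology.** Nodes `G01…G16`; the first 4 form the DNB group, wired as a
  clique. Every non-DNB node attaches to two DNB nodes (round-robin) and to
  its neighbors on a ring over the non-DNB nodes. Consequently every ego
  network contains at least two DNB members, so every center can express a
  co-deviation spike near criticality — mirroring the observation that local
  scores rise broadly, and most strongly for DNB-centered locals, at the
  tipping point.
* **Dynamics.** Latent Ornstein–Uhlenbeck-type factors integrated by
  Euler–Maruyama (dt = 0.05): a slow collective mode `s` loaded only on DNB
  nodes, a fast shared factor `f` (eigenvalue −1) loaded on every node, and
  private fast fluctuations per node. The slow mode's eigenvalue is `p` on
  the pre-transition branch (p ≤ 0) and `−p` on the emergent post-transition
  branch (p > 0, fixed point offset `0.5·p`): the quasi-statically
  linearized normal form of a transcritical bifurcation at p = 0. A linear
  surrogate suffices because the DNB early-warning phenomenon depends only
  on the leading eigenvalue approaching zero, not on specific kinetics; the
  model specification is serialized to `model.json` so nonlinear kinetics
  can be substituted. Observed expression is
  `baseline + loadings·latents`, floored at 0 to keep the synthetic data
  shaped like the non-negative input contract.
* **Why the three DNB conditions emerge.** Var(s) ≈ σ²/(2|p|) inflates as
  |p| → 0 (at p = 0 the mode is marginal and finite-time fluctuations grow
  with the integration horizon), driving SD_in up; the slow mode's growing
  share of DNB variance drives within-group correlation toward 1 (PCC_in
  up); the DNB–rest correlation is mediated by the fixed-variance fast
  factor, so it is progressively drowned out (PCC_out down).
* **Sampling.** 50 reference samples are drawn at the most stable grid value
  (p = −0.5), standing in for the "relatively normal" background cohort;
  10 case samples per grid value p ∈ {−0.5, …, 0.2}. Burn-in is 1000 steps
  (50 time units) and retained draws are thinned by 150 steps (7.5 time
  units) so that draws at stable grid values are close to independent while
  the critical point's persistent fluctuations remain coherent — without
  thinning, autocorrelated draws at stable p occasionally produce spurious
  whole-stage spikes. Noise scale 0.1 against a baseline of 5 expression
  units, i.e. a ~2–3% coefficient of variation in the stable regime. All
  randomness flows from a single integer seed through per-grid-value
  `SeedSequence` streams; a run is bit-for-bit reproducible from its config.

### What the simulator does and does not emulate

It reproduces the features the method relies on: a reference cohort, staged
case cohorts, variance/correlation restructuring near a critical transition,
and non-negative expression with stationary noise. It does **not** emulate
heavy-tailed or count-distributed expression, batch effects, sample-specific
library sizes, or networks with thousands of nodes. Passing tests therefore
demonstrate that the pipeline detects a genuine bifurcation signature under
Gaussian-like noise; they do not certify performance on RNA-seq-scale data,
where normalization quality and background non-normality matter.

## Numerical choices

* Probability-vector validation tolerance 1e−9; oracle agreement asserted at
  1e−12 (pure floating-point identity of two evaluation orders).
* Euler–Maruyama divergence guard: any latent exceeding 1e6 in magnitude
  raises with a suggestion to reduce dt.
* Per-stage SD is reported as 0 for single-sample stages (n−1 convention
  undefined there).
* Floats in reports are serialized at 12 significant digits; identical
  config + inputs give byte-identical outputs.
* Constant nodes in the diagnostics get correlation 0 with a warning rather
  than NaN.

## Problem sizes used in the shipped validation

The packaged validation sweeps use the default conditions above (16 nodes,
8 grid values, 50 + 8×10 samples, ~20k integration steps per sweep); the
seed-robustness check repeats the full sweep 20 times and the DNB-condition
diagnostics use 200 case samples per grid value. These sizes make the whole
validation run in well under a minute on one CPU while leaving the
Monte-Carlo margins (e.g. the 18-of-20 seed criterion) comfortable.

## Known limitations

* The critical-stage call is an argmax: exactly one stage is named even for
  flat curves — always check `no_signal` and `signal_ratio`.
* The Gaussian background is not robust to reference outliers (no
  median/MAD option) and assumes pooled, exchangeable reference samples.
* Identifier spaces of the network and the expression matrix must already
  match; no Ensembl↔symbol conversion is performed.
* Edge weights are used only for thresholding; the entropy itself is
  unweighted.
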
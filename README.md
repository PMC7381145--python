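# snetropy

Single-sample node entropy (SNE) for detecting the **critical
(pre-deterioration) stage** of a progressing disease from staged expression
cohorts and a prior interaction network.

Complex diseases often pass through a tipping point: a stage at which the
system abruptly transitions from a relatively normal state into the disease
state. Dynamic network biomarker (DNB) theory predicts early-warning signals
just before this transition — a group of molecules whose variance and mutual
correlation rise sharply while their correlation with the rest of the network
falls. `snetropy` turns these signals into a score computable from **one case
sample at a time**, so it works in clinical settings where per-stage samples
are scarce.

## The method

Given a template protein–protein interaction network with Q nodes, the graph
is segmented into Q *local networks*: each gene `g^k` together with its
first-order neighbors `g_1^k … g_m^k`. From reference (control) samples, a
Gaussian background `N(μ_g, σ_g²)` is fitted per gene. For a single case
sample, each gene's binary deviation state is

    state(g) = 1   iff  |x_g − μ_g| > z_{1−α/2} · σ_g      (default α = 0.05)

The states of a local network are normalized to a probability vector
`p_i = state(g_i^k) / Σ_j state(g_j^k)` and the **local SNE** is the scaled
Shannon entropy

    Hⁿ(g^k) = −1/(m+1) · Σ_{i=0}^{m} p_i ln p_i

The **global SNE score** of the sample sums the top 5% largest local scores:
`H = Σ_{k=1}^{L} Hⁿ(g^k)`, `L = ⌈0.05·Q⌉`. Averaged per clinical stage, `H`
stays low in stable stages and spikes at the critical stage; the spike's
argmax is reported as the verdict together with a `signal_ratio` diagnostic
(peak / median of the other stages, "no signal" below 2).

The package also ships a stochastic simulator of a 16-node regulatory network
whose steady state loses stability at control parameter `p = 0`
(transcritical bifurcation; a 4-node DNB group shares a slow mode with
linearization eigenvalue `p`), used to validate the method end to end.

## Worked example

Generate a synthetic bundle and sweep it:

```
$ snetropy simulate --out sim --seed 1
$ snetropy sweep --config sim/config.yaml
{
  "critical_stage": "p=+0.0",
  "signal_ratio": 3.101955000865387,
  "no_signal": false,
  "per_stage": [
    {"stage": "p=-0.5", "mean_h": 0.006931471805599452, "sd_h": 0.0219..., "n": 10},
    ...
    {"stage": "p=-0.1", "mean_h": 0.0855333223803211,   "sd_h": 0.0948..., "n": 10},
    {"stage": "p=+0.0", "mean_h": 0.10750556815368328,  "sd_h": 0.0982..., "n": 10},
    {"stage": "p=+0.1", "mean_h": 0.04158883083359671,  "sd_h": 0.0669..., "n": 10},
    ...
  ]
}
```

The stage-mean score is near zero deep in the stable regime (`p = −0.5`),
rises as the bifurcation approaches and peaks exactly at the critical value
`p = 0` — the early-warning spike. The verdict names that stage as critical
with a signal ratio of 3.1 (> 2, a genuine signal). The output directory also
receives per-sample scores (`scores.tsv`), the per-center local-entropy table
with the selected top genes (`local_sne.tsv`), a long per-gene node-entropy
export for downstream survival/enrichment tools (`gene_entropy.tsv`), the
stage curve (`stage_curve.tsv`) and the verdict JSON.

To score real data, supply your own STRING-style edge list (scores above the
0.7 confidence threshold are kept), a genes × samples expression matrix and a
two-column manifest (`sample_id`, `stage`; reference samples labelled
`reference`) via a YAML config — see `sim/config.yaml` for the layout.

Single-sample scoring:

```
$ snetropy score --network sim/network.tsv --expression sim/expression.tsv \
    --manifest sim/manifest.tsv --sample "p=+0.0_s002"
{"sample": "p=+0.0_s002", "H": 0.13862943611198905, "L": 1, "Q": 16}
```

Here the single near-critical sample's best local network has two of its five
members deviating simultaneously (`H = ln 2 / 5 ≈ 0.139`); individual samples
far from the transition mostly score exactly 0.

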
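"""Synthetic regulatory network losing stability at control parameter p = 0.

The generator emulates the classic dynamic-network-biomarker (DNB) setting:
a small regulatory network (16 nodes by default) whose steady state undergoes
a codimension-1 (transcritical) bifurcation at p = 0.  A designated DNB group
shares a slow collective mode whose linearization eigenvalue equals p on the
pre-transition branch, so as p rises toward 0 the group shows the three DNB
early-warning conditions: its variance inflates (SD_in up), its internal
correlation approaches 1 (PCC_in up), and its correlation with the rest of
the network — mediated by a fast shared factor of fixed variance — is
progressively drowned out (PCC_out down).

Node expressions are observed as

    x_i = baseline + a * s + c * f + e_i        (DNB nodes)
    x_j = baseline + c * f + e_j                (non-DNB nodes)

where s is the slow mode (eigenvalue p for p <= 0; after the bifurcation the
system follows the emergent branch with eigenvalue -p and fixed-point offset
proportional to p), f is a shared fast factor (eigenvalue -1) and e are
private fast fluctuations (eigenvalue -1).  All latent variables follow
Ornstein-Uhlenbeck-type SDEs integrated by Euler-Maruyama; expressions are
floored at 0.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import background, detect, entropy
from .network import TemplateNetwork
import networkx as nx

__all__ = [
    "SimulationConfig",
    "RegulatoryModel",
    "SimulationRun",
    "Fig2Result",
    "build_model",
    "sample_steady_state",
    "simulate_run",
    "dnb_diagnostics",
    "run_fig2_experiment",
    "write_bundle",
]

logger = logging.getLogger(__name__)

_DIVERGENCE_CAP = 1e6


def _default_p_grid() -> tuple[float, ...]:
    return tuple(round(-0.5 + 0.1 * i, 10) for i in range(8))  # -0.5 .. 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic sweep.

    Defaults: a 16-node network with 4 DNB nodes, control parameter swept
    over p = -0.5 .. 0.2 in steps of 0.1, 50 reference samples drawn at the
    most stable grid value and 10 case samples per grid value.
    """

    n_nodes: int = 16
    n_dnb: int = 4
    p_grid: tuple[float, ...] = field(default_factory=_default_p_grid)
    n_reference: int = 50
    n_case_per_p: int = 10
    noise_sd: float = 0.1
    seed: int = 1
    baseline: float = 5.0
    slow_loading: float = 1.0       # a: DNB loading on the slow mode
    shared_fast_loading: float = 0.5  # c: loading of every node on the fast factor
    post_shift: float = 0.5         # slow-mode fixed point k*p on the p > 0 branch
    dt: float = 0.05
    burn_in_steps: int = 1000
    thin_steps: int = 150

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or not 1 <= self.n_dnb < self.n_nodes:
            raise ValueError("need n_nodes >= 2 and 1 <= n_dnb < n_nodes")
        if any(b <= a for a, b in zip(self.p_grid, self.p_grid[1:])):
            raise ValueError("p_grid must be strictly increasing")
        if self.n_reference < 1 or self.n_case_per_p < 1:
            raise ValueError("sample counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def node_names(self) -> tuple[str, ...]:
        width = len(str(self.n_nodes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_nodes))

    @property
    def dnb_nodes(self) -> tuple[str, ...]:
        return self.node_names[: self.n_dnb]


@dataclass(frozen=True)
class RegulatoryModel:
    """Serializable specification of the stochastic regulatory-network model."""

    config: SimulationConfig
    nodes: tuple[str, ...]
    dnb_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    @property
    def non_dnb_nodes(self) -> tuple[str, ...]:
        dnb = set(self.dnb_nodes)
        return tuple(n for n in self.nodes if n not in dnb)

    def slow_eigenvalue(self, p: float) -> float:
        """Leading eigenvalue of the occupied branch: p before, -p after the bifurcation."""
        return p if p <= 0 else -p

    def slow_fixed_point(self, p: float) -> float:
        """Slow-mode fixed point: 0 on the normal branch, k*p after the transition."""
        return 0.0 if p <= 0 else self.config.post_shift * p

    def template_network(self) -> TemplateNetwork:
        graph = nx.Graph()
        graph.add_edges_from(self.edges)
        return TemplateNetwork.from_graph(graph)

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "nodes": list(self.nodes),
            "dnb_nodes": list(self.dnb_nodes),
            "edges": [list(e) for e in self.edges],
            "dynamics": {
                "type": "linearized transcritical bifurcation (OU latent factors)",
                "slow_eigenvalue": "p for p <= 0, -p for p > 0",
                "slow_fixed_point": f"0 for p <= 0, {cfg.post_shift}*p for p > 0",
                "fast_eigenvalue": -1.0,
                "slow_loading": cfg.slow_loading,
                "shared_fast_loading": cfg.shared_fast_loading,
                "noise_sd": cfg.noise_sd,
                "baseline": cfg.baseline,
                "dt": cfg.dt,
                "burn_in_steps": cfg.burn_in_steps,
                "thin_steps": cfg.thin_steps,
            },
        }


def build_model(config: SimulationConfig) -> RegulatoryModel:
    """Build the network topology and dynamics specification.

    DNB nodes are densely wired (a clique); every non-DNB node attaches to two
    DNB nodes (round-robin) and to its neighbors on a ring over the non-DNB
    nodes, so each local network contains at least two DNB members and can
    express a co-deviation spike near criticality.
    """
    nodes = config.node_names
    dnb = list(config.dnb_nodes)
    rest = [n for n in nodes if n not in set(dnb)]

    edges: list[tuple[str, str]] = []
    for i in range(len(dnb)):
        for j in range(i + 1, len(dnb)):
            edges.append((dnb[i], dnb[j]))
    for idx, node in enumerate(rest):
        edges.append((dnb[idx % len(dnb)], node))
        if len(dnb) > 1:
            edges.append((dnb[(idx + 1) % len(dnb)], node))
    if len(rest) > 2:
        for idx, node in enumerate(rest):
            edges.append((node, rest[(idx + 1) % len(rest)]))
    elif len(rest) == 2:
        edges.append((rest[0], rest[1]))

    uniq = sorted({tuple(sorted(e)) for e in edges})
    return RegulatoryModel(
        config=config, nodes=nodes, dnb_nodes=tuple(dnb), edges=tuple(uniq)
    )


def sample_steady_state(
    model: RegulatoryModel, p: float, n: int, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Draw ``n`` quasi-stationary expression samples at control parameter ``p``.

    Latent factors start on the occupied fixed point and are integrated by
    Euler-Maruyama for a fixed burn-in, after which ``n`` temporally thinned
    draws are read out.  Deterministic given the seed.  At p = 0 the slow
    mode is marginal (no stationary law); the draws then reflect the growing
    finite-time fluctuations characteristic of criticality.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = model.config
    rng = np.random.default_rng(seed)
    lam = model.slow_eigenvalue(p)
    s_star = model.slow_fixed_point(p)
    n_nodes = len(model.nodes)
    dnb_mask = np.array([node in set(model.dnb_nodes) for node in model.nodes])

    dt = cfg.dt
    sq = math.sqrt(dt) * cfg.noise_sd
    s = s_star
    f = 0.0
    e = np.zeros(n_nodes)

    draws = np.empty((n_nodes, n))
    total = cfg.burn_in_steps + n * cfg.thin_steps
    next_draw = cfg.burn_in_steps + cfg.thin_steps
    k = 0
    for step in range(1, total + 1):
        s += lam * (s - s_star) * dt + sq * rng.standard_normal()
        f += -f * dt + sq * rng.standard_normal()
        e += -e * dt + sq * rng.standard_normal(n_nodes)
        if abs(s) > _DIVERGENCE_CAP or np.abs(e).max() > _DIVERGENCE_CAP:
            raise RuntimeError(
                f"simulation diverged at p={p} (step {step}); use a smaller dt"
            )
        if step == next_draw:
            x = cfg.baseline + cfg.shared_fast_loading * f + e
            x = x + np.where(dnb_mask, cfg.slow_loading * s, 0.0)
            draws[:, k] = np.maximum(x, 0.0)
            k += 1
            next_draw += cfg.thin_steps
    return pd.DataFrame(draws, index=list(model.nodes))


@dataclass
class SimulationRun:
    """Output of one full parameter sweep."""

    config: SimulationConfig
    model: RegulatoryModel
    reference: pd.DataFrame
    cases: dict[float, pd.DataFrame]
    diagnostics: pd.DataFrame | None = None


def _seed_for(config_seed: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config_seed, spawn_key=(stream,))


def simulate_run(config: SimulationConfig) -> SimulationRun:
    """Sweep the grid: reference matrix at the most stable grid value, then
    ``n_case_per_p`` case samples at every grid value; fully reproducible from
    (config, seed)."""
    model = build_model(config)
    p_ref = config.p_grid[0]
    reference = sample_steady_state(
        model, p_ref, config.n_reference, _seed_for(config.seed, 0)
    )
    reference.columns = [f"ref{i + 1:03d}" for i in range(config.n_reference)]
    cases: dict[float, pd.DataFrame] = {}
    for gi, p in enumerate(config.p_grid, start=1):
        mat = sample_steady_state(
            model, p, config.n_case_per_p, _seed_for(config.seed, gi)
        )
        mat.columns = [
            f"{_stage_label(p)}_s{i + 1:03d}" for i in range(config.n_case_per_p)
        ]
        cases[p] = mat
    return SimulationRun(config=config, model=model, reference=reference, cases=cases)


def _stage_label(p: float) -> str:
    return f"p={p:+.1f}"


def _mean_abs_corr(mat: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray) -> float:
    """Mean |Pearson r| over pairs (a in rows_a, b in rows_b); constant rows -> r = 0."""
    sd = mat.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant node(s); their correlations set to 0", const.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    vals = []
    for a in rows_a:
        for b in rows_b:
            if a != b:
                vals.append(abs(corr[a, b]))
    return float(np.mean(vals))


def dnb_diagnostics(run: SimulationRun) -> pd.DataFrame:
    """Per-grid-value DNB early-warning diagnostics.

    SD_in: mean standard deviation over DNB nodes; PCC_in: mean |Pearson r|
    over DNB pairs; PCC_out: mean |Pearson r| over (DNB, non-DNB) pairs.
    """
    if run.config.n_case_per_p < 3:
        raise ValueError("diagnostics need n_case_per_p >= 3")
    nodes = list(run.model.nodes)
    dnb_idx = np.array([nodes.index(n) for n in run.model.dnb_nodes])
    out_idx = np.array([nodes.index(n) for n in run.model.non_dnb_nodes])
    rows = []
    for p, mat in sorted(run.cases.items()):
        arr = mat.to_numpy()
        sd_in = float(arr[dnb_idx].std(axis=1, ddof=1).mean())
        pcc_in = _mean_abs_corr(arr, dnb_idx, dnb_idx)
        pcc_out = _mean_abs_corr(arr, dnb_idx, out_idx)
        rows.append({"p": p, "SD_in": sd_in, "PCC_in": pcc_in, "PCC_out": pcc_out})
    diag = pd.DataFrame(rows).set_index("p")
    run.diagnostics = diag
    return diag


@dataclass
class Fig2Result:
    """End-to-end sweep result: SNE curve over p with the detected critical value."""

    run: SimulationRun
    series: detect.StageSeries
    scores: dict[str, entropy.GlobalScore]
    local_sne: pd.DataFrame  # centers x case samples
    manifest: dict[str, str]
    stage_order: tuple[str, ...]

    @property
    def critical_p(self) -> float:
        return float(self.series.critical_stage.split("=")[1])

    def local_sne_stage_means(self) -> pd.DataFrame:
        """Per-center mean local SNE at each grid value (centers x stages)."""
        stages = pd.Series({s: self.manifest[s] for s in self.local_sne.columns})
        return self.local_sne.T.groupby(stages).mean().T[list(self.stage_order)]


def run_fig2_experiment(
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
    top_fraction: float = 0.05,
) -> Fig2Result:
    """Full validation sweep: simulate, fit the background on the reference
    draws, score every case sample and locate the spike of the SNE curve."""
    config = config or SimulationConfig()
    run = simulate_run(config)
    net = run.model.template_network()
    model_bg = background.fit_background(run.reference, alpha=alpha)

    scores: dict[str, entropy.GlobalScore] = {}
    manifest: dict[str, str] = {}
    local_cols: dict[str, pd.Series] = {}
    for p, mat in sorted(run.cases.items()):
        stage = _stage_label(p)
        for sample in mat.columns:
            states = background.sample_states(model_bg, mat[sample])
            profile = entropy.sample_entropy_profile(net, states)
            scores[sample] = entropy.global_sne(profile, top_fraction=top_fraction)
            local_cols[sample] = profile.sne
            manifest[sample] = stage
    stage_order = tuple(_stage_label(p) for p in config.p_grid)
    series = detect.stage_curve(scores, manifest, stage_order)
    series = detect.detect_critical_stage(series)
    return Fig2Result(
        run=run,
        series=series,
        scores=scores,
        local_sne=pd.DataFrame(local_cols),
        manifest=manifest,
        stage_order=stage_order,
    )


def write_bundle(run: SimulationRun, outdir: str | Path) -> dict[str, Path]:
    """Write a simulation bundle directly consumable by the scoring pipeline.

    Files: ``network.tsv`` (edge list), ``expression.tsv`` (genes x samples,
    reference + cases), ``manifest.tsv`` (sample, stage; references labelled
    ``reference``), ``diagnostics.tsv``, ``model.json`` and a pre-filled
    ``config.yaml`` for ``snetropy sweep``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    net_path = outdir / "network.tsv"
    with net_path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in run.model.edges:
            fh.write(f"{a}\t{b}\t1.0\n")
    paths["network"] = net_path

    expr = pd.concat([run.reference] + [run.cases[p] for p in run.config.p_grid], axis=1)
    expr_path = outdir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", index_label="gene", float_format="%.12g")
    paths["expression"] = expr_path

    man_path = outdir / "manifest.tsv"
    with man_path.open("w") as fh:
        fh.write("sample_id\tstage\n")
        for col in run.reference.columns:
            fh.write(f"{col}\treference\n")
        for p in run.config.p_grid:
            for col in run.cases[p].columns:
                fh.write(f"{col}\t{_stage_label(p)}\n")
    paths["manifest"] = man_path

    diag = run.diagnostics if run.diagnostics is not None else dnb_diagnostics(run)
    diag_path = outdir / "diagnostics.tsv"
    diag.to_csv(diag_path, sep="\t", float_format="%.12g")
    paths["diagnostics"] = diag_path

    model_path = outdir / "model.json"
    model_path.write_text(json.dumps(run.model.to_dict(), indent=2) + "\n")
    paths["model"] = model_path

    cfg_path = outdir / "config.yaml"
    stage_order = [_stage_label(p) for p in run.config.p_grid]
    cfg_lines = [
        f"network: {net_path.name}",
        f"expression: {expr_path.name}",
        f"manifest: {man_path.name}",
        "outdir: results",
        "alpha: 0.05",
        "min_confidence: 0.7",
        "top_fraction: 0.05",
        "reference_label: reference",
        "stage_order: [" + ", ".join(f'"{s}"' for s in stage_order) + "]",
        "",
    ]
    cfg_path.write_text("\n".join(cfg_lines))
    paths["config"] = cfg_path
    return paths
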
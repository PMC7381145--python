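"""End-to-end scoring pipeline: network + expression + manifest -> stage verdict.

Composes the method's six steps: map genes onto the template network, segment
it into local networks, fit the per-gene Gaussian background from the
reference samples, derive each case sample's deviation states, compute local
and global single-sample node entropy, and locate the critical stage on the
ordered stage curve.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import background, detect, entropy, io, network

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every numeric knob has a documented default."""

    network: Path
    expression: Path
    manifest: Path
    outdir: Path
    alpha: float = 0.05
    min_confidence: float = 0.7
    top_fraction: float = 0.05
    stage_order: tuple[str, ...] | None = None
    reference_label: str = "reference"
    no_signal_ratio: float = detect.DEFAULT_NO_SIGNAL_RATIO

    def __post_init__(self) -> None:
        self.network = Path(self.network)
        self.expression = Path(self.expression)
        self.manifest = Path(self.manifest)
        self.outdir = Path(self.outdir)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML config; keyword overrides (e.g. from CLI flags) win.

        Relative paths in the file are resolved against its directory.
        """
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if "stage_order" in raw and raw["stage_order"] is not None:
            raw["stage_order"] = tuple(str(s) for s in raw["stage_order"])
        for key, value in overrides.items():
            if value is not None:
                raw[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for attr in ("network", "expression", "manifest", "outdir"):
            p = getattr(cfg, attr)
            if not p.is_absolute():
                setattr(cfg, attr, path.parent / p)
        return cfg


@dataclass
class PipelineResult:
    series: detect.StageSeries
    scores: dict[str, entropy.GlobalScore]
    profiles: dict[str, entropy.LocalEntropyProfile]
    net: network.TemplateNetwork
    files: dict[str, Path] = field(default_factory=dict)


def _split_samples(
    expr: pd.DataFrame, manifest: pd.Series, reference_label: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    unknown = [s for s in expr.columns if s not in manifest.index]
    if unknown:
        raise KeyError(
            f"expression sample(s) missing from manifest: {', '.join(unknown[:5])}"
        )
    missing = [s for s in manifest.index if s not in expr.columns]
    if missing:
        raise KeyError(
            f"manifest references unknown sample(s): {', '.join(missing[:5])}"
        )
    ref_samples = [s for s in expr.columns if manifest[s] == reference_label]
    case_samples = [s for s in expr.columns if manifest[s] != reference_label]
    if not ref_samples:
        raise ValueError(f"no reference samples (stage label {reference_label!r}) found")
    if not case_samples:
        raise ValueError("no case samples found")
    return expr[ref_samples], expr[case_samples], manifest[case_samples]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full scoring pipeline and write the report files.

    Writes into ``config.outdir``: per-sample global scores (TSV), per-sample
    selected top-gene tables (TSV), the long per-gene node-entropy table, the
    stage curve (TSV) and the verdict JSON.  On error, partial outputs are
    removed and the exception propagates.
    """
    written: list[Path] = []
    try:
        return _run_pipeline(config, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_pipeline(config: RunConfig, written: list[Path]) -> PipelineResult:
    net = network.read_edge_list(config.network, min_confidence=config.min_confidence)
    logger.info("network: %d nodes, %d edges after confidence filter > %g",
                net.q, net.graph.number_of_edges(), config.min_confidence)

    expr = io.read_expression(config.expression)
    manifest = io.read_manifest(config.manifest)
    ref, cases, case_stages = _split_samples(expr, manifest, config.reference_label)
    logger.info("samples: %d reference, %d case", ref.shape[1], cases.shape[1])

    n_before = net.q
    net = network.restrict_to_measured(net, set(expr.index))
    logger.info("gene universe: %d network genes measured (%d dropped); Q = %d",
                net.q, n_before - net.q, net.q)

    stage_order = config.stage_order
    if stage_order is None:
        stage_order = tuple(sorted(set(case_stages)))
        logger.warning("no stage_order supplied; using lexicographic order %s",
                       list(stage_order))
    bad_stages = sorted(set(case_stages) - set(stage_order))
    if bad_stages:
        raise KeyError(f"manifest stage(s) not in stage_order: {bad_stages}")

    model = background.fit_background(ref.loc[list(net.graph.nodes)], alpha=config.alpha)

    scores: dict[str, entropy.GlobalScore] = {}
    profiles: dict[str, entropy.LocalEntropyProfile] = {}
    for sample in cases.columns:
        states = background.sample_states(model, cases[sample])
        profile = entropy.sample_entropy_profile(net, states)
        profiles[sample] = profile
        scores[sample] = entropy.global_sne(profile, top_fraction=config.top_fraction)
    any_score = next(iter(scores.values()))
    logger.info("scoring: Q = %d local networks, L = %d aggregated (top %g)",
                any_score.q, any_score.l, config.top_fraction)

    series = detect.stage_curve(scores, case_stages.to_dict(), stage_order)
    series = detect.detect_critical_stage(series, no_signal_ratio=config.no_signal_ratio)
    logger.info("verdict: critical stage %s (signal ratio %.3g%s)",
                series.critical_stage, series.signal_ratio,
                ", no signal" if series.no_signal else "")

    files = _write_reports(config, series, scores, profiles, case_stages, written)
    return PipelineResult(series=series, scores=scores, profiles=profiles,
                          net=net, files=files)


def _sanitize_json(obj: Any) -> Any:
    """Replace non-finite floats (valid in Python, not in JSON) by strings."""
    if isinstance(obj, dict):
        return {k: _sanitize_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize_json(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def _write_reports(
    config: RunConfig,
    series: detect.StageSeries,
    scores: dict[str, entropy.GlobalScore],
    profiles: dict[str, entropy.LocalEntropyProfile],
    case_stages: pd.Series,
    written: list[Path],
) -> dict[str, Path]:
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def track(name: str, path: Path) -> Path:
        written.append(path)
        files[name] = path
        return path

    score_rows = [
        {"sample": s, "stage": case_stages[s], "H": sc.h, "L": sc.l, "Q": sc.q}
        for s, sc in sorted(scores.items())
    ]
    pd.DataFrame(score_rows).to_csv(
        track("scores", outdir / "scores.tsv"), sep="\t", index=False,
        float_format=io.FLOAT_FORMAT,
    )

    top_rows = []
    for sample, sc in sorted(scores.items()):
        profile = profiles[sample]
        selected = set(sc.selected_centers)
        tab = profile.table()
        tab.insert(0, "sample", sample)
        tab["selected_in_top"] = tab["center_gene"].isin(selected).astype(int)
        top_rows.append(tab)
    pd.concat(top_rows, ignore_index=True).to_csv(
        track("local_sne", outdir / "local_sne.tsv"), sep="\t", index=False,
        float_format=io.FLOAT_FORMAT,
    )

    gene_table = io.export_gene_entropy_table(profiles, case_stages.to_dict())
    gene_table.to_csv(
        track("gene_entropy", outdir / "gene_entropy.tsv"), sep="\t", index=False,
        float_format=io.FLOAT_FORMAT,
    )

    curve = pd.DataFrame(
        {"stage": series.stages, "mean_H": series.mean_h,
         "sd_H": series.sd_h, "n": series.n_samples}
    )
    curve.to_csv(track("stage_curve", outdir / "stage_curve.tsv"), sep="\t",
                 index=False, float_format=io.FLOAT_FORMAT)

    verdict_path = track("verdict", outdir / "verdict.json")
    verdict_path.write_text(
        json.dumps(_sanitize_json(series.as_dict()), indent=2, allow_nan=False) + "\n"
    )
    return files
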
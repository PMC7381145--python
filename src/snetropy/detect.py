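"""Stage-curve aggregation and critical-stage detection.

Per-sample global SNE scores are grouped by ordered clinical stage; the
critical (pre-deterioration) stage is the spike of the stage-mean curve.
The spike strength is reported as ``signal_ratio`` = peak mean divided by the
median of the other stage means; curves whose ratio falls below a no-signal
threshold (default 2) are flagged as carrying no early-warning signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .entropy import GlobalScore

__all__ = ["StageSeries", "stage_curve", "detect_critical_stage"]

logger = logging.getLogger(__name__)

DEFAULT_NO_SIGNAL_RATIO = 2.0


@dataclass
class StageSeries:
    """Ordered per-stage summary of global SNE scores.

    ``critical_stage`` and ``signal_ratio`` are populated by
    :func:`detect_critical_stage`.
    """

    stages: tuple[str, ...]
    mean_h: tuple[float, ...]
    sd_h: tuple[float, ...]
    n_samples: tuple[int, ...]
    critical_stage: str | None = None
    signal_ratio: float | None = None
    no_signal: bool | None = None
    no_signal_ratio: float = DEFAULT_NO_SIGNAL_RATIO

    def as_dict(self) -> dict:
        per_stage = [
            {"stage": s, "mean_h": m, "sd_h": sd, "n": n}
            for s, m, sd, n in zip(self.stages, self.mean_h, self.sd_h, self.n_samples)
        ]
        return {
            "critical_stage": self.critical_stage,
            "signal_ratio": self.signal_ratio,
            "no_signal": self.no_signal,
            "per_stage": per_stage,
        }


def _score_value(score: GlobalScore | float) -> float:
    return score.h if isinstance(score, GlobalScore) else float(score)


def stage_curve(
    scores: Mapping[str, GlobalScore | float],
    manifest: Mapping[str, str],
    stage_order: Sequence[str],
) -> StageSeries:
    """Group per-sample global scores into an ordered per-stage curve.

    Parameters
    ----------
    scores
        Mapping sample id -> :class:`~snetropy.entropy.GlobalScore` (or bare H).
    manifest
        Mapping sample id -> stage label; must cover every scored sample.
    stage_order
        Ordered stage labels; stages without scored samples are dropped with
        a warning.
    """
    if not scores:
        raise ValueError("no scores supplied")
    known = set(stage_order)
    by_stage: dict[str, list[float]] = {s: [] for s in stage_order}
    for sample, score in scores.items():
        if sample not in manifest:
            raise KeyError(f"scored sample {sample!r} missing from the stage manifest")
        stage = manifest[sample]
        if stage not in known:
            raise KeyError(
                f"sample {sample!r} has stage {stage!r} not in the stage order {list(stage_order)}"
            )
        by_stage[stage].append(_score_value(score))

    stages, means, sds, counts = [], [], [], []
    for stage in stage_order:
        vals = by_stage[stage]
        if not vals:
            logger.warning("stage %r has no scored samples; dropped from the curve", stage)
            continue
        arr = np.asarray(vals, dtype=float)
        stages.append(stage)
        means.append(float(arr.mean()))
        sds.append(float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        counts.append(arr.size)
    return StageSeries(
        stages=tuple(stages),
        mean_h=tuple(means),
        sd_h=tuple(sds),
        n_samples=tuple(counts),
    )


def detect_critical_stage(
    series: StageSeries, no_signal_ratio: float = DEFAULT_NO_SIGNAL_RATIO
) -> StageSeries:
    """Identify the critical stage as the argmax of the stage-mean curve.

    Requires at least three stages.  Ties are broken by the earliest stage in
    the given order.  ``signal_ratio`` is the peak mean divided by the median
    of the remaining stage means (infinite when that median is zero); curves
    with ratio below ``no_signal_ratio`` are flagged ``no_signal``.
    """
    if len(series.stages) < 3:
        raise ValueError(
            f"critical-stage detection needs >= 3 stages, got {len(series.stages)}"
        )
    means = np.asarray(series.mean_h, dtype=float)
    peak_idx = int(np.argmax(means))  # argmax returns the first (earliest) maximum
    peak = means[peak_idx]
    others = np.delete(means, peak_idx)
    med = float(np.median(others))
    if med == 0.0:
        ratio = math.inf if peak > 0 else 1.0
    else:
        ratio = float(peak / med)
    series.critical_stage = series.stages[peak_idx]
    series.signal_ratio = ratio
    series.no_signal_ratio = no_signal_ratio
    series.no_signal = ratio < no_signal_ratio
    return series
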
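"""Readers and writers for expression matrices, stage manifests and reports."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .entropy import LocalEntropyProfile

__all__ = [
    "read_expression",
    "read_manifest",
    "export_gene_entropy_table",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def _sep_for(path: Path) -> str | None:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression table (TSV or CSV).

    First column holds gene identifiers, header row holds sample ids.
    Duplicate gene rows are collapsed by their mean (with a warning);
    duplicate sample ids or non-numeric cells are errors.
    """
    path = Path(path)
    sep = _sep_for(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
    samples = header.split(sep)[1:] if header else []
    dup_samples = pd.Index(samples)[pd.Index(samples).duplicated()].unique()
    if len(dup_samples) > 0:  # pandas would silently mangle these to s, s.1, ...
        raise ValueError(
            f"{path}: duplicate sample id(s): {', '.join(map(str, dup_samples[:5]))}"
        )
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty expression file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: expression table has no data")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value for gene {gene!r} in sample {col!r}"
            )
        df[col] = coerced

    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        logger.warning(
            "%s: %d duplicated gene id(s) collapsed by mean (e.g. %s)",
            path,
            len(dups),
            dups[0],
        )
        df = df.groupby(level=0).mean()
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def read_manifest(path: str | Path) -> pd.Series:
    """Read a two-column sample manifest: sample_id, stage."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: manifest needs two columns (sample_id, stage)")
    sample_col, stage_col = df.columns[:2]
    manifest = pd.Series(
        df[stage_col].astype(str).to_numpy(),
        index=df[sample_col].astype(str),
        name="stage",
    )
    if manifest.index.duplicated().any():
        dup = manifest.index[manifest.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r} in manifest")
    return manifest


def export_gene_entropy_table(
    profiles: Mapping[str, LocalEntropyProfile], manifest: Mapping[str, str]
) -> pd.DataFrame:
    """Long-format per-gene node-entropy table for external downstream tools.

    One row per (gene, sample): columns gene, sample, stage, local_sne.  The
    per-gene node entropy is the local SNE of the network centered on that
    gene, which is the quantity used as a per-gene biomarker.
    """
    if not profiles:
        raise ValueError("no entropy profiles supplied")
    rows = []
    for sample, profile in profiles.items():
        stage = manifest.get(sample, "")
        for gene, value in profile.sne.items():
            rows.append((gene, sample, stage, float(value)))
    return pd.DataFrame(rows, columns=["gene", "sample", "stage", "local_sne"])
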
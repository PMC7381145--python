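"""Per-gene Gaussian background fitted from reference samples.

For every gene a normal distribution N(mu_g, sigma_g^2) is fitted from the
reference (control) samples.  A case sample's gene is *deviating* (state 1)
when its expression falls in the two-sided small-probability tail of that
background, i.e. outside the central 1 - alpha probability interval:

    state(g) = 1  iff  |x - mu_g| > z_{1-alpha/2} * sigma_g

A gene with sigma_g = 0 has a point-mass background; any departure from the
mean counts as a deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BackgroundModel", "fit_background", "gene_state", "sample_states"]


@dataclass
class BackgroundModel:
    """Per-gene Gaussian parameters plus the deviation-interval rule.

    Attributes
    ----------
    mean, sd
        Per-gene sample mean and standard deviation (n-1 denominator),
        indexed by gene identifier, in expression units.
    n_ref
        Number of reference samples used in the fit.
    alpha
        Two-sided tail probability defining the small-probability interval.
    """

    mean: pd.Series
    sd: pd.Series
    n_ref: int
    alpha: float

    @property
    def genes(self) -> pd.Index:
        return self.mean.index

    @property
    def z_threshold(self) -> float:
        """Normal quantile z_{1-alpha/2} bounding the central interval."""
        return float(stats.norm.ppf(1.0 - self.alpha / 2.0))


def fit_background(ref_matrix: pd.DataFrame, alpha: float = 0.05) -> BackgroundModel:
    """Fit the per-gene Gaussian background from a genes x reference-samples table.

    Parameters
    ----------
    ref_matrix
        Expression table, rows indexed by gene identifier, columns by
        reference sample.  At least two reference samples are required and
        every cell must be numeric (rows with missing values are rejected).
    alpha
        Two-sided tail probability in (0, 1); default 0.05.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n_ref = ref_matrix.shape[1]
    if n_ref < 2:
        raise ValueError(f"need >= 2 reference samples to fit a background, got {n_ref}")

    numeric = ref_matrix.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~ref_matrix.isna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric expression value for gene {gene!r} in sample {sample!r}"
        )
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"missing reference value(s) for gene {gene!r}")

    return BackgroundModel(
        mean=numeric.mean(axis=1),
        sd=numeric.std(axis=1, ddof=1),
        n_ref=n_ref,
        alpha=alpha,
    )


def gene_state(model: BackgroundModel, gene: str, x: float) -> int:
    """Binary deviation state of one gene for one case expression value.

    Returns 1 iff ``x`` lies outside the central ``1 - alpha`` interval of the
    gene's background Gaussian; for a degenerate background (sigma = 0) any
    value different from the mean deviates.
    """
    if gene not in model.mean.index:
        raise KeyError(f"gene {gene!r} not present in the background model")
    mu = float(model.mean[gene])
    sigma = float(model.sd[gene])
    # sigma = 0 collapses the threshold to 0, so |x - mu| > 0 <=> x != mu
    return int(abs(x - mu) > model.z_threshold * sigma)


def sample_states(
    model: BackgroundModel, case_expression: Mapping[str, float] | pd.Series
) -> pd.Series:
    """Deviation-state vector of a single case sample over all model genes.

    Parameters
    ----------
    case_expression
        Mapping or Series of expression values; must cover every gene of the
        background model.

    Returns
    -------
    pandas.Series of int8 in {0, 1}, indexed like the model's genes.
    """
    case = pd.Series(case_expression, dtype=float)
    missing = model.genes.difference(case.index)
    if len(missing) > 0:
        raise KeyError(
            "case sample missing expression for model gene(s): "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    case = case.reindex(model.genes)
    dev = (case - model.mean).abs().to_numpy()
    thr = model.z_threshold * model.sd.to_numpy()
    states = (dev > thr).astype(np.int8)
    return pd.Series(states, index=model.genes, name="state")
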
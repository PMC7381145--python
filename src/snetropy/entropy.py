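"""Single-sample node entropy (SNE): local scores and the global score.

For a local network with center g^k and m neighbors, the deviation states are
normalized to a probability vector

    p_i = state(g_i^k) / sum_j state(g_j^k),          i = 0..m

(the all-zero sentinel when no member deviates), and the local SNE is the
scaled Shannon entropy

    H^n(g^k) = -1/(m+1) * sum_i p_i ln p_i ,   0 * ln 0 := 0 .

The global score of a sample sums the L largest local SNE values, where L is
the top 5% (by default) of the Q local networks:  H(t) = sum_{k=1..L} H^n(g^k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import TemplateNetwork

__all__ = [
    "LocalEntropyProfile",
    "GlobalScore",
    "local_p_vector",
    "local_sne",
    "sample_entropy_profile",
    "global_sne",
]

_SUM_TOL = 1e-9


@dataclass
class LocalEntropyProfile:
    """Per-center local SNE scores for one case sample.

    ``sne``, ``n_deviating`` and ``m`` are Series indexed by center gene:
    the local SNE score H^n(g^k), the number of deviating members of the
    local network, and the neighbor count m.
    """

    sne: pd.Series
    n_deviating: pd.Series
    m: pd.Series

    @property
    def q(self) -> int:
        return len(self.sne)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_gene": self.sne.index,
                "m": self.m.to_numpy(),
                "n_deviating": self.n_deviating.to_numpy(),
                "local_sne": self.sne.to_numpy(),
            }
        )


@dataclass
class GlobalScore:
    """Aggregated per-sample score: sum of the top-fraction local SNE values."""

    h: float
    l: int
    q: int
    selected_centers: tuple[str, ...]


def local_p_vector(states: Sequence[int] | np.ndarray) -> np.ndarray:
    """Normalized deviation-probability vector of one local network.

    ``states`` lists the binary states of the center followed by its m
    neighbors (length m + 1 >= 2).  When no member deviates the all-zero
    sentinel vector is returned.
    """
    arr = np.asarray(states, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("states must be a 1-D vector of length >= 2 (center + neighbors)")
    total = arr.sum()
    if total == 0:
        return np.zeros_like(arr)
    return arr / total


def local_sne(p: Sequence[float] | np.ndarray) -> float:
    """Local single-sample node entropy of a probability vector of length m + 1.

    Natural-log Shannon entropy divided by m + 1; the all-zero sentinel maps
    to 0.  Raises if the vector sums to neither 0 nor 1 (tolerance 1e-9).
    """
    arr = np.asarray(p, dtype=float)
    total = arr.sum()
    if abs(total) > _SUM_TOL and abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"probability vector must sum to 0 or 1, got {total!r}")
    if total < 0.5:  # sentinel
        return 0.0
    pos = arr[arr > 0]
    return float(-(pos * np.log(pos)).sum() / arr.size)


def sample_entropy_profile(
    net: TemplateNetwork, states: pd.Series
) -> LocalEntropyProfile:
    """Local SNE score for every local network of ``net`` given a state vector.

    ``states`` must cover all network genes with binary 0/1 entries.
    """
    missing = [n for n in net.graph.nodes if n not in states.index]
    if missing:
        raise KeyError(
            "state vector missing network gene(s): " + ", ".join(sorted(missing)[:10])
        )
    state_map = states.astype(int)

    centers = sorted(net.locals_)
    sne_vals = np.empty(len(centers))
    n_dev = np.empty(len(centers), dtype=int)
    m_vals = np.empty(len(centers), dtype=int)
    for i, center in enumerate(centers):
        members = net.local_members(center)
        local_states = state_map[list(members)].to_numpy()
        m_vals[i] = len(members) - 1
        n_dev[i] = int(local_states.sum())
        sne_vals[i] = local_sne(local_p_vector(local_states))
    idx = pd.Index(centers, name="center_gene")
    return LocalEntropyProfile(
        sne=pd.Series(sne_vals, index=idx, name="local_sne"),
        n_deviating=pd.Series(n_dev, index=idx, name="n_deviating"),
        m=pd.Series(m_vals, index=idx, name="m"),
    )


def global_sne(profile: LocalEntropyProfile, top_fraction: float = 0.05) -> GlobalScore:
    """Global SNE score: sum of the L largest local SNE values.

    L = ceil(top_fraction * Q), so at least one local network is always
    aggregated.  Ties at the cutoff are broken by lexicographic center
    identifier for reproducible selected-gene lists.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    q = profile.q
    if q == 0:
        raise ValueError("empty entropy profile")
    l = math.ceil(top_fraction * q)
    order = sorted(profile.sne.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = tuple(center for center, _ in order[:l])
    h = float(sum(score for _, score in order[:l]))
    return GlobalScore(h=h, l=l, q=q, selected_centers=selected)
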
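"""Morphology-based birth-order proxy: cortex neurite length and its
correlation with lineage birth rank.

In an EM reconstruction, a neuron's soma sits in the cell-body cortex and its
neurite travels some distance before entering the synapse-rich neuropil.
Because later-born neurons are displaced further from the neuropil, the
along-skeleton (geodesic) distance from the soma to the neuropil-entry node —
the "cortex neurite length" — increases roughly with birth rank and serves as
an anatomical proxy for birth order. This module computes that geodesic on a
rooted skeleton tree and quantifies the proxy with a Pearson correlation
between precisely known birth ranks and measured lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import Skeleton


def cortex_neurite_length(s: Skeleton) -> float:
    """Geodesic path length between the soma node and the neuropil-entry node.

    The path is the unique tree path; length is the sum of Euclidean segment
    lengths along it, in the skeleton's coordinate unit.
    """
    pa = s.path_to_root(s.soma_node)
    pb = s.path_to_root(s.entry_node)
    on_a = set(pa)
    # splice at the lowest common ancestor
    lca = next(nid for nid in pb if nid in on_a)
    path = pa[: pa.index(lca)] + pb[: pb.index(lca) + 1][::-1]
    total = 0.0
    for u, v in zip(path, path[1:]):
        a, b = s.nodes[u], s.nodes[v]
        total += math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
    return total


@dataclass
class BirthOrderTable:
    """Per-neuron birth rank and cortex neurite length on each side.

    ``df`` has columns neuron_id, birth_rank, length_L, length_R (lengths may
    be NaN when one side is missing); ``length_avg`` is the mean over
    available sides, falling back to the single present side.
    """

    df: pd.DataFrame

    REQUIRED = ("neuron_id", "birth_rank", "length_L", "length_R")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"birth-order table missing column(s): {missing}")
        df = self.df.copy()
        lengths = df[["length_L", "length_R"]].astype(float)
        if (lengths.dropna() < 0).any().any():
            raise ValueError("neurite lengths must be non-negative")
        df["length_avg"] = lengths.mean(axis=1, skipna=True)
        df["one_sided"] = lengths.isna().any(axis=1)
        self.df = df

    def lengths(self, which: str) -> pd.Series:
        col = {"L": "length_L", "R": "length_R", "avg": "length_avg"}.get(which)
        if col is None:
            raise ValueError(f"which must be 'L', 'R' or 'avg', got {which!r}")
        return self.df[col]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def df(self) -> int:
        """Degrees of freedom of the t test (n - 2)."""
        return self.n - 2


def birth_order_correlation(
    table: BirthOrderTable, which: str = "avg"
) -> CorrelationResult:
    """Pearson correlation between birth rank and cortex neurite length.

    Two-sided p from the t distribution with n-2 degrees of freedom. Unit of
    length does not affect r. Requires >= 3 neurons with both a rank and a
    length on the chosen side, and nonzero variance in both variables.
    """
    y = table.lengths(which).astype(float)
    x = table.df["birth_rank"].astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 neurons with rank and length, have {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in rank or length")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def lengths_from_skeletons(
    skeletons: dict[str, Skeleton],
    ranks: dict[str, int],
    homologs: Optional[dict[str, str]] = None,
    side_of: Optional[dict[str, str]] = None,
) -> BirthOrderTable:
    """Assemble a :class:`BirthOrderTable` from measured skeletons.

    ``ranks`` maps the left-side (or canonical) neuron id to its birth rank;
    ``homologs``/``side_of`` resolve the right-side copy when present. With no
    homolog information each neuron contributes a one-sided row.
    """
    homologs = homologs or {}
    side_of = side_of or {}
    rows = []
    for nid, rank in sorted(ranks.items()):
        length = cortex_neurite_length(skeletons[nid]) if nid in skeletons else np.nan
        hom = homologs.get(nid)
        hom_length = (
            cortex_neurite_length(skeletons[hom])
            if hom is not None and hom != nid and hom in skeletons
            else np.nan
        )
        if side_of.get(nid) == "R":
            length, hom_length = hom_length, length
        rows.append({
            "neuron_id": nid,
            "birth_rank": rank,
            "length_L": length,
            "length_R": hom_length,
        })
    return BirthOrderTable(pd.DataFrame(rows))
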
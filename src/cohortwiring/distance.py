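"""Permutation-null Euclidean distance analysis of synaptic input vectors.

Each analyzed neuron's inputs are a vector of synapse counts over a shared,
identically ordered universe of presynaptic partners. The pairwise Euclidean
distance between two vectors measures how differently the two neurons are
wired; whether a given distance is smaller or larger than chance is judged
against a shuffle null in which every neuron's input vector is independently
permuted across the universe — preserving its in-degree (number of nonzero
entries) and its per-partner synapse counts, but scrambling partner identity.
Real distances are z-scored against the per-pair null mean and standard
deviation; at the default two-tailed alpha of 0.05, z < -1.96 calls a pair
significantly *similar* (closer than chance) and z > +1.96 significantly
*different*.

A binary variant replaces counts by presence/absence so that partner identity
alone, not synapse strength, drives the distances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .model import Catalog, SynapseTable

logger = logging.getLogger(__name__)

DROPOUTS = ("none", "sensory_only", "interneuron_only")


@dataclass
class InputMatrix:
    """Per-neuron synaptic input vectors over a shared presynaptic universe.

    Rows follow ``analyzed`` order; columns follow ``universe`` order (sorted
    presynaptic ids, identical for every row). ``mode`` is "count" (synapse
    numbers) or "binary" (presence bits). ``dropout`` records which source
    restriction produced the universe.
    """

    analyzed: list[str]
    universe: list[str]
    values: np.ndarray
    mode: str = "count"
    dropout: str = "none"
    zero_input_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.analyzed), len(self.universe)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.analyzed)} analyzed x {len(self.universe)} universe"
            )
        if self.mode not in ("count", "binary"):
            raise ValueError(f"mode must be 'count' or 'binary', got {self.mode!r}")
        if self.mode == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix may contain only 0 and 1")
        if (self.values < 0).any():
            raise ValueError("input matrix values must be non-negative")

    def binarize(self) -> "InputMatrix":
        """Presence/absence view of the same matrix (idempotent)."""
        return InputMatrix(
            analyzed=list(self.analyzed),
            universe=list(self.universe),
            values=(self.values > 0).astype(self.values.dtype),
            mode="binary",
            dropout=self.dropout,
            zero_input_rows=list(self.zero_input_rows),
        )


def build_input_matrix(
    sub: SynapseTable,
    analyzed: list[str],
    mode: str = "count",
    dropout: str = "none",
    catalog: Optional[Catalog] = None,
) -> InputMatrix:
    """Tabulate inputs onto ``analyzed`` neurons into an :class:`InputMatrix`.

    The universe is the set of presynaptic partners observed onto the analyzed
    group after the dropout restriction, in sorted order, so no column is all
    zero. ``dropout`` = "sensory_only" keeps only sensory sources,
    "interneuron_only" only interneurons (catalog required for either).
    Analyzed neurons with no surviving inputs get a zero row and are flagged.
    """
    if dropout not in DROPOUTS:
        raise ValueError(f"dropout must be one of {DROPOUTS}, got {dropout!r}")
    if dropout != "none" and catalog is None:
        raise ValueError("dropout filtering requires a catalog")
    if catalog is not None:
        missing = [n for n in analyzed if n not in catalog]
        if missing:
            raise ValueError(f"analyzed neuron(s) absent from catalog: {missing}")
    if len(set(analyzed)) != len(analyzed):
        raise ValueError("analyzed neuron ids must be unique")

    df = sub.df[sub.df["post_id"].isin(set(analyzed))]
    if dropout == "sensory_only":
        df = df[[catalog.source_type(p) == "sensory" for p in df["pre_id"]]]
    elif dropout == "interneuron_only":
        df = df[[catalog.source_type(p) == "interneuron" for p in df["pre_id"]]]

    universe = sorted(set(df["pre_id"]))
    col = {p: j for j, p in enumerate(universe)}
    row = {n: i for i, n in enumerate(analyzed)}
    values = np.zeros((len(analyzed), len(universe)), dtype=np.int64)
    for r in df.itertuples(index=False):
        values[row[r.post_id], col[r.pre_id]] = r.count
    if mode == "binary":
        values = (values > 0).astype(np.int64)

    zero_rows = [n for n in analyzed if values[row[n]].sum() == 0]
    if zero_rows:
        logger.warning(
            "%d analyzed neuron(s) have no inputs after dropout=%s: %s",
            len(zero_rows), dropout, zero_rows,
        )
    return InputMatrix(
        analyzed=list(analyzed),
        universe=universe,
        values=values,
        mode=mode,
        dropout=dropout,
        zero_input_rows=zero_rows,
    )


def euclidean_distances(m: InputMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances between input vectors."""
    if len(m.analyzed) < 2:
        raise ValueError("need at least two analyzed neurons")
    return squareform(pdist(m.values.astype(float), metric="euclidean"))


def shuffle_null(
    m: InputMatrix,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    return_distances: bool = False,
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Monte-Carlo shuffle null for the pairwise distances.

    In each of ``n_perm`` rounds every row of the matrix is independently
    permuted across the universe columns (a uniform random permutation of that
    row's entries, conserving the row's value multiset and hence its in-degree
    and total synapse count), and all pairwise Euclidean distances are
    computed on the shuffled matrix. Returns the per-pair sample mean and
    sample standard deviation (n-1 denominator) over rounds, plus the raw
    per-round condensed distance vectors when ``return_distances``.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2 (standard deviation undefined)")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n, k = m.values.shape
    if n < 2:
        raise ValueError("need at least two analyzed neurons")
    base = m.values.astype(float)
    dists = np.empty((n_perm, n * (n - 1) // 2))
    for t in range(n_perm):
        dists[t] = pdist(shuffle_rows(base, rng), metric="euclidean")
    null_mean = squareform(dists.mean(axis=0))
    null_sd = squareform(dists.std(axis=0, ddof=1))
    return null_mean, null_sd, (dists if return_distances else None)


def shuffle_rows(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One permutation round: every row independently permuted across columns.

    This is the elementary operation of the shuffle null; each returned row is
    a uniform random rearrangement of the corresponding input row, so the
    row's value multiset (and hence its in-degree and total synapse count) is
    conserved exactly.
    """
    out = np.empty_like(values)
    k = values.shape[1]
    for i in range(values.shape[0]):
        out[i] = values[i, rng.permutation(k)]
    return out


def exhaustive_null(m: InputMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Exact null mean/sd by enumerating all joint row permutations.

    Feasible only for tiny instances (the joint space has (k!)^n points for k
    universe columns and n rows); used as the ground-truth reference that the
    Monte-Carlo null converges to. Because rows are shuffled independently,
    each pair's null depends only on that pair's two rows, so pairs are
    enumerated over (k!)^2 joint permutations rather than the full joint
    space.
    """
    n, k = m.values.shape
    if n < 2:
        raise ValueError("need at least two analyzed neurons")
    if math.factorial(k) ** 2 > 4_000_000:
        raise ValueError(f"universe of {k} columns too large to enumerate")
    base = m.values.astype(float)
    perms = list(itertools.permutations(range(k)))
    null_mean = np.zeros((n, n))
    null_sd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ds = [
                float(np.linalg.norm(base[i, list(pa)] - base[j, list(pb)]))
                for pa in perms
                for pb in perms
            ]
            mu = float(np.mean(ds))
            # population sd over the full permutation distribution
            sd = float(np.std(ds))
            null_mean[i, j] = null_mean[j, i] = mu
            null_sd[i, j] = null_sd[j, i] = sd
    return null_mean, null_sd


@dataclass
class DistanceResult:
    """Distances, null statistics, z-scores and significance calls."""

    analyzed: list[str]
    d: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    similar: np.ndarray
    different: np.ndarray
    undefined: np.ndarray  # pairs with null_sd == 0 (z not computable)
    n_perm: int
    seed: Optional[int]
    alpha: float
    z_threshold: float
    mode: str = "count"
    dropout: str = "none"

    def pair_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-unordered-pair view (diagonal excluded)."""
        rows = []
        n = len(self.analyzed)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "a": self.analyzed[i],
                    "b": self.analyzed[j],
                    "d": self.d[i, j],
                    "null_mean": self.null_mean[i, j],
                    "null_sd": self.null_sd[i, j],
                    "z": self.z[i, j],
                    "similar": bool(self.similar[i, j]),
                    "different": bool(self.different[i, j]),
                    "undefined": bool(self.undefined[i, j]),
                })
        return pd.DataFrame(rows)


def zscore_and_call(
    d: np.ndarray,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    analyzed: list[str],
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: Optional[int] = None,
    mode: str = "count",
    dropout: str = "none",
) -> DistanceResult:
    """z-score real distances against the null and call significance.

    z = (d - null_mean) / null_sd per pair; the threshold is the standard
    normal two-tailed quantile for ``alpha`` (1.96 at 0.05). Negative z (real
    distance smaller than chance) marks a pair similar, positive z different.
    Pairs with zero null sd are flagged undefined and never significant; the
    diagonal is excluded from all calls.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != null_mean.shape or d.shape != null_sd.shape:
        raise ValueError("distance and null matrices must share a shape")
    if d.shape[0] != len(analyzed):
        raise ValueError("labels do not match matrix size")
    thr = float(norm.ppf(1 - alpha / 2))
    off_diag = ~np.eye(d.shape[0], dtype=bool)
    defined = (null_sd > 0) & off_diag
    z = np.full_like(d, np.nan)
    np.divide(d - null_mean, null_sd, out=z, where=defined)
    similar = defined & (z < -thr)
    different = defined & (z > thr)
    return DistanceResult(
        analyzed=list(analyzed),
        d=d,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        similar=similar,
        different=different,
        undefined=off_diag & ~defined,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        z_threshold=thr,
        mode=mode,
        dropout=dropout,
    )


def run_distance_analysis(
    sub: SynapseTable,
    analyzed: list[str],
    catalog: Optional[Catalog] = None,
    mode: str = "count",
    dropout: str = "none",
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> DistanceResult:
    """Build the input matrix, compute real and null distances, and call pairs."""
    m = build_input_matrix(sub, analyzed, mode=mode, dropout=dropout, catalog=catalog)
    d = euclidean_distances(m)
    null_mean, null_sd, _ = shuffle_null(m, n_perm=n_perm, seed=seed)
    return zscore_and_call(
        d, null_mean, null_sd, analyzed=m.analyzed, alpha=alpha,
        n_perm=n_perm, seed=seed, mode=mode, dropout=dropout,
    )


@dataclass
class PairZScores:
    """z-scores of left–right and following (consecutive-birth) pairs."""

    left_right: pd.DataFrame  # columns: a, b, cohort_group, z
    following: pd.DataFrame  # columns: a, b, cohort_group, z
    z_threshold: float


def pair_summaries(result: DistanceResult, catalog: Catalog) -> PairZScores:
    """Pool pairwise z-scores by biological pair type, regardless of significance.

    Left–right pairs are the same cell type on the two sides (linked by
    ``homolog_id``; midline self-homologs are degenerate and excluded).
    Following pairs are neurons born consecutively (birth ranks k, k+1) in the
    same (lineage, hemilineage, side); neurons missing a birth rank are
    skipped. Each pair carries the cohort label shared by its members (or
    "mixed").
    """
    idx = {n: i for i, n in enumerate(result.analyzed)}

    def group(a: str, b: str) -> str:
        ca = catalog[a].cohort or "other"
        cb = catalog[b].cohort or "other"
        return ca if ca == cb else "mixed"

    def zrow(a: str, b: str) -> dict:
        i, j = idx[a], idx[b]
        return {"a": a, "b": b, "cohort_group": group(a, b), "z": result.z[i, j]}

    lr_rows = []
    seen = set()
    for n in result.analyzed:
        rec = catalog.get(n)
        if rec is None or rec.homolog_id is None or rec.homolog_id == n:
            continue
        if rec.homolog_id in idx and frozenset((n, rec.homolog_id)) not in seen:
            seen.add(frozenset((n, rec.homolog_id)))
            lr_rows.append(zrow(n, rec.homolog_id))

    by_group: dict[tuple, dict[int, str]] = {}
    skipped = []
    for n in result.analyzed:
        rec = catalog.get(n)
        if rec is None:
            continue
        if rec.birth_order is None:
            skipped.append(n)
            continue
        key = (rec.lineage, rec.hemilineage, rec.side, rec.segment)
        by_group.setdefault(key, {})[rec.birth_order] = n
    if skipped:
        logger.warning(
            "pair_summaries: %d neuron(s) without birth_order skipped from "
            "following pairs", len(skipped),
        )
    fl_rows = []
    for ranks in by_group.values():
        for k in sorted(ranks):
            if k + 1 in ranks:
                fl_rows.append(zrow(ranks[k], ranks[k + 1]))

    cols = ["a", "b", "cohort_group", "z"]
    return PairZScores(
        left_right=pd.DataFrame(lr_rows, columns=cols),
        following=pd.DataFrame(fl_rows, columns=cols),
        z_threshold=result.z_threshold,
    )
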
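"""Filtering and summary statistics on the inputs to a chosen target neuron set.

Given the full edge table and a target set (e.g. every neuron of one lineage
in one segment, left and right copies), these operations reproduce the
standard accounting a connectomics study performs before any modelling:

* restrict the edge table to inputs onto the targets and count totals;
* break synapses down by source type (interneuron / sensory / brain-or-SEZ /
  fragment) and, per target, by sensory modality;
* histogram per-edge or per-source synapse counts and compare two count
  distributions with a two-sample Kolmogorov–Smirnov test;
* apply the left–right pairing reliability filter (a partner counts only if
  its hemisegmental homolog also contacts the homologous target);
* apply the highly-connected filter (>= ``min_syn`` synapses from at least one
  member of a left–right pair) and summarise class composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Catalog, SynapseTable

logger = logging.getLogger(__name__)


@dataclass
class TargetSet:
    """A named, ordered set of postsynaptic neurons under analysis.

    ``homolog_pairs`` lists (left, right) copies of the same cell type in
    homologous hemisegments; every L/R member should appear in exactly one
    pair.
    """

    name: str
    members: list[str]
    homolog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"target set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"target set {self.name!r} has duplicate members")
        member_set = set(self.members)
        for a, b in self.homolog_pairs:
            if a not in member_set or b not in member_set:
                raise ValueError(
                    f"homolog pair ({a}, {b}) references non-member target"
                )

    @property
    def homolog_map(self) -> dict[str, str]:
        m: dict[str, str] = {}
        for a, b in self.homolog_pairs:
            m[a] = b
            m[b] = a
        return m


@dataclass
class InputSummary:
    total_synapses: int
    distinct_sources: int


def inputs_onto(
    table: SynapseTable,
    targets: TargetSet,
    catalog: Optional[Catalog] = None,
) -> tuple[SynapseTable, InputSummary]:
    """Sub-table of inputs onto the target set, with totals.

    If a catalog is supplied, every target member must resolve against it.
    """
    if catalog is not None:
        unknown = [m for m in targets.members if m not in catalog]
        if unknown:
            raise ValueError(
                f"target member(s) absent from catalog: {unknown}"
            )
    sub = table.onto(targets.members)
    summary = InputSummary(
        total_synapses=sub.total_synapses,
        distinct_sources=len(set(sub.df["pre_id"])),
    )
    logger.info(
        "inputs onto %s: %d synapses from %d distinct sources",
        targets.name, summary.total_synapses, summary.distinct_sources,
    )
    return sub, summary


def compose_by_source_type(sub: SynapseTable, catalog: Catalog) -> pd.DataFrame:
    """Synapse counts and percentages per source type.

    Percentages sum to exactly 100 before rounding; sources absent from the
    catalog are fragments.
    """
    if not len(sub):
        return pd.DataFrame(columns=["source_type", "synapses", "percentage"])
    df = sub.df.copy()
    df["source_type"] = [catalog.source_type(p) for p in df["pre_id"]]
    grouped = (
        df.groupby("source_type", sort=True)["count"].sum().reset_index()
        .rename(columns={"count": "synapses"})
    )
    total = grouped["synapses"].sum()
    grouped["percentage"] = 100.0 * grouped["synapses"] / total
    return grouped.sort_values("synapses", ascending=False, ignore_index=True)


def sensory_breakdown(
    sub: SynapseTable, catalog: Catalog, targets: TargetSet
) -> pd.DataFrame:
    """Per-target fraction of total input coming from each sensory modality.

    One row per target member (in target order) with a ``total`` column, one
    fraction column per sensory class, and ``no_input`` flagging targets with
    zero synaptic input (whose fractions are reported as 0).
    """
    from .model import SENSORY_CLASSES

    lookup = sub.df.groupby("post_id")
    rows = []
    for t in targets.members:
        if t in lookup.groups:
            g = lookup.get_group(t)
            total = int(g["count"].sum())
        else:
            g, total = None, 0
        row: dict = {"target": t, "total": total, "no_input": total == 0}
        for cls in SENSORY_CLASSES:
            if total == 0:
                row[cls] = 0.0
                continue
            mask = [
                catalog.source_type(p) == "sensory"
                and (catalog.get(p).sensory_class == cls)
                for p in g["pre_id"]
            ]
            row[cls] = float(g["count"][mask].sum()) / total
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- histograms


@dataclass(frozen=True)
class HistogramBin:
    label: str
    lo: int
    hi: Optional[int]  # inclusive upper bound; None = open-ended

    def contains(self, v: int) -> bool:
        return v >= self.lo and (self.hi is None or v <= self.hi)


@dataclass
class HistogramSpec:
    """Explicit labeled integer bins, disjoint and exhaustive above ``lo``.

    The last bin must be open-ended; values below the first bin fall into an
    underflow bucket (reported separately, never silently dropped).
    """

    bins: list[HistogramBin]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("histogram needs at least one bin")
        if self.bins[-1].hi is not None:
            raise ValueError("last histogram bin must be open-ended")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.hi is None or b.lo != a.hi + 1:
                raise ValueError(
                    f"bins {a.label!r} and {b.label!r} are not contiguous"
                )

    @property
    def start(self) -> int:
        return self.bins[0].lo

    @classmethod
    def unit_bins(cls, lo: int, hi: int) -> "HistogramSpec":
        """Single-count bins lo..hi then an open '(hi+1)+' bin."""
        bins = [HistogramBin(str(v), v, v) for v in range(lo, hi + 1)]
        bins.append(HistogramBin(f"{hi + 1}+", hi + 1, None))
        return cls(bins)

    @classmethod
    def range_bins(cls, width: int, n_closed: int, lo: int = 0) -> "HistogramSpec":
        """``n_closed`` bins of ``width`` counts starting at ``lo``, then open."""
        bins = []
        for i in range(n_closed):
            a = lo + i * width
            bins.append(HistogramBin(f"{a}-{a + width - 1}", a, a + width - 1))
        top = lo + n_closed * width
        bins.append(HistogramBin(f"{top}+", top, None))
        return cls(bins)


#: Per-edge synapse-count bins: 1..9 then 10+.
PER_EDGE_BINS = HistogramSpec.unit_bins(1, 9)
#: Pooled per-source bins: 0-4, 5-9, ..., 40-44, 45+.
POOLED_BINS = HistogramSpec.range_bins(width=5, n_closed=9, lo=0)


def synapse_histogram(
    sub: SynapseTable,
    spec: HistogramSpec = PER_EDGE_BINS,
    per: str = "edge",
) -> pd.DataFrame:
    """Bin synapse counts per edge or per pooled source.

    ``per="edge"`` bins each (pre, target) contact count; ``per="source_pooled"``
    bins each presynaptic neuron's summed synapses onto the whole target set.
    Returns one row per bin (plus ``underflow`` if hit); counts sum to the
    number of binned items.
    """
    if per == "edge":
        values = sub.df["count"].tolist()
    elif per == "source_pooled":
        values = sub.df.groupby("pre_id")["count"].sum().tolist()
    else:
        raise ValueError(f"per must be 'edge' or 'source_pooled', got {per!r}")
    counts = {b.label: 0 for b in spec.bins}
    underflow = 0
    for v in values:
        if v < spec.start:
            underflow += 1
            continue
        for b in spec.bins:
            if b.contains(v):
                counts[b.label] += 1
                break
    rows = [{"bin": lbl, "count": c} for lbl, c in counts.items()]
    if underflow:
        logger.warning("%d value(s) below lowest histogram bin", underflow)
        rows.append({"bin": "underflow", "count": underflow})
    return pd.DataFrame(rows)


def ks_compare(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test on raw count samples.

    Exact p-value when both samples have n <= 25, asymptotic otherwise.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare requires two non-empty samples")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# -------------------------------------------------------------- pair filters


@dataclass
class PairedInputSet:
    """Interneurons retained by the left–right pairing reliability filter."""

    pairs: list[tuple[str, ...]]  # (id,) for midline neurons, (idL, idR) else
    evidence: list[tuple[int, int]]  # (max, min) qualifying counts per pair
    total_neurons: int
    total_synapses: int
    skipped_unpaired: list[str] = field(default_factory=list)

    @property
    def neuron_ids(self) -> set[str]:
        return {n for pair in self.pairs for n in pair}


def _candidate_pairs(
    pre_ids: Iterable[str], catalog: Catalog, source_types: tuple[str, ...]
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Group presynaptic candidates into homolog pairs / midline singletons.

    Returns (pairs, skipped) where skipped lists candidates of an eligible
    source type whose homolog annotation is missing.
    """
    pairs: list[tuple[str, ...]] = []
    skipped: list[str] = []
    seen: set[str] = set()
    for pid in sorted(set(pre_ids)):
        if pid in seen:
            continue
        rec = catalog.get(pid)
        if rec is None or rec.source_type not in source_types:
            continue
        hom = rec.homolog_id
        if hom is None:
            skipped.append(pid)
            continue
        if hom == pid:
            pairs.append((pid,))
            seen.add(pid)
        else:
            pairs.append(tuple(sorted((pid, hom))))
            seen.update((pid, hom))
    return pairs, skipped


def lr_pair_filter(
    sub: SynapseTable,
    catalog: Catalog,
    targets: TargetSet,
    thr_high: int = 4,
    thr_low: int = 2,
) -> PairedInputSet:
    """Retain interneurons whose left–right pair reliably contacts homologous targets.

    A pair {p, q} (p == q for a midline neuron) qualifies iff some target
    homolog pair (tL, tR) has count(p1 -> tX) >= thr_high and
    count(p2 -> homolog(tX)) >= thr_low for some assignment of {p, q} to the
    high/low roles and of the targets to sides. Reports the retained neurons
    and their total synapses onto the whole target set.
    """
    lut = sub.count_lookup()
    totals = sub.df.groupby("pre_id")["count"].sum().to_dict()

    def c(pre: str, post: str) -> int:
        return lut.get((pre, post), 0)

    pairs, skipped = _candidate_pairs(sub.df["pre_id"], catalog, ("interneuron",))
    if skipped:
        logger.warning(
            "lr_pair_filter: %d candidate(s) without homolog annotation skipped",
            len(skipped),
        )

    kept: list[tuple[str, ...]] = []
    evidence: list[tuple[int, int]] = []
    for pair in pairs:
        p, q = (pair[0], pair[0]) if len(pair) == 1 else pair
        best: Optional[tuple[int, int]] = None
        for t_l, t_r in targets.homolog_pairs:
            for hi_count, lo_count in (
                (c(p, t_l), c(q, t_r)),
                (c(p, t_r), c(q, t_l)),
                (c(q, t_l), c(p, t_r)),
                (c(q, t_r), c(p, t_l)),
            ):
                if hi_count >= thr_high and lo_count >= thr_low:
                    cand = (hi_count, lo_count)
                    if best is None or cand > best:
                        best = cand
        if best is not None:
            kept.append(pair)
            evidence.append(best)

    neuron_ids = {n for pair in kept for n in pair}
    total_syn = int(sum(totals.get(n, 0) for n in neuron_ids))
    return PairedInputSet(
        pairs=kept,
        evidence=evidence,
        total_neurons=len(neuron_ids),
        total_synapses=total_syn,
        skipped_unpaired=skipped,
    )


@dataclass
class HighlyConnectedResult:
    """Neurons passing the >= ``min_syn`` synapses-onto-targets filter.

    ``members`` is pair-expanded (both members of a qualifying left–right pair,
    restricted to those actually presynaptic to the targets);
    ``qualifying_neurons`` is the strict per-neuron set with >= min_syn
    synapses itself. ``composition`` summarises members by morphological class.
    """

    members: set[str]
    qualifying_neurons: set[str]
    composition: pd.DataFrame
    min_syn: int


def highly_connected(
    sub: SynapseTable,
    catalog: Catalog,
    targets: TargetSet,
    min_syn: int = 10,
) -> HighlyConnectedResult:
    """Sensory neurons and interneurons highly connected to the target set.

    A left–right pair (or midline neuron, or unpaired candidate) is retained
    when at least one member's summed synapses onto the targets reach
    ``min_syn``.
    """
    totals = sub.df.groupby("pre_id")["count"].sum().to_dict()
    pairs, unpaired = _candidate_pairs(
        sub.df["pre_id"], catalog, ("interneuron", "sensory")
    )
    # candidates without a homolog annotation are evaluated singly
    pairs += [(pid,) for pid in unpaired]

    members: set[str] = set()
    qualifying = {
        pid for pid, tot in totals.items()
        if tot >= min_syn
        and catalog.source_type(pid) in ("interneuron", "sensory")
    }
    for pair in pairs:
        if any(totals.get(n, 0) >= min_syn for n in pair):
            members.update(n for n in pair if n in totals)

    rows = []
    for cls, ids in _group_by_class(members, catalog).items():
        rows.append({
            "morph_class": cls,
            "neurons": len(ids),
            "synapses": int(sum(totals.get(n, 0) for n in ids)),
        })
    comp = pd.DataFrame(rows, columns=["morph_class", "neurons", "synapses"])
    if len(comp):
        comp = comp.sort_values("synapses", ascending=False, ignore_index=True)
    return HighlyConnectedResult(
        members=members,
        qualifying_neurons=qualifying,
        composition=comp,
        min_syn=min_syn,
    )


def _group_by_class(ids: Iterable[str], catalog: Catalog) -> dict[str, set[str]]:
    groups: dict[str, set[str]] = {}
    for pid in ids:
        rec = catalog.get(pid)
        cls = (rec.morph_class if rec is not None and rec.morph_class else "other")
        groups.setdefault(cls, set()).add(pid)
    return groups


def class_composition(
    sub: SynapseTable,
    catalog: Catalog,
    classes: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Distinct-source counts, synapse counts and synapse percentages per class.

    ``classes`` restricts the listed morphological classes; sources of any
    other (or missing) class are pooled under "other". Percentages are over
    all synapses in ``sub`` and sum to exactly 100 before rounding.
    """
    if not len(sub):
        return pd.DataFrame(columns=["morph_class", "neurons", "synapses", "percentage"])
    totals = sub.df.groupby("pre_id")["count"].sum().to_dict()
    grand_total = sub.total_synapses
    groups = _group_by_class(totals, catalog)
    if classes is not None:
        merged: dict[str, set[str]] = {c: groups.pop(c, set()) for c in classes}
        merged.setdefault("other", set()).update(
            pid for ids in groups.values() for pid in ids
        )
        groups = merged
    rows = []
    for cls, ids in groups.items():
        syn = int(sum(totals[i] for i in ids))
        rows.append({
            "morph_class": cls,
            "neurons": len(ids),
            "synapses": syn,
            "percentage": 100.0 * syn / grand_total,
        })
    return (
        pd.DataFrame(rows)
        .sort_values("synapses", ascending=False, ignore_index=True)
    )
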
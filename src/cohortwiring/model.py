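"""Core domain types for temporal-cohort connectivity analysis.

A connectome, for our purposes, is a directed weighted edge list (who synapses
onto whom, and how many times) plus an annotation catalog describing each
neuron: which side of the midline it sits on, which segment, whether it is a
nerve-cord interneuron or a sensory neuron, which stem-cell lineage it came
from, its birth rank within that lineage, and which temporal cohort it belongs
to. These types carry no computation beyond validation; every analysis stage
consumes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIDES = ("L", "R", "M")
SOURCE_TYPES = ("interneuron", "sensory", "brain_or_SEZ", "unknown_fragment")
SENSORY_CLASSES = ("chordotonal", "proprioceptive", "other")
HEMILINEAGES = ("NotchON", "NotchOFF")

#: Anterior-to-posterior order used for any segment comparison.
SEGMENT_ORDER = ("T1", "T2", "T3") + tuple(f"A{i}" for i in range(1, 11))


@dataclass(frozen=True)
class NeuronRecord:
    """Identity and annotations of one reconstructed neuron (or fragment).

    ``side`` is one of L/R/M, M meaning an unpaired midline neuron whose
    ``homolog_id`` is itself. ``birth_order`` is the 1-based rank within
    (lineage, hemilineage, side). Optional annotations are ``None`` when the
    reconstruction could not assign them (e.g. a fragment never traced back to
    a cell body).
    """

    neuron_id: str
    name: str = ""
    side: Optional[str] = None
    segment: Optional[str] = None
    source_type: str = "unknown_fragment"
    sensory_class: Optional[str] = None
    morph_class: Optional[str] = None
    lineage: Optional[str] = None
    hemilineage: Optional[str] = None
    birth_order: Optional[int] = None
    cohort: Optional[str] = None
    homolog_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"neuron {self.neuron_id!r}: invalid side {self.side!r}")
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(
                f"neuron {self.neuron_id!r}: invalid source_type {self.source_type!r}"
            )
        if self.sensory_class is not None and self.sensory_class not in SENSORY_CLASSES:
            raise ValueError(
                f"neuron {self.neuron_id!r}: invalid sensory_class {self.sensory_class!r}"
            )
        if self.hemilineage is not None and self.hemilineage not in HEMILINEAGES:
            raise ValueError(
                f"neuron {self.neuron_id!r}: invalid hemilineage {self.hemilineage!r}"
            )
        if self.birth_order is not None and self.birth_order < 1:
            raise ValueError(f"neuron {self.neuron_id!r}: birth_order must be >= 1")


class Catalog:
    """Collection of :class:`NeuronRecord` keyed by ``neuron_id``."""

    def __init__(self, records: Iterable[NeuronRecord]):
        self._records: dict[str, NeuronRecord] = {}
        for rec in records:
            if rec.neuron_id in self._records:
                raise ValueError(f"duplicate neuron_id {rec.neuron_id!r} in catalog")
            self._records[rec.neuron_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, neuron_id: str) -> bool:
        return neuron_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __getitem__(self, neuron_id: str) -> NeuronRecord:
        return self._records[neuron_id]

    def get(self, neuron_id: str) -> Optional[NeuronRecord]:
        return self._records.get(neuron_id)

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def source_type(self, neuron_id: str) -> str:
        """Source type of a neuron; unresolvable ids are fragments."""
        rec = self._records.get(neuron_id)
        return rec.source_type if rec is not None else "unknown_fragment"

    def homolog(self, neuron_id: str) -> Optional[str]:
        rec = self._records.get(neuron_id)
        return rec.homolog_id if rec is not None else None


@dataclass
class SynapseTable:
    """Directed weighted edge list: one row per (pre, post) with synapse count.

    Invariants: counts are integers >= 1 and (pre_id, post_id) rows are unique.
    Use :meth:`from_rows` to aggregate raw exports that list one row per
    synapse.
    """

    df: pd.DataFrame

    COLUMNS = ("pre_id", "post_id", "count")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"edge table missing column(s): {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(df):
            counts = df["count"]
            if not np.issubdtype(np.asarray(counts).dtype, np.integer):
                as_float = counts.astype(float)
                if not np.all(as_float == np.floor(as_float)):
                    bad = df.index[as_float != np.floor(as_float)][0]
                    raise ValueError(f"non-integer synapse count at row {bad}")
                df["count"] = as_float.astype(np.int64)
            if (df["count"] < 1).any():
                bad = df.index[df["count"] < 1][0]
                raise ValueError(f"synapse count < 1 at row {bad}")
            dup = df.duplicated(subset=["pre_id", "post_id"])
            if dup.any():
                raise ValueError(
                    f"duplicate (pre_id, post_id) row at index {df.index[dup][0]}; "
                    "aggregate with SynapseTable.from_rows"
                )
        else:
            df = df.astype({"pre_id": object, "post_id": object, "count": np.int64})
        self.df = df

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, int]]) -> "SynapseTable":
        """Build a table from raw (pre, post, count) rows, summing duplicates."""
        df = pd.DataFrame(list(rows), columns=list(cls.COLUMNS))
        if len(df):
            n_raw = len(df)
            df = (
                df.groupby(["pre_id", "post_id"], as_index=False, sort=True)["count"]
                .sum()
            )
            if len(df) < n_raw:
                logger.warning(
                    "aggregated %d raw rows into %d unique (pre, post) edges",
                    n_raw,
                    len(df),
                )
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_synapses(self) -> int:
        return int(self.df["count"].sum())

    @property
    def pre_ids(self) -> list[str]:
        return sorted(self.df["pre_id"].unique())

    @property
    def post_ids(self) -> list[str]:
        return sorted(self.df["post_id"].unique())

    def onto(self, post_ids: Iterable[str]) -> "SynapseTable":
        """Sub-table of edges whose postsynaptic neuron is in ``post_ids``."""
        keep = set(post_ids)
        return SynapseTable(self.df[self.df["post_id"].isin(keep)].reset_index(drop=True))

    def count_lookup(self) -> dict[tuple[str, str], int]:
        return {
            (r.pre_id, r.post_id): int(r.count)
            for r in self.df.itertuples(index=False)
        }


@dataclass(frozen=True)
class SkeletonNode:
    node_id: int
    x: float
    y: float
    z: float
    parent_id: Optional[int]  # None for the root


@dataclass
class Skeleton:
    """Rooted tree of 3-D nodes with soma and neuropil-entry nodes marked.

    Coordinates are in the length unit of the run (nanometres by default for
    EM reconstructions). The node graph must be a single connected tree with
    exactly one root.
    """

    nodes: Mapping[int, SkeletonNode]
    soma_node: int
    entry_node: int

    def __post_init__(self) -> None:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent_id is not None and n.parent_id not in self.nodes:
                raise ValueError(
                    f"node {n.node_id} references absent parent {n.parent_id}"
                )
        for marker, name in ((self.soma_node, "soma_node"), (self.entry_node, "entry_node")):
            if marker not in self.nodes:
                raise ValueError(f"{name} {marker} not in node set")
        # reachability from root == connected single tree (parent pointers
        # cannot encode a cycle through the root, but can through a detached
        # loop, which the reachability check rejects)
        children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                children[n.parent_id].append(n.node_id)
        seen = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(children[nid])
        if len(seen) != len(self.nodes):
            raise ValueError("skeleton nodes form a cycle or disconnected component")

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)
        return path


@dataclass
class ValidationIssue:
    kind: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.issues

    def by_kind(self, kind: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == kind]

    def __str__(self) -> str:
        if self.passed:
            return "validation passed: 0 issues"
        lines = [f"validation failed: {len(self.issues)} issue(s)"]
        lines += [f"  [{i.kind}] {i.detail}" for i in self.issues]
        return "\n".join(lines)


def validate_catalog(catalog: Catalog, table: SynapseTable) -> ValidationReport:
    """Cross-check a catalog and edge table against the shared invariants.

    Reported issue kinds: ``dangling_edge`` (edge endpoint absent from the
    catalog and not a declared fragment), ``asymmetric_homolog``,
    ``midline_homolog`` (side-M neuron whose homolog is not itself),
    ``birth_order_duplicate``. Duplicate neuron ids and duplicate (pre, post)
    rows are rejected at construction time by :class:`Catalog` /
    :class:`SynapseTable`, so the report covers the cross-referential rules.
    The report is order-independent: issues are emitted in sorted order.
    """
    issues: list[ValidationIssue] = []

    for rec in catalog:
        if rec.homolog_id is not None:
            if rec.side == "M" and rec.homolog_id != rec.neuron_id:
                issues.append(
                    ValidationIssue(
                        "midline_homolog",
                        f"midline neuron {rec.neuron_id} has homolog {rec.homolog_id}",
                    )
                )
            partner = catalog.get(rec.homolog_id)
            if partner is None:
                issues.append(
                    ValidationIssue(
                        "missing_homolog",
                        f"homolog {rec.homolog_id} of {rec.neuron_id} absent from catalog",
                    )
                )
            elif partner.homolog_id != rec.neuron_id:
                issues.append(
                    ValidationIssue(
                        "asymmetric_homolog",
                        f"homolog link {rec.neuron_id} -> {rec.homolog_id} not reciprocated",
                    )
                )

    seen_orders: dict[tuple, str] = {}
    for rec in catalog:
        if rec.birth_order is None:
            continue
        key = (rec.lineage, rec.hemilineage, rec.side, rec.birth_order)
        if key in seen_orders:
            issues.append(
                ValidationIssue(
                    "birth_order_duplicate",
                    f"birth_order {rec.birth_order} shared by {seen_orders[key]} "
                    f"and {rec.neuron_id} within {key[:3]}",
                )
            )
        else:
            seen_orders[key] = rec.neuron_id

    if len(table):
        known = set(catalog.ids)
        for col in ("pre_id", "post_id"):
            for nid in sorted(set(table.df[col]) - known):
                issues.append(
                    ValidationIssue("dangling_edge", f"{col} {nid} absent from catalog")
                )

    issues.sort(key=lambda i: (i.kind, i.detail))
    # symmetric-homolog issues come in mirrored pairs; keep them distinct —
    # the report is diagnostic, not a count of broken neurons
    return ValidationReport(issues)
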
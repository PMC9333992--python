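"""Readers and writers for the file formats the pipeline touches.

Edge tables and annotation catalogs are plain CSV (comma separator, UTF-8,
ids unquoted, empty string = missing). Skeletons are SWC with a companion CSV
mapping each neuron to its neuropil-entry node, since vanilla SWC has no way
to mark one. Labeled square matrices (distances, z-scores) round-trip through
CSV with row/column labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import Catalog, NeuronRecord, Skeleton, SkeletonNode, SynapseTable

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending row."""


@dataclass
class SwcDialect:
    """Conventions for interpreting an SWC file.

    ``length_unit`` applies to coordinates as stored ("nm" for CATMAID-style
    EM reconstructions, "um" for light microscopy). ``soma_marker`` is the SWC
    structure-type code treated as the soma (1 in the standard). The neuropil
    entry node comes from a companion mapping, not the SWC itself.
    """

    length_unit: str = "nm"
    soma_marker: int = 1

    def __post_init__(self) -> None:
        if self.length_unit not in ("nm", "um"):
            raise ValueError(f"unsupported length_unit {self.length_unit!r}")


# ---------------------------------------------------------------- edge table


def read_edge_table(path: PathLike) -> SynapseTable:
    """Read a pre_id,post_id,count CSV; duplicate (pre, post) rows are summed."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    except Exception as exc:  # noqa: BLE001 - rewrap any parse failure
        raise FormatError(f"{path}: unreadable edge table: {exc}") from exc
    for col in SynapseTable.COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != np.floor(counts))
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: non-integer synapse count at line {line}")
    if (counts < 1).any():
        line = int(df.index[counts < 1][0]) + 2
        raise FormatError(f"{path}: synapse count < 1 at line {line}")
    df["count"] = counts.astype(np.int64)
    table = SynapseTable.from_rows(df.itertuples(index=False, name=None))
    logger.info(
        "%s: %d edges, %d synapses", path.name, len(table), table.total_synapses
    )
    return table


def write_edge_table(path: PathLike, table: SynapseTable) -> None:
    table.df.to_csv(path, index=False)


# ------------------------------------------------------------------- catalog

CATALOG_COLUMNS = [
    "neuron_id", "name", "side", "segment", "source_type", "sensory_class",
    "morph_class", "lineage", "hemilineage", "birth_order", "cohort", "homolog_id",
]


def read_catalog(path: PathLike) -> Catalog:
    """Read an annotation catalog CSV into a :class:`Catalog`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: unreadable catalog: {exc}") from exc
    for col in CATALOG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")

    def opt(v: str) -> Optional[str]:
        return v if v != "" else None

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            birth = opt(row.birth_order)
            records.append(
                NeuronRecord(
                    neuron_id=row.neuron_id,
                    name=row.name,
                    side=opt(row.side),
                    segment=opt(row.segment),
                    source_type=row.source_type or "unknown_fragment",
                    sensory_class=opt(row.sensory_class),
                    morph_class=opt(row.morph_class),
                    lineage=opt(row.lineage),
                    hemilineage=opt(row.hemilineage),
                    birth_order=int(birth) if birth is not None else None,
                    cohort=opt(row.cohort),
                    homolog_id=opt(row.homolog_id),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    try:
        return Catalog(records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_catalog(path: PathLike, catalog: Catalog) -> None:
    rows = []
    for rec in catalog:
        rows.append({
            "neuron_id": rec.neuron_id,
            "name": rec.name,
            "side": rec.side or "",
            "segment": rec.segment or "",
            "source_type": rec.source_type,
            "sensory_class": rec.sensory_class or "",
            "morph_class": rec.morph_class or "",
            "lineage": rec.lineage or "",
            "hemilineage": rec.hemilineage or "",
            "birth_order": "" if rec.birth_order is None else rec.birth_order,
            "cohort": rec.cohort or "",
            "homolog_id": rec.homolog_id or "",
        })
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, index=False)


# ----------------------------------------------------------------- skeletons


def read_skeleton(
    path: PathLike,
    dialect: SwcDialect = SwcDialect(),
    entry_node: Optional[int] = None,
) -> Skeleton:
    """Parse one SWC file into a :class:`Skeleton`.

    SWC rows are ``id type x y z radius parent`` separated by whitespace, with
    ``#`` comments; exactly one node has parent -1 (the root). The soma is the
    first node whose type equals ``dialect.soma_marker``. ``entry_node`` (the
    node where the neurite enters the neuropil) defaults to the last node in
    file order, which matches generator output; real reconstructions supply it
    via :func:`read_entry_map`.
    """
    path = Path(path)
    nodes: dict[int, SkeletonNode] = {}
    soma: Optional[int] = None
    last_id: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"{path}: line {lineno}: expected 7 SWC columns")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z = (float(v) for v in parts[2:5])
                float(parts[5])  # radius: parsed for validity, unused
                parent = int(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if nid in nodes:
                raise FormatError(f"{path}: line {lineno}: duplicate node id {nid}")
            nodes[nid] = SkeletonNode(nid, x, y, z, None if parent == -1 else parent)
            if soma is None and ntype == dialect.soma_marker:
                soma = nid
            last_id = nid
    if not nodes:
        raise FormatError(f"{path}: empty SWC file")
    if soma is None:
        raise FormatError(
            f"{path}: no node with soma marker type {dialect.soma_marker}"
        )
    if entry_node is None:
        entry_node = last_id
    try:
        return Skeleton(nodes=nodes, soma_node=soma, entry_node=entry_node)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_entry_map(path: PathLike) -> dict[str, int]:
    """Companion CSV ``neuron_id,entry_node`` mapping skeletons to entry nodes."""
    df = pd.read_csv(path, dtype={"neuron_id": str})
    for col in ("neuron_id", "entry_node"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return {r.neuron_id: int(r.entry_node) for r in df.itertuples(index=False)}


def write_skeleton(path: PathLike, skeleton: Skeleton, soma_type: int = 1) -> None:
    """Write a skeleton as SWC (type code ``soma_type`` on the soma node)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in skeleton.nodes.values():
            ntype = soma_type if n.node_id == skeleton.soma_node else 0
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(f"{n.node_id} {ntype} {n.x:g} {n.y:g} {n.z:g} 1 {parent}\n")


# ------------------------------------------------------------------ matrices


def write_matrix(path: PathLike, matrix: np.ndarray, labels: list[str]) -> None:
    """Write a labeled square matrix as CSV; re-reading reproduces the values."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError("label count does not match matrix size")
    if len(set(labels)) != len(labels):
        raise ValueError("matrix labels must be unique")
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, float_format="%.12g", index_label="")


def read_matrix(path: PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    labels = [str(v) for v in df.index]
    if labels != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), labels


# ------------------------------------------------------------------- targets


def read_targets(path: PathLike):
    """Read a target-set YAML (name, members, homolog pairs)."""
    from .input_accounting import TargetSet

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    pairs = [tuple(p) for p in doc.get("homolog_pairs", [])]
    return TargetSet(
        name=doc["name"],
        members=[str(m) for m in doc["members"]],
        homolog_pairs=[(str(a), str(b)) for a, b in pairs],
    )


def write_targets(path: PathLike, targets) -> None:
    doc = {
        "name": targets.name,
        "members": list(targets.members),
        "homolog_pairs": [list(p) for p in targets.homolog_pairs],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
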
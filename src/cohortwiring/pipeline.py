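"""Config-driven end-to-end runs and the consolidated report.

A run executes: catalog/edge validation -> input accounting (source-type
composition, per-edge histogram, left-right pairing filter, highly-connected
census, class composition) -> distance analysis (count and binary modes, plus
optional dropout variants) -> left-right / following pair summaries -> birth
order correlation from skeletons. Every stage is a pure function of (inputs,
config, seed); the report embeds the seed and a config hash so any number in
it can be recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .birth_order import birth_order_correlation, lengths_from_skeletons
from .distance import pair_summaries, run_distance_analysis
from .input_accounting import (
    PER_EDGE_BINS,
    TargetSet,
    class_composition,
    compose_by_source_type,
    highly_connected,
    inputs_onto,
    lr_pair_filter,
    sensory_breakdown,
    synapse_histogram,
)
from .io_formats import (
    SwcDialect,
    read_catalog,
    read_edge_table,
    read_entry_map,
    read_skeleton,
    read_targets,
)
from .model import Catalog, Skeleton, SynapseTable, validate_catalog

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (mirrors run.yaml)."""

    edges: Path
    catalog: Path
    targets: Path
    skeleton_dir: Optional[Path] = None
    entry_map: Optional[Path] = None
    ranks: Optional[Path] = None
    out_dir: Path = Path("run_out")
    seed: int = 0
    n_perm: int = 100
    alpha: float = 0.05
    thr_high: int = 4
    thr_low: int = 2
    min_syn: int = 10
    dropouts: tuple[str, ...] = ()
    length_unit: str = "nm"
    stages: dict = field(default_factory=dict)  # stage-name -> bool toggles

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        paths = {
            k: Path(doc[k]) if doc.get(k) else None
            for k in ("edges", "catalog", "targets", "skeleton_dir", "entry_map", "ranks")
        }
        for k in ("edges", "catalog", "targets"):
            if paths[k] is None:
                raise StageError(f"config: required path {k!r} missing")
        params = {
            k: doc[k]
            for k in ("seed", "n_perm", "alpha", "thr_high", "thr_low",
                      "min_syn", "length_unit")
            if k in doc
        }
        return cls(
            **paths,
            out_dir=Path(doc.get("out_dir", "run_out")),
            dropouts=tuple(doc.get("dropouts", ())),
            stages=dict(doc.get("stages", {})),
            **params,
        )

    def check_paths(self) -> None:
        for name in ("edges", "catalog", "targets", "skeleton_dir", "entry_map", "ranks"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise StageError(f"config: {name} path does not exist: {p}")

    def hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze(
    catalog: Catalog,
    table: SynapseTable,
    targets: TargetSet,
    skeletons: Optional[dict[str, Skeleton]] = None,
    ranks: Optional[dict[str, int]] = None,
    seed: int = 0,
    n_perm: int = 100,
    alpha: float = 0.05,
    thr_high: int = 4,
    thr_low: int = 2,
    min_syn: int = 10,
    dropouts: tuple[str, ...] = (),
) -> dict:
    """Run every analysis stage on in-memory inputs; return the report dict.

    Matrices (distances, z-scores) are included as labeled nested lists;
    numbers are stored unrounded.
    """
    report: dict = {
        "meta": {
            "version": __version__,
            "seed": seed,
            "n_perm": n_perm,
            "alpha": alpha,
            "thr_high": thr_high,
            "thr_low": thr_low,
            "min_syn": min_syn,
        },
        "warnings": [],
    }

    t0 = time.perf_counter()
    validation = validate_catalog(catalog, table)
    report["validation"] = {
        "passed": validation.passed,
        "n_issues": len(validation.issues),
        "issues": [f"[{i.kind}] {i.detail}" for i in validation.issues],
    }
    _log_stage("validate", len(table), t0)
    if not validation.passed:
        report["warnings"].append("validation reported issues; results may be off")

    t0 = time.perf_counter()
    sub, summary = inputs_onto(table, targets, catalog)
    comp = compose_by_source_type(sub, catalog)
    hist = synapse_histogram(sub, PER_EDGE_BINS, per="edge")
    paired = lr_pair_filter(sub, catalog, targets, thr_high=thr_high, thr_low=thr_low)
    hc = highly_connected(sub, catalog, targets, min_syn=min_syn)
    classes = class_composition(sub, catalog)
    sens = sensory_breakdown(sub, catalog, targets)
    report["accounting"] = {
        "target_set": targets.name,
        "total_synapses": summary.total_synapses,
        "distinct_sources": summary.distinct_sources,
        "composition_by_source_type": comp.to_dict(orient="records"),
        "per_edge_histogram": hist.to_dict(orient="records"),
        "lr_paired": {
            "neurons": paired.total_neurons,
            "synapses": paired.total_synapses,
            "n_pairs": len(paired.pairs),
            "skipped_unpaired": len(paired.skipped_unpaired),
        },
        "highly_connected": {
            "members": sorted(hc.members),
            "n_members": len(hc.members),
            "n_qualifying_neurons": len(hc.qualifying_neurons),
            "composition": hc.composition.to_dict(orient="records"),
        },
        "class_composition": classes.to_dict(orient="records"),
        "sensory_breakdown": sens.to_dict(orient="records"),
    }
    if paired.skipped_unpaired:
        report["warnings"].append(
            f"{len(paired.skipped_unpaired)} pairing candidate(s) lacked "
            "homolog annotations"
        )
    _log_stage("accounting", len(sub), t0)

    t0 = time.perf_counter()
    report["distance"] = {}
    analyzed = targets.members
    variants = [("count", "none"), ("binary", "none")]
    variants += [("count", dr) for dr in dropouts]
    binary_result = None
    for mode, dropout in variants:
        try:
            res = run_distance_analysis(
                sub, analyzed, catalog=catalog, mode=mode, dropout=dropout,
                n_perm=n_perm, seed=seed, alpha=alpha,
            )
        except ValueError as exc:
            raise StageError(f"distance ({mode}, dropout={dropout}): {exc}") from exc
        key = mode if dropout == "none" else f"{mode}_{dropout}"
        iu = np.triu_indices(len(analyzed), 1)
        n_und = int(res.undefined[iu].sum())
        n_defined = len(iu[0]) - n_und
        report["distance"][key] = {
            "analyzed": res.analyzed,
            "universe_size": _universe_size(sub, analyzed, catalog, dropout),
            "d": _rounded(res.d),
            "z": _rounded(res.z),
            "similar_pairs": _true_pairs(res.similar, res.analyzed),
            "different_pairs": _true_pairs(res.different, res.analyzed),
            "similar_call_rate": (
                float(res.similar[iu].sum() / n_defined) if n_defined else None
            ),
            "different_call_rate": (
                float(res.different[iu].sum() / n_defined) if n_defined else None
            ),
            "n_undefined_pairs": n_und,
            "z_threshold": res.z_threshold,
        }
        if n_und:
            report["warnings"].append(
                f"distance {key}: {n_und} pair(s) with zero null sd (z undefined)"
            )
        if mode == "binary" and dropout == "none":
            binary_result = res
    _log_stage("distance", len(analyzed), t0)

    t0 = time.perf_counter()
    pairs = pair_summaries(binary_result, catalog)
    report["pair_summaries"] = {
        "z_threshold": pairs.z_threshold,
        "left_right": pairs.left_right.to_dict(orient="records"),
        "following": pairs.following.to_dict(orient="records"),
    }
    _log_stage("pair_summaries", len(pairs.left_right) + len(pairs.following), t0)

    if skeletons and ranks:
        t0 = time.perf_counter()
        homologs = {n: catalog.homolog(n) for n in ranks}
        bo_table = lengths_from_skeletons(skeletons, ranks, homologs=homologs)
        corr = {}
        for which in ("L", "R", "avg"):
            try:
                res = birth_order_correlation(bo_table, which)
                corr[which] = {"r": res.r, "p": res.p, "n": res.n, "df": res.df}
            except ValueError as exc:
                corr[which] = {"error": str(exc)}
        report["birth_order"] = corr
        _log_stage("birth_order", len(ranks), t0)

    return report


def _universe_size(sub, analyzed, catalog, dropout) -> int:
    from .distance import build_input_matrix

    return len(build_input_matrix(sub, analyzed, dropout=dropout, catalog=catalog).universe)


def _rounded(m: np.ndarray, digits: int = 6) -> list:
    out = np.where(np.isnan(m), None, np.round(m, digits))
    return [[None if v is None else float(v) for v in row] for row in out.tolist()]


def _true_pairs(mask: np.ndarray, labels: list[str]) -> list[list[str]]:
    n = len(labels)
    return [
        [labels[i], labels[j]]
        for i in range(n)
        for j in range(i + 1, n)
        if mask[i, j]
    ]


def _log_stage(name: str, size: int, t0: float) -> None:
    logger.info("stage %-14s size=%-6d elapsed=%.2fs", name, size, time.perf_counter() - t0)


def run_all(cfg: RunConfig) -> dict:
    """Load inputs per the config, run :func:`analyze`, write the report bundle."""
    cfg.check_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        table = read_edge_table(cfg.edges)
        catalog = read_catalog(cfg.catalog)
        targets = read_targets(cfg.targets)
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc

    skeletons = ranks = None
    if cfg.skeleton_dir is not None:
        dialect = SwcDialect(length_unit=cfg.length_unit)
        entry = read_entry_map(cfg.entry_map) if cfg.entry_map else {}
        skeletons = {}
        for swc in sorted(Path(cfg.skeleton_dir).glob("*.swc")):
            nid = swc.stem
            skeletons[nid] = read_skeleton(swc, dialect, entry_node=entry.get(nid))
        if cfg.ranks is not None:
            import pandas as pd

            rdf = pd.read_csv(cfg.ranks, dtype={"neuron_id": str})
            ranks = {r.neuron_id: int(r.birth_rank) for r in rdf.itertuples(index=False)}

    report = analyze(
        catalog, table, targets, skeletons=skeletons, ranks=ranks,
        seed=cfg.seed, n_perm=cfg.n_perm, alpha=cfg.alpha,
        thr_high=cfg.thr_high, thr_low=cfg.thr_low, min_syn=cfg.min_syn,
        dropouts=cfg.dropouts,
    )
    report["meta"]["config_hash"] = cfg.hash()

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
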
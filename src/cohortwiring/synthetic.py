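"""Seeded generator of synthetic nervous systems for pipeline testing.

The generator emulates the statistical structure the analysis assumes, at the
scale of one segmental hemisegment pair: one or more stem-cell lineages of
10–30 neurons partitioned into temporal cohorts, mirrored into left–right
homolog pairs, wired to a shared universe of presynaptic partner units
(left–right interneuron pairs, unpaired midline neurons, sensory neurons)
under one of three wiring models:

* ``sharp``  — each cohort draws a dedicated partner pool; members connect to
  pool partners with probability ``p_within`` and to all other partners with
  ``p_across``. Cohort boundaries are abrupt.
* ``graded`` — each neuron inherits its rank-predecessor's partner set, with
  every partner independently replaced with probability ``drift_rate``;
  connectivity drifts continuously with birth rank and no sharp boundary
  exists.
* ``null``   — every (partner, neuron) edge is independent with a uniform
  probability matched to the sharp model's expected density; no structure.

Per-edge synapse counts are heavy-tailed (geometric, most edges one synapse,
rare edges into the tens), and a straight-chain skeleton is emitted per
lineage neuron with cortex neurite length increasing linearly in birth rank
plus Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .input_accounting import TargetSet
from .model import Catalog, NeuronRecord, Skeleton, SkeletonNode, SynapseTable

WIRING_MODELS = ("sharp", "graded", "null")


@dataclass
class CountLaw:
    """Skewed per-edge synapse-count distribution.

    A mixture: with probability ``p_one`` an edge carries a single synapse;
    otherwise the count is 1 + Geometric(``p_tail``), truncated at
    ``max_count``. The default (p_tail = p_one) is geometric-like: ~80% of
    edges are singletons and the tail decays fast. Lowering ``p_tail``
    (e.g. to 0.3) gives the heavier tail of real EM edge lists, where a few
    reliable partners contribute 10-30 synapses; note that heavy tails make
    the count-mode permutation z-score mildly anticonservative at small
    problem sizes (see the methods note), so the distance-statistics defaults
    stay geometric-like.
    """

    p_one: float = 0.8
    p_tail: float = 0.8
    max_count: int = 30

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        counts = np.ones(size, dtype=np.int64)
        tail = rng.random(size) >= self.p_one
        counts[tail] += rng.geometric(self.p_tail, size=int(tail.sum()))
        return np.minimum(counts, self.max_count)


@dataclass
class SkeletonLaw:
    """Cortex neurite length model: base + slope * rank + N(0, noise_sd).

    Units follow the skeleton coordinate unit of the run (micrometres by
    convention here). Negative draws are clamped to a small positive length.
    """

    base: float = 5.0
    slope: float = 2.0
    noise_sd: float = 1.0
    n_segments: int = 5


@dataclass
class SynthConfig:
    """Parameters of one synthetic nervous system."""

    n_lineages: int = 1
    n_neurons: int = 10  # per lineage, per side
    cohort_cuts: tuple[int, ...] = (5,)  # rank cut-points; (5,) = cohorts 1-5, 6-10
    segment: str = "A1"
    universe_size: int = 200  # presynaptic partner units
    n_midline: int = 10  # of which unpaired midline units
    frac_interneuron: float = 0.61
    frac_sensory: float = 0.19
    wiring_model: str = "sharp"
    p_within: float = 0.8
    p_across: float = 0.05
    pool_size: int = 30  # shared-partner pool per cohort (sharp/graded seed set)
    pool_overlap: float = 0.0  # fraction of pool shared with the previous cohort
    drift_rate: float = 0.2  # per-rank partner turnover (graded)
    # probability a mirrored edge is redrawn instead of copied; a scalar
    # applies to every cohort, a tuple gives one rate per cohort (left-right
    # wiring conservation differs between cohorts in real lineages)
    mirror_noise: float | tuple[float, ...] = (0.1, 0.6)
    # probability a mirrored edge is carried by the *same* presynaptic neuron
    # (a bilateral arbor contacting both homologous targets) rather than by
    # the opposite-side homolog member; scalar or one value per cohort.
    # Midline partners always contact both sides themselves.
    p_bilateral: float | tuple[float, ...] = (0.8, 0.2)
    count_law: CountLaw = field(default_factory=CountLaw)
    skeleton_law: SkeletonLaw = field(default_factory=SkeletonLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wiring_model not in WIRING_MODELS:
            raise ValueError(f"wiring_model must be one of {WIRING_MODELS}")
        for name in ("p_within", "p_across", "drift_rate", "pool_overlap",
                     "frac_interneuron", "frac_sensory"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_interneuron + self.frac_sensory > 1.0:
            raise ValueError("source-type fractions exceed 1")
        cuts = tuple(self.cohort_cuts)
        if list(cuts) != sorted(set(cuts)) or (cuts and cuts[-1] >= self.n_neurons):
            raise ValueError("cohort_cuts must be strictly increasing and < n_neurons")
        for name in ("mirror_noise", "p_bilateral"):
            v = getattr(self, name)
            vals = (v,) if isinstance(v, (int, float)) else tuple(v)
            if any(not 0.0 <= x <= 1.0 for x in vals):
                raise ValueError(f"{name} values must be in [0, 1]")
            if len(vals) not in (1, len(cuts) + 1):
                raise ValueError(
                    f"{name} must be a scalar or give one rate per cohort"
                )
        if self.n_midline > self.universe_size:
            raise ValueError("n_midline exceeds universe_size")
        n_cohorts = len(cuts) + 1
        fresh_per_pool = self.pool_size - int(round(self.pool_overlap * self.pool_size))
        need = self.pool_size + (n_cohorts - 1) * fresh_per_pool
        if self.wiring_model == "sharp" and need * self.n_lineages > self.universe_size:
            raise ValueError(
                f"cohort pools need {need * self.n_lineages} partners but "
                f"universe has {self.universe_size}"
            )

    @property
    def cohort_labels(self) -> list[str]:
        n = len(self.cohort_cuts) + 1
        if n == 2:
            return ["early", "late"]
        return [f"cohort{i + 1}" for i in range(n)]

    def cohort_of_rank(self, rank: int) -> int:
        """0-based cohort index of a 1-based birth rank."""
        for i, cut in enumerate(self.cohort_cuts):
            if rank <= cut:
                return i
        return len(self.cohort_cuts)

    @staticmethod
    def _per_cohort(value, cohort_index: int) -> float:
        if isinstance(value, (int, float)):
            return float(value)
        vals = tuple(value)
        return float(vals[0] if len(vals) == 1 else vals[cohort_index])

    def mirror_noise_of(self, cohort_index: int) -> float:
        return self._per_cohort(self.mirror_noise, cohort_index)

    def p_bilateral_of(self, cohort_index: int) -> float:
        return self._per_cohort(self.p_bilateral, cohort_index)


@dataclass
class GroundTruth:
    """What the generator actually wired, for recovery scoring."""

    wiring_model: str
    cohort_of: dict[str, str]  # lineage neuron id -> cohort label
    pools: dict[str, set[str]]  # cohort label -> dedicated partner unit ids
    has_cohort_structure: bool


@dataclass
class SyntheticSystem:
    catalog: Catalog
    table: SynapseTable
    skeletons: dict[str, Skeleton]
    truth: GroundTruth
    config: SynthConfig

    def target_set(self, lineage: int = 0) -> TargetSet:
        """Target set of one lineage's neurons, in birth order, L before R."""
        members, pairs = [], []
        name = _lineage_name(lineage)
        for rank in range(1, self.config.n_neurons + 1):
            left = _neuron_id(lineage, "L", rank)
            right = _neuron_id(lineage, "R", rank)
            members += [left, right]
            pairs.append((left, right))
        return TargetSet(name=f"{name}_{self.config.segment}LR",
                         members=members, homolog_pairs=pairs)


def _lineage_name(i: int) -> str:
    return f"LIN{i + 1}"


def _neuron_id(lineage: int, side: str, rank: int) -> str:
    return f"{_lineage_name(lineage)}_{side}_r{rank:02d}"


def generate(cfg: SynthConfig, seed: Optional[int] = None) -> SyntheticSystem:
    """Generate one synthetic nervous system.

    Identical (cfg, seed) always regenerates a bit-identical system. ``seed``
    overrides ``cfg.seed`` when given.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    # ---- presynaptic partner universe -------------------------------------
    n_paired = cfg.universe_size - cfg.n_midline
    unit_ids = [f"MID{i:03d}" for i in range(cfg.n_midline)] + [
        f"U{i:03d}" for i in range(n_paired)
    ]
    is_midline = [True] * cfg.n_midline + [False] * n_paired

    n_sens = int(round(cfg.frac_sensory * cfg.universe_size))
    n_inter = int(round(cfg.frac_interneuron * cfg.universe_size))
    # midline units are Ladder-style interneurons by construction
    types = ["interneuron"] * cfg.n_midline
    remaining = ["sensory"] * n_sens + ["interneuron"] * max(0, n_inter - cfg.n_midline)
    remaining += ["brain_or_SEZ"] * (n_paired - len(remaining))
    rng.shuffle(remaining)
    types += remaining[:n_paired]

    sensory_classes = ("chordotonal", "proprioceptive", "other")
    records: list[NeuronRecord] = []
    member_of: dict[str, tuple[str, str]] = {}  # unit -> (left member, right member)
    for uid, mid, stype in zip(unit_ids, is_midline, types):
        s_class = (
            sensory_classes[rng.integers(len(sensory_classes))]
            if stype == "sensory" else None
        )
        if mid:
            records.append(NeuronRecord(
                neuron_id=uid, name=uid, side="M", segment=cfg.segment,
                source_type=stype, sensory_class=s_class,
                morph_class="Ladder" if stype == "interneuron" else None,
                homolog_id=uid,
            ))
            member_of[uid] = (uid, uid)
        else:
            left, right = f"{uid}_L", f"{uid}_R"
            for nid, side, hom in ((left, "L", right), (right, "R", left)):
                records.append(NeuronRecord(
                    neuron_id=nid, name=nid, side=side, segment=cfg.segment,
                    source_type=stype, sensory_class=s_class, homolog_id=hom,
                ))
            member_of[uid] = (left, right)

    # ---- lineage neurons ---------------------------------------------------
    cohort_of: dict[str, str] = {}
    for li in range(cfg.n_lineages):
        for rank in range(1, cfg.n_neurons + 1):
            cohort = cfg.cohort_labels[cfg.cohort_of_rank(rank)]
            left = _neuron_id(li, "L", rank)
            right = _neuron_id(li, "R", rank)
            for nid, side, hom in ((left, "L", right), (right, "R", left)):
                records.append(NeuronRecord(
                    neuron_id=nid, name=nid, side=side, segment=cfg.segment,
                    source_type="interneuron", lineage=_lineage_name(li),
                    hemilineage="NotchOFF", birth_order=rank, cohort=cohort,
                    homolog_id=hom,
                ))
                cohort_of[nid] = cohort
    catalog = Catalog(records)

    # ---- wiring ------------------------------------------------------------
    # A mirrored edge is carried either by the same presynaptic neuron (a
    # bilateral arbor contacting both homologous targets, probability
    # p_bilateral for the target's cohort; always for midline partners) or by
    # the opposite-side homolog member. Without some same-neuron sharing,
    # left and right homologous targets would have disjoint input vectors and
    # left-right similarity would be undetectable by construction.
    midline_mask = np.asarray(is_midline)
    pools: dict[str, set[str]] = {}
    edge_rows: list[tuple[str, str, int]] = []

    if cfg.wiring_model == "null":
        # structureless control: every (partner neuron, target) edge is
        # independent, both within and across sides, with a uniform
        # probability matched to the sharp model's expected in-degree
        members = [m for uid in unit_ids for m in dict.fromkeys(member_of[uid])]
        expected_indegree = (
            cfg.p_within * cfg.pool_size
            + cfg.p_across * (cfg.universe_size - cfg.pool_size)
        )
        p_member = expected_indegree / len(members)
        for li in range(cfg.n_lineages):
            for rank in range(1, cfg.n_neurons + 1):
                for side in ("L", "R"):
                    target = _neuron_id(li, side, rank)
                    present = rng.random(len(members)) < p_member
                    counts = cfg.count_law.draw(rng, len(members))
                    edge_rows.extend(
                        (members[j], target, int(counts[j]))
                        for j in np.flatnonzero(present)
                    )
        return _assemble(cfg, catalog, edge_rows, cohort_of, pools, rng)

    for li in range(cfg.n_lineages):
        probs, lineage_pools = _connection_probabilities(cfg, unit_ids, rng)
        if cfg.wiring_model == "sharp":
            for label, pool in lineage_pools.items():
                pools.setdefault(label, set()).update(pool)
        for rank in range(1, cfg.n_neurons + 1):
            cohort_idx = cfg.cohort_of_rank(rank)
            p_row = probs[rank - 1]
            present = rng.random(len(unit_ids)) < p_row
            counts = cfg.count_law.draw(rng, len(unit_ids))
            left_target = _neuron_id(li, "L", rank)
            right_target = _neuron_id(li, "R", rank)
            noise = cfg.mirror_noise_of(cohort_idx)
            redraw = rng.random(len(unit_ids)) < noise
            present_r = np.where(redraw, rng.random(len(unit_ids)) < p_row, present)
            counts_r = np.where(redraw, cfg.count_law.draw(rng, len(unit_ids)), counts)
            same_member = rng.random(len(unit_ids)) < cfg.p_bilateral_of(cohort_idx)
            same_member |= midline_mask
            for j, uid in enumerate(unit_ids):
                m_l, m_r = member_of[uid]
                mirror_member = m_l if same_member[j] else m_r
                if present[j]:
                    edge_rows.append((m_l, left_target, int(counts[j])))
                if present_r[j]:
                    edge_rows.append((mirror_member, right_target, int(counts_r[j])))
    return _assemble(cfg, catalog, edge_rows, cohort_of, pools, rng)


def _assemble(
    cfg: SynthConfig,
    catalog: Catalog,
    edge_rows: list[tuple[str, str, int]],
    cohort_of: dict[str, str],
    pools: dict[str, set[str]],
    rng: np.random.Generator,
) -> SyntheticSystem:
    table = SynapseTable.from_rows(edge_rows)

    skeletons: dict[str, Skeleton] = {}
    law = cfg.skeleton_law
    for li in range(cfg.n_lineages):
        for rank in range(1, cfg.n_neurons + 1):
            for side in ("L", "R"):
                length = law.base + law.slope * rank + rng.normal(0.0, law.noise_sd)
                length = max(length, 0.1)
                skeletons[_neuron_id(li, side, rank)] = _chain_skeleton(
                    length, law.n_segments, rng
                )

    truth = GroundTruth(
        wiring_model=cfg.wiring_model,
        cohort_of=cohort_of,
        pools=pools if cfg.wiring_model == "sharp" else {},
        has_cohort_structure=cfg.wiring_model == "sharp",
    )
    return SyntheticSystem(
        catalog=catalog, table=table, skeletons=skeletons, truth=truth, config=cfg
    )


def _connection_probabilities(
    cfg: SynthConfig, unit_ids: list[str], rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, set[str]]]:
    """Per-(rank, unit) connection probability matrix for one lineage."""
    k = len(unit_ids)
    probs = np.full((cfg.n_neurons, k), cfg.p_across)
    pools: dict[str, set[str]] = {}

    if cfg.wiring_model == "sharp":
        available = list(range(k))
        prev: list[int] = []
        for ci, label in enumerate(cfg.cohort_labels):
            n_shared = int(round(cfg.pool_overlap * cfg.pool_size)) if ci else 0
            shared = list(rng.choice(prev, size=n_shared, replace=False)) if n_shared else []
            n_fresh = cfg.pool_size - len(shared)
            fresh = list(rng.choice(available, size=n_fresh, replace=False))
            available = [i for i in available if i not in set(fresh)]
            pool = shared + fresh
            pools[label] = {unit_ids[i] for i in pool}
            for rank in range(1, cfg.n_neurons + 1):
                if cfg.cohort_of_rank(rank) == ci:
                    probs[rank - 1, pool] = cfg.p_within
            prev = pool
    elif cfg.wiring_model == "graded":
        current = set(rng.choice(k, size=min(cfg.pool_size, k), replace=False).tolist())
        for rank in range(1, cfg.n_neurons + 1):
            if rank > 1:
                kept = {u for u in current if rng.random() >= cfg.drift_rate}
                n_new = len(current) - len(kept)
                outside = [i for i in range(k) if i not in kept]
                new = rng.choice(outside, size=n_new, replace=False).tolist()
                current = kept | set(new)
            probs[rank - 1, sorted(current)] = cfg.p_within
    else:  # null: uniform density matched to the sharp model's expectation
        p_null = (
            cfg.p_within * cfg.pool_size
            + cfg.p_across * (cfg.universe_size - cfg.pool_size)
        ) / cfg.universe_size
        probs[:, :] = p_null
    return probs, pools


def _chain_skeleton(
    length: float, n_segments: int, rng: np.random.Generator
) -> Skeleton:
    """Straight chain of n_segments+1 nodes with total path length ``length``."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    origin = rng.uniform(-100.0, 100.0, size=3)
    step = length / n_segments
    nodes: dict[int, SkeletonNode] = {}
    for i in range(n_segments + 1):
        pos = origin + direction * step * i
        nodes[i + 1] = SkeletonNode(
            node_id=i + 1,
            x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            parent_id=None if i == 0 else i,
        )
    return Skeleton(nodes=nodes, soma_node=1, entry_node=n_segments + 1)


def mirror_divergence(system: SyntheticSystem, lineage: int = 0) -> float:
    """Mean fraction of partner-set disagreement between left–right homologs.

    Diagnostic of ``mirror_noise``: 0 when every right vector mirrors its left
    homolog exactly, approaching the model's chance disagreement as noise
    grows.
    """
    cfg = system.config
    lut: dict[str, set[str]] = {}
    for r in system.table.df.itertuples(index=False):
        lut.setdefault(r.post_id, set()).add(_unit_of(r.pre_id))
    fracs = []
    for rank in range(1, cfg.n_neurons + 1):
        a = lut.get(_neuron_id(lineage, "L", rank), set())
        b = lut.get(_neuron_id(lineage, "R", rank), set())
        union = a | b
        if union:
            fracs.append(len(a ^ b) / len(union))
    return float(np.mean(fracs)) if fracs else math.nan


def _unit_of(member_id: str) -> str:
    return member_id[:-2] if member_id.endswith(("_L", "_R")) else member_id
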
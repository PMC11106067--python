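"""Seeded generators for chronograms, range histories, and temperature series.

Everything the analysis consumes can be produced here with known ground truth:

* :func:`simulate_tree` -- forward birth-death trees conditioned on an extant
  tip count, optionally retaining extinct lineages as dated fossil tips;
* :func:`simulate_ranges` -- exact (Gillespie) forward simulation of the
  anagenetic gain/loss process with epoch-correct rates plus cladogenetic
  draws, logging every realized event with its exact time and scope;
* :func:`simulate_temperature` -- a piecewise-linear temperature trend with
  iid Gaussian noise on a regular age grid.

One integer seed drives each generator through its own ``numpy`` Generator, so
stages can be re-run in isolation and byte-identical outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chronogram import Chronogram
from .range_space import AreaSet, StateSpace, _bits, dispersal_scope, vicariance_scope
from .ancestral_events import (
    DISPERSAL,
    EXTINCTION,
    VICARIANCE,
    AncestralReconstruction,
    BiogeoEvent,
)
from .biogeo_models import BiogeoModel, EpochSchedule, cladogenesis_distribution
from .range_space import EXTINCTION_SCOPE
from .paleoclimate import TemperatureSeries

__all__ = [
    "simulate_tree",
    "SimulatedHistory",
    "simulate_ranges",
    "simulate_temperature",
]


def simulate_tree(
    birth: float,
    death: float,
    n_extant: int,
    fossil_sampling: float = 0.0,
    seed: int = 0,
    max_tries: int = 1000,
) -> Chronogram:
    """Forward birth-death chronogram conditioned on ``n_extant`` extant tips.

    Simulation starts from the crown (two lineages) and runs until the extant
    lineage count first reaches ``n_extant``; the present is then placed
    uniformly inside the waiting interval before the next event, a simple and
    reproducible (if approximate) conditioning scheme.  Each extinct lineage is
    retained as a fossil tip at its extinction time with probability
    ``1 - exp(-fossil_sampling * pendant_length)``, otherwise pruned.  Runs
    that go extinct before reaching ``n_extant`` are retried (bounded).
    """
    if not birth > death >= 0:
        raise ValueError(f"need birth > death >= 0, got birth={birth}, death={death}")
    if n_extant < 2:
        raise ValueError(f"need n_extant >= 2, got {n_extant}")
    if fossil_sampling < 0:
        raise ValueError("fossil_sampling must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        newick = _simulate_tree_once(birth, death, n_extant, fossil_sampling, rng)
        if newick is not None:
            return Chronogram.from_newick(newick)
    raise RuntimeError(
        f"failed to reach {n_extant} extant tips in {max_tries} attempts "
        f"(birth={birth}, death={death})"
    )


def _simulate_tree_once(birth, death, n_extant, fossil_sampling, rng):
    # each lineage: dict(birth_time, death_time|None, children, sampled)
    lineages = [
        {"t0": 0.0, "t1": None, "children": [], "alive": True} for _ in range(2)
    ]
    root_pair = (lineages[0], lineages[1])
    alive = list(lineages)
    t = 0.0
    while True:
        n_alive = len(alive)
        if n_alive == 0:
            return None
        total = n_alive * (birth + death)
        wait = rng.exponential(1.0 / total)
        if n_alive == n_extant:
            t_stop = t + rng.uniform(0.0, wait)
            break
        t += wait
        lin = alive[rng.integers(n_alive)]
        if rng.uniform() < birth / (birth + death):
            lin["t1"] = t
            lin["alive"] = False
            kids = [
                {"t0": t, "t1": None, "children": [], "alive": True} for _ in range(2)
            ]
            lin["children"] = kids
            alive.remove(lin)
            alive.extend(kids)
        else:
            lin["t1"] = t
            lin["alive"] = False
            alive.remove(lin)

    tip_counter = [0]

    def render(lin) -> str | None:
        end = lin["t1"] if lin["t1"] is not None else t_stop
        length = end - lin["t0"]
        if lin["children"]:
            parts = [render(c) for c in lin["children"]]
            parts = [p for p in parts if p is not None]
            if len(parts) == 2:
                return f"({parts[0]},{parts[1]}):{length:.12f}"
            if len(parts) == 1:
                # unifurcation: absorb this edge into the surviving child
                child = parts[0]
                stem, _, clen = child.rpartition(":")
                return f"{stem}:{float(clen) + length:.12f}"
            return None
        if lin["alive"]:
            tip_counter[0] += 1
            return f"t{tip_counter[0]}:{length:.12f}"
        # extinct pendant lineage: fossil-sample or prune
        if fossil_sampling > 0 and rng.uniform() < 1.0 - np.exp(-fossil_sampling * length):
            tip_counter[0] += 1
            return f"f{tip_counter[0]}:{length:.12f}"
        return None

    parts = [render(l) for l in root_pair]
    parts = [p for p in parts if p is not None]
    if len(parts) != 2:
        return None  # crown side lost entirely; retry for a clean crown tree
    return f"({parts[0]},{parts[1]});"


# -- range evolution --------------------------------------------------------


@dataclass
class SimulatedHistory:
    """A forward-simulated range history with full ground truth.

    ``true_events`` logs every realized anagenetic jump (exact time, source,
    scope) and every cladogenetic vicariance/founder outcome; subset-sympatry
    and copy outcomes change no range and generate no event, so the corner
    states needed to replay the history are recorded separately in
    ``corner_states``.  ``branch_paths`` holds the realized piecewise state
    path (age, range) per branch, oldest point first.
    """

    tree: Chronogram
    model: BiogeoModel
    epochs: EpochSchedule
    space: StateSpace
    root_range: int
    tip_ranges: dict[str, int]
    node_states: dict[str, int]
    corner_states: dict[str, int]
    branch_paths: dict[str, list[tuple[float, int]]]
    true_events: list[BiogeoEvent]
    seed: int

    @property
    def areas(self) -> AreaSet:
        return self.space.areas

    @property
    def dead_tips(self) -> tuple[str, ...]:
        return tuple(t for t, m in self.tip_ranges.items() if m == 0)

    def observable_tip_ranges(self) -> dict[str, int]:
        return {t: m for t, m in self.tip_ranges.items() if m != 0}

    def pruned_to_observable(self):
        """Drop dead (null-range) tips from the tree, as an observer would.

        Returns ``(tree, tip_ranges)`` restricted to observable tips.  Raises
        if fewer than two tips survive.
        """
        from .chronogram import prune_tip

        tree = self.tree
        for label in self.dead_tips:
            tree = prune_tip(tree, label)
        return tree, self.observable_tip_ranges()

    def to_reconstruction(self) -> AncestralReconstruction:
        """Point-mass 'reconstruction' of the true history (bypasses inference)."""
        marginals = {}
        node_map = {}
        for nid, state in self.node_states.items():
            v = np.zeros(len(self.space))
            v[self.space.index_of(state)] = 1.0
            marginals[nid] = v
            node_map[nid] = state
        return AncestralReconstruction(
            tree=self.tree,
            space=self.space,
            marginals=marginals,
            node_map=node_map,
            corner_map=dict(self.corner_states),
            model_name="true-history",
            branch_paths={k: list(v) for k, v in self.branch_paths.items()},
        )

    def replay_tip_ranges(self) -> dict[str, int]:
        """Re-derive tip ranges from corner states plus logged anagenetic events."""
        by_branch: dict[str, list[BiogeoEvent]] = {}
        for ev in self.true_events:
            if ev.event_type in (DISPERSAL, EXTINCTION):
                by_branch.setdefault(ev.branch_id, []).append(ev)
        out: dict[str, int] = {}
        tree = self.tree
        for node in tree.preorder():
            nid = tree.id_of(node)
            if node.parent_node is None:
                state = self.root_range
            else:
                state = self.corner_states[nid]
                for ev in sorted(by_branch.get(nid, []), key=lambda e: -e.time):
                    bit = 1 << self.areas.index(ev.detail)
                    if ev.event_type == DISPERSAL and not _is_cladogenetic(ev, tree, nid):
                        state |= bit
                    elif ev.event_type == EXTINCTION:
                        state &= ~bit
            if node.is_leaf():
                out[nid] = state
        return out


def _is_cladogenetic(ev: BiogeoEvent, tree: Chronogram, nid: str) -> bool:
    # founder events are logged on the daughter's branch at exactly the parent's age
    node = tree.node(nid)
    return (
        node.parent_node is not None
        and abs(ev.time - tree.age(node.parent_node)) < 1e-12
    )


def simulate_ranges(
    tree: Chronogram,
    model: BiogeoModel,
    epochs: EpochSchedule,
    root_range: int,
    seed: int = 0,
    space: StateSpace | None = None,
    areas: AreaSet | None = None,
    max_range_size: int | None = None,
) -> SimulatedHistory:
    """Forward-simulate range evolution along a chronogram.

    Anagenesis is simulated exactly by Gillespie jumps with the epoch's rates
    (waiting times are re-drawn at epoch boundaries, valid because rates are
    piecewise constant); cladogenetic outcomes are drawn from the model's
    cladogenesis distribution with the node-epoch multiplier gating founder
    targets.  Lineages that lose their last area become dead (null range) and
    stay dead; their tips report a null range.
    """
    if space is None:
        if areas is None:
            raise ValueError("provide either a StateSpace or an AreaSet")
        space = StateSpace(areas, max_range_size)
    areas = space.areas
    if root_range == 0:
        raise ValueError("root range must be non-empty")
    space.index_of(root_range)  # validates size constraint
    rng = np.random.default_rng(seed)

    node_states: dict[str, int] = {}
    corner_states: dict[str, int] = {}
    branch_paths: dict[str, list[tuple[float, int]]] = {}
    events: list[BiogeoEvent] = []
    clado_cache: dict[tuple[int, int], tuple[list[tuple[int, int]], np.ndarray]] = {}

    def clado_draw(parent: int, age: float) -> tuple[int, int]:
        k = epochs.epoch_index(age)
        key = (parent, k)
        if key not in clado_cache:
            dist = cladogenesis_distribution(
                space, model, parent, epochs.multipliers[k]
            )
            pairs = sorted(dist)
            clado_cache[key] = (pairs, np.array([dist[p] for p in pairs]))
        pairs, probs = clado_cache[key]
        return pairs[rng.choice(len(pairs), p=probs)]

    def evolve(state: int, start_age: float, end_age: float, branch_id: str) -> int:
        path = [(start_age, state)]
        t_hi = start_age
        for k, dt in epochs.segments(start_age, end_age):
            m = epochs.multipliers[k]
            t = t_hi
            seg_lo = t_hi - dt
            while state != 0:
                members = list(_bits(state))
                gains = []
                if len(members) < space.max_range_size:
                    for b in range(space.n_areas):
                        if state >> b & 1:
                            continue
                        rate = model.d * sum(m[a, b] for a in members)
                        if rate > 0:
                            gains.append((b, rate))
                losses = [(a, model.e) for a in members] if model.e > 0 else []
                total = sum(r for _, r in gains) + sum(r for _, r in losses)
                if total <= 0:
                    break
                wait = rng.exponential(1.0 / total)
                if t - wait < seg_lo:
                    break  # next epoch (or branch end): memoryless restart
                t -= wait
                choices = gains + losses
                rates = np.array([r for _, r in choices])
                idx = rng.choice(len(choices), p=rates / rates.sum())
                area, _ = choices[idx]
                if idx < len(gains):
                    events.append(
                        BiogeoEvent(
                            DISPERSAL,
                            t,
                            dispersal_scope(areas, state, area),
                            state,
                            areas.codes[area],
                            branch_id,
                        )
                    )
                    state |= 1 << area
                else:
                    events.append(
                        BiogeoEvent(
                            EXTINCTION, t, EXTINCTION_SCOPE, state,
                            areas.codes[area], branch_id,
                        )
                    )
                    state &= ~(1 << area)
                path.append((t, state))
            t_hi = seg_lo  # advance to the segment end even without events
        path.append((end_age, state))
        branch_paths[branch_id] = path
        return state

    def visit(node, state: int) -> None:
        nid = tree.id_of(node)
        node_states[nid] = state
        if node.is_leaf():
            return
        age = tree.age(node)
        if state == 0:
            left_c = right_c = 0
        else:
            left_c, right_c = clado_draw(state, age)
            if left_c | right_c == state and left_c and right_c and not left_c & right_c and left_c != state:
                events.append(
                    BiogeoEvent(
                        VICARIANCE,
                        age,
                        vicariance_scope(areas, left_c, right_c),
                        state,
                        f"{areas.format_range(left_c)}|{areas.format_range(right_c)}",
                        nid,
                    )
                )
        children = node.child_nodes()
        for child, corner in zip(children, (left_c, right_c)):
            cid = tree.id_of(child)
            corner_states[cid] = corner
            if corner & ~state:
                b = next(_bits(corner & ~state))
                events.append(
                    BiogeoEvent(
                        DISPERSAL,
                        age,
                        dispersal_scope(areas, state, b),
                        state,
                        areas.codes[b],
                        cid,
                    )
                )
            end_state = (
                evolve(corner, age, tree.age(child), cid) if corner else 0
            )
            if corner == 0:
                branch_paths[cid] = [(age, 0), (tree.age(child), 0)]
            visit(child, end_state)

    visit(tree.root, root_range)
    events.sort(key=lambda ev: (-ev.time, ev.branch_id, ev.event_type, ev.detail))
    return SimulatedHistory(
        tree=tree,
        model=model,
        epochs=epochs,
        space=space,
        root_range=root_range,
        tip_ranges={t: node_states[t] for t in tree.tip_labels},
        node_states=node_states,
        corner_states=corner_states,
        branch_paths=branch_paths,
        true_events=events,
        seed=seed,
    )


# -- temperature ------------------------------------------------------------


def simulate_temperature(
    trend: list[tuple[float, float]],
    noise_sd: float = 0.5,
    step: float = 0.25,
    seed: int = 0,
    age_min: float = 0.0,
    age_max: float | None = None,
) -> TemperatureSeries:
    """Piecewise-linear temperature trend plus iid Gaussian noise on an age grid.

    ``trend`` lists (age, temperature) anchor points; slope-change points in
    the trend become detectable breaks in the loess slope.  Reproducible byte
    for byte given the seed.
    """
    if noise_sd < 0 or step <= 0:
        raise ValueError("need noise_sd >= 0 and step > 0")
    if len(trend) < 2:
        raise ValueError("trend needs at least two (age, temperature) anchors")
    anchors = sorted((float(a), float(v)) for a, v in trend)
    t_ages = np.array([a for a, _ in anchors])
    t_vals = np.array([v for _, v in anchors])
    if age_max is None:
        age_max = float(t_ages.max())
    if not age_max > age_min >= 0:
        raise ValueError(f"empty age span [{age_min}, {age_max}]")
    if age_min < t_ages.min() or age_max > t_ages.max():
        raise ValueError("trend anchors must cover the requested age span")
    grid = np.round(np.arange(age_min, age_max + step / 2, step), 10)
    rng = np.random.default_rng(seed)
    temps = np.interp(grid, t_ages, t_vals)
    if noise_sd > 0:
        temps = temps + rng.normal(0.0, noise_sd, size=grid.size)
    return TemperatureSeries(grid, temps)
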
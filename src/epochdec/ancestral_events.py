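"""Ancestral range reconstruction and deterministic biogeographic event extraction.

Marginal ancestral ranges come from an inside-outside pass over the fitted
model (same epoch-aware propagators and cladogenetic weights as the
likelihood).  Events are then read off deterministically:

* cladogenetic events from the MAP parent range versus the daughters' "corner"
  ranges immediately after cladogenesis -- vicariance when the corners are
  disjoint and their union is the parent, founder dispersal when a corner
  contains an area outside the parent;
* anagenetic events from the corner range versus the child node's MAP range --
  one dispersal per gained area and one extinction per lost area, placed at
  the branch midpoint age (gains before losses, areas in bitmask order).

When the reconstruction carries realized per-branch state paths (simulated
true histories), anagenetic events are read from the actual jumps instead of
the endpoint difference, so canceling jumps are not lost; reported times still
follow the midpoint convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .chronogram import Chronogram
from .range_space import (
    ADJACENT,
    EXTINCTION_SCOPE,
    INTERCONTINENTAL,
    AreaSet,
    StateSpace,
    _bits,
    dispersal_scope,
    vicariance_scope,
)
from .biogeo_models import EpochSchedule, FitResult, PruningEngine

__all__ = [
    "DISPERSAL",
    "VICARIANCE",
    "EXTINCTION",
    "BiogeoEvent",
    "AncestralReconstruction",
    "marginal_ranges",
    "extract_events",
    "EventDensityCurve",
    "event_density",
    "period_summary",
    "events_to_frame",
]

DISPERSAL = "dispersal"
VICARIANCE = "vicariance"
EXTINCTION = "extinction"


@dataclass(frozen=True)
class BiogeoEvent:
    """One typed, timed, scoped range-change event.

    ``detail`` names the gained/lost area for dispersal/extinction or the
    ``L|R`` partition for vicariance; ``branch_id`` is the id of the node below
    the hosting branch (or the node itself for cladogenetic events).
    """

    event_type: str
    time: float
    scope: str
    source: int
    detail: str
    branch_id: str

    def key(self) -> tuple[str, str, str]:
        """(type, scope, detail) triple used when comparing event logs."""
        return (self.event_type, self.scope, self.detail)


@dataclass
class AncestralReconstruction:
    """Per-node marginals, MAP ranges, and per-daughter corner ranges."""

    tree: Chronogram
    space: StateSpace
    marginals: dict[str, np.ndarray]
    node_map: dict[str, int]
    corner_map: dict[str, int]
    model_name: str = ""
    branch_paths: dict[str, list[tuple[float, int]]] | None = None

    def map_range(self, node_id: str) -> int:
        return self.node_map[node_id]

    def to_frame(self) -> pd.DataFrame:
        """Node table: id, age, MAP range, and the full marginal distribution."""
        areas = self.space.areas
        rows = []
        for node in self.tree.preorder():
            nid = self.tree.id_of(node)
            marg = self.marginals[nid]
            top = np.argsort(marg)[::-1][:3]
            rows.append(
                {
                    "node_id": nid,
                    "age_ma": self.tree.age(node),
                    "map_range": areas.format_range(self.node_map[nid]),
                    "map_prob": float(marg.max()),
                    "top_states": ";".join(
                        f"{self.space.format_state(int(i))}:{marg[int(i)]:.4f}"
                        for i in top
                        if marg[int(i)] > 0
                    ),
                }
            )
        return pd.DataFrame(rows)


def marginal_ranges(
    tree: Chronogram,
    tip_ranges: dict[str, int],
    fit: FitResult,
    space: StateSpace,
    epochs: EpochSchedule,
    root_prior: np.ndarray | None = None,
) -> AncestralReconstruction:
    """Marginal and MAP ancestral ranges under a fitted model."""
    if not fit.converged:
        raise ValueError("refusing to reconstruct from a non-converged fit")
    engine = PruningEngine(tree, tip_ranges, space, epochs, fit.model.family, root_prior)
    marginals, node_map, corner_map = engine.reconstruct(fit.model)
    return AncestralReconstruction(
        tree=tree,
        space=space,
        marginals=marginals,
        node_map=node_map,
        corner_map=corner_map,
        model_name=fit.name,
    )


# -- event extraction -------------------------------------------------------


def _classify_cladogenesis(areas, parent: int, left: int, right: int):
    """Return a cladogenetic BiogeoEvent template or None (sympatry/copy)."""
    if left == parent and right == parent:
        return None
    if left | right == parent and not left & right and left and right:
        return (VICARIANCE, parent, (left, right))
    for corner in (left, right):
        if corner & ~parent:
            gained = corner & ~parent
            if gained.bit_count() != 1 or (corner != gained and corner != parent | gained):
                raise ValueError(
                    f"inconsistent corner state {areas.format_range(corner)} under "
                    f"parent {areas.format_range(parent)}"
                )
            return (DISPERSAL, parent, gained)
    if (left == parent and right and not right & ~parent) or (
        right == parent and not left & ~parent and left
    ):
        return None  # subset sympatry
    raise ValueError(
        f"inconsistent corner states {areas.format_range(left)}, "
        f"{areas.format_range(right)} under parent {areas.format_range(parent)}"
    )


def _anagenetic_steps(recon, branch_id: str, corner: int, child_state: int):
    """Yield (source, gained_or_lost_bitmask, is_gain) steps for one branch."""
    paths = recon.branch_paths or {}
    if branch_id in paths and len(paths[branch_id]) > 1:
        states = [s for _, s in paths[branch_id]]
        for a, b in zip(states, states[1:]):
            diff = a ^ b
            if diff == 0:
                continue  # path endpoints repeat the last jump's state
            yield a, diff, bool(b & diff)
        return
    state = corner
    gains = child_state & ~corner
    losses = corner & ~child_state
    for bit in _bits(gains):
        yield state, 1 << bit, True
        state |= 1 << bit
    for bit in _bits(losses):
        yield state, 1 << bit, False
        state &= ~(1 << bit)


def extract_events(recon: AncestralReconstruction, areas: AreaSet) -> list[BiogeoEvent]:
    """Deterministic dispersal/vicariance/extinction event list, oldest first."""
    tree = recon.tree
    events: list[BiogeoEvent] = []
    for node in tree.preorder():
        nid = tree.id_of(node)
        if node.is_leaf():
            continue
        parent_range = recon.node_map[nid]
        children = node.child_nodes()
        corners = [recon.corner_map[tree.id_of(c)] for c in children]
        if parent_range == 0 or all(c == 0 for c in corners):
            continue  # dead (null-range) lineage: no biogeography to read
        clado = _classify_cladogenesis(areas, parent_range, corners[0], corners[1])
        if clado is not None:
            etype, source, detail = clado
            if etype == VICARIANCE:
                left, right = detail
                events.append(
                    BiogeoEvent(
                        VICARIANCE,
                        tree.age(node),
                        vicariance_scope(areas, left, right),
                        source,
                        f"{areas.format_range(left)}|{areas.format_range(right)}",
                        nid,
                    )
                )
            else:
                bit = next(_bits(detail))
                events.append(
                    BiogeoEvent(
                        DISPERSAL,
                        tree.age(node),
                        dispersal_scope(areas, source, bit),
                        source,
                        areas.codes[bit],
                        nid,
                    )
                )
        for child, corner in zip(children, corners):
            cid = tree.id_of(child)
            if corner == 0:
                continue
            midpoint = 0.5 * (tree.age(node) + tree.age(child))
            for source, diff, is_gain in _anagenetic_steps(
                recon, cid, corner, recon.node_map[cid]
            ):
                bit = next(_bits(diff))
                if is_gain:
                    events.append(
                        BiogeoEvent(
                            DISPERSAL,
                            midpoint,
                            dispersal_scope(areas, source, bit),
                            source,
                            areas.codes[bit],
                            cid,
                        )
                    )
                else:
                    events.append(
                        BiogeoEvent(
                            EXTINCTION,
                            midpoint,
                            EXTINCTION_SCOPE,
                            source,
                            areas.codes[bit],
                            cid,
                        )
                    )
    events.sort(key=lambda ev: (-ev.time, ev.branch_id, ev.event_type, ev.detail))
    return events


def events_to_frame(events: Sequence[BiogeoEvent], areas: AreaSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time_ma": ev.time,
                "type": ev.event_type,
                "scope": ev.scope,
                "source_range": areas.format_range(ev.source),
                "detail": ev.detail,
                "branch_id": ev.branch_id,
            }
            for ev in events
        ],
        columns=["time_ma", "type", "scope", "source_range", "detail", "branch_id"],
    )


# -- event density ----------------------------------------------------------


@dataclass(frozen=True)
class EventDensityCurve:
    """Gaussian kernel density of event times, reflected at age 0.

    The curve is scaled to integrate to the event count over ages [0, inf);
    reflection at the present keeps mass from leaking to negative ages.
    """

    event_times: np.ndarray
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    event_type: str = ""

    def evaluate(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if self.event_times.size == 0:
            return np.zeros_like(ages)
        h = self.bandwidth
        t = self.event_times[:, None]
        z = (ages[None, :] - t) / h
        zr = (ages[None, :] + t) / h
        dens = (np.exp(-0.5 * z**2) + np.exp(-0.5 * zr**2)).sum(axis=0)
        return dens / (h * sqrt(2 * pi))

    def integral(self) -> float:
        if self.grid.size < 2:
            return 0.0
        return float(np.trapezoid(self.density, self.grid))

    @property
    def count(self) -> int:
        return int(self.event_times.size)


def event_density(
    events: Sequence[BiogeoEvent],
    bandwidth: float = 2.0,
    grid_step: float = 0.1,
    event_type: str | None = None,
) -> EventDensityCurve:
    """Event-density curve (events/Ma) for one event type (or all)."""
    if bandwidth <= 0 or grid_step <= 0:
        raise ValueError("bandwidth and grid_step must be positive")
    sel = [ev for ev in events if event_type is None or ev.event_type == event_type]
    times = np.asarray(sorted(ev.time for ev in sel), dtype=float)
    if times.size == 0:
        return EventDensityCurve(
            times, bandwidth, np.array([]), np.array([]), event_type or "all"
        )
    hi = times.max() + 5 * bandwidth
    grid = np.arange(0.0, hi + grid_step, grid_step)
    curve = EventDensityCurve(times, bandwidth, grid, np.array([]), event_type or "all")
    density = curve.evaluate(grid)
    return EventDensityCurve(times, bandwidth, grid, density, event_type or "all")


# -- period summaries -------------------------------------------------------


def period_summary(events: Sequence[BiogeoEvent], periods) -> pd.DataFrame:
    """Contingency table period x {dispersal, vicariance} x {scope}.

    ``periods`` is a sequence of objects with ``label``, ``older`` and
    ``younger`` age bounds (see :func:`epochdec.paleoclimate.segment_periods`);
    they must be contiguous and non-overlapping, oldest first.  The oldest
    period is treated as unbounded above so that the root-age event is counted.
    An event at exactly an interior boundary belongs to the younger period.
    """
    periods = list(periods)
    if not periods:
        raise ValueError("no periods given")
    for p1, p2 in zip(periods, periods[1:]):
        if p2.older > p1.younger + 1e-9:
            raise ValueError(f"overlapping periods: {p1.label!r} and {p2.label!r}")
        if p2.older < p1.younger - 1e-9:
            raise ValueError(f"gap between periods {p1.label!r} and {p2.label!r}")

    def locate(t: float) -> str:
        for i, p in enumerate(periods):
            lower_ok = t > p.younger or (i == len(periods) - 1 and t >= 0)
            if lower_ok and (i == 0 or t <= p.older):
                return p.label
        raise ValueError(f"event time {t} outside all periods")

    scopes = (INTERCONTINENTAL, ADJACENT)
    cols = pd.MultiIndex.from_product(
        [(DISPERSAL, VICARIANCE), scopes], names=["type", "scope"]
    )
    table = pd.DataFrame(0, index=[p.label for p in periods], columns=cols)
    table.index.name = "period"
    for ev in events:
        if ev.event_type == EXTINCTION:
            continue
        table.loc[locate(ev.time), (ev.event_type, ev.scope)] += 1
    return table
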
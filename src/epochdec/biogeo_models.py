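"""Epoch-stratified range-evolution models: DEC, BAYAREALIKE, and +J variants.

Anagenesis
    A continuous-time Markov chain over range states.  From range R, area b
    (not in R) is gained at rate ``d * sum_{a in R} m[a][b]`` where ``m`` is the
    dispersal multiplier matrix of the epoch; each area of R is lost at rate
    ``e``; the null range is absorbing.  Both model families share this process;
    they differ only at cladogenesis.

Cladogenesis
    DEC: a single-area parent is copied to both daughters; a wider parent
    either undergoes subset sympatry (one daughter keeps the full range, the
    other a single constituent area) or vicariance (a single area splits from
    its complement), every ordered outcome with unit weight.  BAYAREALIKE:
    the parent range is copied to both daughters.  +J adds founder outcomes in
    which one daughter jumps to a single area outside the parent, each with
    weight ``j``; founder targets must have a positive incoming multiplier in
    the epoch containing the node's age.  Weights are normalized per parent.

Likelihood
    Felsenstein pruning with branch propagators composed across epoch
    boundaries (piecewise-constant rate matrices, matrix exponentials applied
    chronologically) and cladogenetic mixing at every internal node including
    the root; the root state is summed under a configurable prior (default:
    uniform over non-null states).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .chronogram import Chronogram
from .range_space import StateSpace, _bits

__all__ = [
    "EpochSchedule",
    "BiogeoModel",
    "FitResult",
    "build_Q",
    "branch_transition",
    "cladogenesis_distribution",
    "prune_likelihood",
    "PruningEngine",
    "fit_ml",
    "aicc",
    "compare_models",
]

FAMILIES = ("DEC", "BAYAREALIKE")


@dataclass(frozen=True)
class EpochSchedule:
    """Piecewise-constant dispersal multipliers over age slices.

    ``boundaries`` are slice limits in Ma, strictly decreasing (e.g. ``(30, 5)``
    for slices >30 Ma, 30-5 Ma, and 5-0 Ma); ``multipliers`` holds one matrix
    per slice, oldest first, with ``multipliers[k][a, b]`` scaling the gain of
    area ``b`` from source area ``a``.  An age exactly on a boundary belongs to
    the younger slice.
    """

    boundaries: tuple[float, ...]
    multipliers: tuple[np.ndarray, ...]

    def __post_init__(self):
        bounds = tuple(float(b) for b in self.boundaries)
        mats = tuple(np.asarray(m, dtype=float) for m in self.multipliers)
        object.__setattr__(self, "boundaries", bounds)
        object.__setattr__(self, "multipliers", mats)
        if any(b <= 0 for b in bounds) or any(
            b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])
        ):
            raise ValueError(f"boundaries must be strictly decreasing and > 0: {bounds}")
        if len(mats) != len(bounds) + 1:
            raise ValueError(
                f"need {len(bounds) + 1} multiplier matrices for {len(bounds)} "
                f"boundaries, got {len(mats)}"
            )
        n = mats[0].shape[0]
        for m in mats:
            if m.shape != (n, n):
                raise ValueError("all multiplier matrices must share one square shape")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("multipliers must lie in [0, 1]")

    @classmethod
    def single(cls, matrix: np.ndarray) -> "EpochSchedule":
        return cls((), (np.asarray(matrix, dtype=float),))

    @classmethod
    def uniform(cls, n_areas: int) -> "EpochSchedule":
        return cls.single(np.ones((n_areas, n_areas)))

    @property
    def n_epochs(self) -> int:
        return len(self.multipliers)

    def epoch_index(self, age: float) -> int:
        for k, b in enumerate(self.boundaries):
            if age > b:
                return k
        return len(self.boundaries)

    def matrix_at(self, age: float) -> np.ndarray:
        return self.multipliers[self.epoch_index(age)]

    def segments(self, start_age: float, end_age: float):
        """Cut (start_age, end_age) at epoch boundaries.

        Yields ``(epoch_index, duration)`` chronologically (oldest first).
        """
        if start_age < end_age:
            raise ValueError(f"start_age {start_age} < end_age {end_age}")
        cuts = [start_age] + [
            b for b in self.boundaries if end_age < b < start_age
        ] + [end_age]
        for hi, lo in zip(cuts, cuts[1:]):
            yield self.epoch_index(0.5 * (hi + lo)), hi - lo


@dataclass(frozen=True)
class BiogeoModel:
    """Range-evolution model parameters.

    d : per-area-pair base dispersal (area gain) rate, events/Ma
    e : per-area extinction (area loss) rate, events/Ma
    j : founder-event weight; 0 disables the +J cladogenetic outcome
    """

    family: str
    d: float
    e: float
    j: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        if self.d < 0 or self.e < 0 or self.j < 0:
            raise ValueError(f"rates must be non-negative: d={self.d}, e={self.e}, j={self.j}")

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.j > 0 else "")


def build_Q(space: StateSpace, model: BiogeoModel, multipliers: np.ndarray) -> np.ndarray:
    """Anagenetic rate matrix over the state space for one epoch's multipliers."""
    m = np.asarray(multipliers, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("multipliers must lie in [0, 1]")
    S = len(space)
    Q = np.zeros((S, S))
    for i, R in enumerate(space.states):
        if R == 0:
            continue  # null range is absorbing
        members = list(_bits(R))
        if len(members) < space.max_range_size:
            for b in range(space.n_areas):
                if R >> b & 1:
                    continue
                rate = model.d * sum(m[a, b] for a in members)
                if rate > 0:
                    Q[i, space.index_of(R | (1 << b))] += rate
        if model.e > 0:
            for a in members:
                Q[i, space.index_of(R & ~(1 << a))] += model.e
        Q[i, i] = -Q[i].sum()
    return Q


def branch_transition(
    space: StateSpace,
    model: BiogeoModel,
    epochs: EpochSchedule,
    start_age: float,
    end_age: float,
) -> np.ndarray:
    """Transition probability matrix along a branch from ``start_age`` down to ``end_age``.

    The branch is cut at every epoch boundary it crosses and the per-segment
    matrix exponentials are composed in chronological order; rows index the
    state at the older end.
    """
    if not start_age > end_age >= 0:
        raise ValueError(f"need start_age > end_age >= 0, got {start_age}, {end_age}")
    P = np.eye(len(space))
    for k, dt in epochs.segments(start_age, end_age):
        P = P @ scipy.linalg.expm(build_Q(space, model, epochs.multipliers[k]) * dt)
    return P


# -- cladogenesis -----------------------------------------------------------


def _clado_entries(space: StateSpace, family: str, with_founder: bool,
                   multipliers: np.ndarray | None):
    """Unnormalized cladogenetic outcome table.

    Returns parallel lists (parent_idx, left_idx, right_idx, is_founder); base
    outcomes carry unit weight, founder outcomes carry weight j (applied later).
    Outcome order is deterministic: parents ascending, then (left, right) index.
    """
    p_idx, l_idx, r_idx, founder = [], [], [], []
    for i, P in enumerate(space.states):
        if P == 0:
            continue
        outcomes: dict[tuple[int, int], bool] = {}
        if family == "BAYAREALIKE" or P.bit_count() == 1:
            outcomes[(i, i)] = False
        else:
            for a in _bits(P):
                s = space.index_of(1 << a)
                comp = space.index_of(P & ~(1 << a))
                # subset sympatry, both daughter orders
                outcomes[(i, s)] = False
                outcomes[(s, i)] = False
                # vicariance: one daughter a single area, the other its complement
                outcomes[(s, comp)] = False
                outcomes[(comp, s)] = False
        if with_founder:
            for b in range(space.n_areas):
                if P >> b & 1:
                    continue
                if multipliers is not None:
                    reachable = any(multipliers[a, b] > 0 for a in _bits(P))
                    if not reachable:
                        continue
                t = space.index_of(1 << b)
                for pair in ((i, t), (t, i)):
                    if pair not in outcomes:
                        outcomes[pair] = True
        for (l, r) in sorted(outcomes):
            p_idx.append(i)
            l_idx.append(l)
            r_idx.append(r)
            founder.append(outcomes[(l, r)])
    return (
        np.asarray(p_idx, dtype=np.intp),
        np.asarray(l_idx, dtype=np.intp),
        np.asarray(r_idx, dtype=np.intp),
        np.asarray(founder, dtype=bool),
    )


def _clado_weights(p_idx, founder, j: float, n_states: int):
    """Per-outcome normalized weights for founder weight ``j`` (dropping j=0 founders)."""
    w = np.where(founder, j, 1.0)
    keep = w > 0
    w = w[keep]
    p = p_idx[keep]
    totals = np.zeros(n_states)
    np.add.at(totals, p, w)
    return keep, w / totals[p]


def cladogenesis_distribution(
    space: StateSpace,
    model: BiogeoModel,
    parent: int,
    multipliers: np.ndarray | None = None,
) -> dict[tuple[int, int], float]:
    """Probability distribution over ordered daughter-range pairs at a node.

    Keys are ``(left_mask, right_mask)`` bitmask pairs.  ``multipliers`` (the
    epoch matrix at the node's age) gates founder targets when ``model.j > 0``.
    """
    if parent == 0:
        raise ValueError("cladogenesis from the null range is undefined")
    i = space.index_of(parent)
    p_idx, l_idx, r_idx, founder = _clado_entries(
        space, model.family, model.j > 0, multipliers
    )
    keep, w = _clado_weights(p_idx, founder, model.j, len(space))
    p, l, r = p_idx[keep], l_idx[keep], r_idx[keep]
    sel = p == i
    return {
        (space.state_at(li), space.state_at(ri)): wi
        for li, ri, wi in zip(l[sel], r[sel], w[sel])
    }


# -- pruning engine ---------------------------------------------------------


class _EpochPropagator:
    """expm(Q t) @ v applied via eigendecomposition, with an expm fallback."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.ok = False
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # near-defective V is handled below
                lam, V = scipy.linalg.eig(Q)
                if np.linalg.cond(V) < 1e12:
                    Vinv = scipy.linalg.inv(V)
                    scale = max(1.0, float(np.abs(Q).max()))
                    if np.abs((V * lam) @ Vinv - Q).max() < 1e-10 * scale:
                        self.lam, self.V, self.Vinv = lam, V, Vinv
                        self.ok = True
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            pass

    def apply(self, v: np.ndarray, dt: float) -> np.ndarray:
        if dt <= 0:
            return v
        if self.ok:
            out = (self.V @ (np.exp(self.lam * dt) * (self.Vinv @ v))).real
        else:
            out = scipy.linalg.expm(self.Q * dt) @ v
        return np.clip(out, 0.0, None)

    def apply_T(self, v: np.ndarray, dt: float) -> np.ndarray:
        """Transpose propagation, expm(Q t).T @ v (for the outside pass)."""
        if dt <= 0:
            return v
        if self.ok:
            out = (self.Vinv.T @ (np.exp(self.lam * dt) * (self.V.T @ v))).real
        else:
            out = scipy.linalg.expm(self.Q * dt).T @ v
        return np.clip(out, 0.0, None)


class PruningEngine:
    """Shared machinery for likelihood evaluation and marginal reconstruction.

    Construction validates the tip range table against the tree and
    pre-computes the traversal, branch epoch segments, per-node epoch indices,
    and the cladogenetic outcome skeleton; :meth:`loglik` is then cheap enough
    to sit inside an optimizer loop.
    """

    def __init__(
        self,
        tree: Chronogram,
        tip_ranges: dict[str, int],
        space: StateSpace,
        epochs: EpochSchedule,
        family: str = "DEC",
        root_prior: np.ndarray | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if epochs.multipliers[0].shape[0] != space.n_areas:
            raise ValueError("epoch multiplier matrices do not match the area count")
        missing = [t for t in tree.tip_labels if t not in tip_ranges]
        if missing:
            raise ValueError(f"tips missing from the range table: {', '.join(sorted(missing))}")
        for t in tree.tip_labels:
            mask = tip_ranges[t]
            if mask == 0:
                raise ValueError(f"tip {t!r} has a null observed range")
            space.index_of(mask)  # validates membership / max_range_size
        self.tree = tree
        self.space = space
        self.epochs = epochs
        self.family = family
        S = len(space)
        if root_prior is None:
            root_prior = np.ones(S) / (S - 1)
            root_prior[0] = 0.0
        else:
            root_prior = np.asarray(root_prior, dtype=float)
            if root_prior.shape != (S,) or np.any(root_prior < 0):
                raise ValueError("root prior must be a non-negative vector over states")
            root_prior = root_prior / root_prior.sum()
        self.root_prior = root_prior

        self.nodes = list(tree.postorder())
        self.node_ids = [tree.id_of(n) for n in self.nodes]
        self._order = {n: k for k, n in enumerate(self.nodes)}
        self.is_tip = [n.is_leaf() for n in self.nodes]
        self.tip_state = [
            space.index_of(tip_ranges[tree.id_of(n)]) if n.is_leaf() else -1
            for n in self.nodes
        ]
        self.node_epoch = [epochs.epoch_index(tree.age(n)) for n in self.nodes]
        # per node: list of (child order-index, segments young->old)
        self.children: list[list[tuple[int, list[tuple[int, float]]]]] = []
        for n in self.nodes:
            entry = []
            for c in n.child_nodes():
                segs = list(epochs.segments(tree.age(n), tree.age(c)))
                entry.append((self._order[c], segs[::-1]))
            self.children.append(entry)
        self.root_index = self._order[tree.root]
        # cladogenetic skeleton per epoch (founder reachability differs by epoch)
        self._clado = [
            _clado_entries(space, family, True, epochs.multipliers[k])
            for k in range(epochs.n_epochs)
        ]
        self.n_tips = tree.n_tips

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.tree.to_newick().encode())
        for k, i in zip(self.node_ids, self.tip_state):
            h.update(f"{k}={i};".encode())
        h.update(str(self.space.states).encode())
        return h.hexdigest()[:16]

    # -- core passes --------------------------------------------------------

    def _propagators(self, model: BiogeoModel) -> list[_EpochPropagator]:
        return [
            _EpochPropagator(build_Q(self.space, model, m))
            for m in self.epochs.multipliers
        ]

    def _weights(self, model: BiogeoModel):
        """Normalized cladogenetic (p, l, r, w) arrays per epoch for this model."""
        out = []
        for p_idx, l_idx, r_idx, founder in self._clado:
            keep, w = _clado_weights(p_idx, founder, model.j, len(self.space))
            out.append((p_idx[keep], l_idx[keep], r_idx[keep], w))
        return out

    def _inside(self, model: BiogeoModel, keep_messages: bool = False):
        props = self._propagators(model)
        tables = self._weights(model)
        S = len(self.space)
        D = [None] * len(self.nodes)
        U = [None] * len(self.nodes) if keep_messages else None
        log_scale = 0.0
        for k, node in enumerate(self.nodes):
            if self.is_tip[k]:
                v = np.zeros(S)
                v[self.tip_state[k]] = 1.0
                D[k] = v
                continue
            msgs = []
            for ci, segs in self.children[k]:
                v = D[ci]
                for epoch_idx, dt in segs:
                    v = props[epoch_idx].apply(v, dt)
                msgs.append(v)
            uL, uR = msgs
            p, l, r, w = tables[self.node_epoch[k]]
            acc = np.bincount(p, weights=w * uL[l] * uR[r], minlength=S)
            top = acc.max()
            if not np.isfinite(top) or top <= 0.0:
                return None, -np.inf, props, tables, U
            acc /= top
            log_scale += math.log(top)
            D[k] = acc
            if keep_messages:
                U[k] = (uL, uR)
        return D, log_scale, props, tables, U

    def loglik(self, model: BiogeoModel, condition_on_survival: bool = False) -> float:
        """Log-likelihood of the observed tip ranges.

        With ``condition_on_survival`` the likelihood is divided by the
        probability that every sampled tip has a non-null range, correcting the
        survivorship bias introduced when dead (null-range) lineages are
        unobservable and pruned from the tree.
        """
        if model.family != self.family:
            raise ValueError(f"engine built for {self.family}, got {model.family}")
        D, log_scale, *_ = self._inside(model)
        if D is None:
            return -np.inf
        rootP = float(self.root_prior @ D[self.root_index])
        if rootP <= 0.0 or not np.isfinite(rootP):
            raise ValueError(
                "non-finite likelihood at the root; check that tip ranges are "
                "reachable under the model and epoch constraints"
            )
        lnl = math.log(rootP) + log_scale
        if condition_on_survival:
            lnl -= self.survival_loglik(model)
        return lnl

    def survival_loglik(self, model: BiogeoModel) -> float:
        """log P(every sampled tip is non-null): pruning with all-ones tip partials."""
        props = self._propagators(model)
        tables = self._weights(model)
        S = len(self.space)
        ones = np.zeros(S)
        ones[1:] = 1.0
        D: list[np.ndarray | None] = [None] * len(self.nodes)
        log_scale = 0.0
        for k in range(len(self.nodes)):
            if self.is_tip[k]:
                D[k] = ones
                continue
            msgs = []
            for ci, segs in self.children[k]:
                v = D[ci]
                for epoch_idx, dt in segs:
                    v = props[epoch_idx].apply(v, dt)
                msgs.append(v)
            p, l, r, w = tables[self.node_epoch[k]]
            acc = np.bincount(p, weights=w * msgs[0][l] * msgs[1][r], minlength=S)
            top = acc.max()
            if not np.isfinite(top) or top <= 0.0:
                return -np.inf
            acc /= top
            log_scale += math.log(top)
            D[k] = acc
        return math.log(float(self.root_prior @ D[self.root_index])) + log_scale

    def reconstruct(self, model: BiogeoModel):
        """Inside-outside marginal state probabilities and MAP corner states.

        Returns ``(marginals, node_map, corner_map)`` keyed by node id; the
        corner map is keyed by the daughter's node id and holds its range
        immediately after cladogenesis at the parent, chosen as the jointly
        most probable outcome conditional on the parent's MAP state.
        """
        D, log_scale, props, tables, U = self._inside(model, keep_messages=True)
        if D is None:
            raise ValueError("data have zero likelihood under this model")
        S = len(self.space)
        O = [None] * len(self.nodes)
        O[self.root_index] = self.root_prior.copy()
        marginals: dict[str, np.ndarray] = {}
        node_map: dict[str, int] = {}
        corner_map: dict[str, int] = {}
        for k in reversed(range(len(self.nodes))):  # preorder over postorder list
            node_id = self.node_ids[k]
            post = O[k] * D[k]
            tot = post.sum()
            if tot <= 0 or not np.isfinite(tot):
                raise ValueError(f"non-finite marginal at node {node_id!r}")
            post /= tot
            marginals[node_id] = post
            node_map[node_id] = self.space.state_at(int(np.argmax(post)))
            if self.is_tip[k]:
                continue
            (ciL, segsL), (ciR, segsR) = self.children[k]
            uL, uR = U[k]
            p, l, r, w = tables[self.node_epoch[k]]
            # outside at each daughter corner
            ocL = np.bincount(l, weights=O[k][p] * w * uR[r], minlength=S)
            ocR = np.bincount(r, weights=O[k][p] * w * uL[l], minlength=S)
            for ci, segs, oc in ((ciL, segsL, ocL), (ciR, segsR, ocR)):
                v = oc
                for epoch_idx, dt in reversed(segs):  # old -> young, transposed
                    v = props[epoch_idx].apply_T(v, dt)
                top = v.max()
                O[ci] = v / top if top > 0 else v
            # MAP corner pair conditional on the parent's MAP state
            i_map = self.space.index_of(node_map[node_id])
            sel = p == i_map
            score = w[sel] * uL[l[sel]] * uR[r[sel]]
            best = int(np.argmax(score))  # first max = smallest (l, r) index pair
            corner_map[self.node_ids[ciL]] = self.space.state_at(int(l[sel][best]))
            corner_map[self.node_ids[ciR]] = self.space.state_at(int(r[sel][best]))
        return marginals, node_map, corner_map


def prune_likelihood(
    tree: Chronogram,
    tip_ranges: dict[str, int],
    space: StateSpace,
    model: BiogeoModel,
    epochs: EpochSchedule,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of observed tip ranges under the model (pruning algorithm)."""
    engine = PruningEngine(tree, tip_ranges, space, epochs, model.family, root_prior)
    return engine.loglik(model)


# -- fitting and model comparison ------------------------------------------


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * lnL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model family on one data set."""

    model: BiogeoModel
    lnL: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_starts: int
    with_j: bool
    data_fingerprint: str
    start_values: tuple = field(default=(), repr=False)

    @property
    def name(self) -> str:
        return self.model.family + ("+J" if self.with_j else "")

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "family": self.model.family,
            "d": self.model.d,
            "e": self.model.e,
            "j": self.model.j,
            "lnL": self.lnL,
            "k": self.k,
            "n": self.n,
            "AICc": self.aicc,
            "converged": self.converged,
        }


_LOG_BOUNDS = (math.log(1e-9), math.log(10.0))
_J_BOUNDS = (0.0, 100.0)


def fit_ml(
    tree: Chronogram,
    tip_ranges: dict[str, int],
    space: StateSpace,
    family: str,
    epochs: EpochSchedule,
    with_j: bool = False,
    seed: int = 0,
    n_starts: int = 5,
    root_prior: np.ndarray | None = None,
    j_fixed: float | None = None,
    condition_on_survival: bool = False,
) -> FitResult:
    """Fit (d, e[, j]) by bounded multi-start maximum likelihood.

    d and e are optimized on a log scale within [1e-9, 10]; j (when free) on a
    linear scale within [0, 100].  Start points are deterministic given
    ``seed``.  ``j_fixed`` pins the founder weight (e.g. to 0) without making
    it a free parameter.  ``condition_on_survival`` maximizes the likelihood
    conditioned on all sampled tips being non-null (see
    :meth:`PruningEngine.loglik`).
    """
    from scipy.optimize import minimize

    engine = PruningEngine(tree, tip_ranges, space, epochs, family, root_prior)
    n = engine.n_tips
    free_j = with_j and j_fixed is None
    k = 3 if free_j else 2
    if n <= k + 1:
        raise ValueError(f"too few tips (n={n}) for a {k}-parameter fit")

    def unpack(theta):
        d, e = math.exp(theta[0]), math.exp(theta[1])
        if free_j:
            j = theta[2]
        else:
            j = (j_fixed or 0.0) if with_j else 0.0
        return BiogeoModel(family, d, e, j)

    def objective(theta):
        try:
            val = engine.loglik(unpack(theta), condition_on_survival=condition_on_survival)
        except (ValueError, FloatingPointError):
            return 1e12
        return -val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    starts = [[math.log(0.01), math.log(0.01)] + ([0.1] if free_j else [])]
    while len(starts) < n_starts:
        s = [
            float(rng.uniform(math.log(1e-4), math.log(1.0))),
            float(rng.uniform(math.log(1e-4), math.log(1.0))),
        ]
        if free_j:
            s.append(float(rng.uniform(0.0, 3.0)))
        starts.append(s)
    bounds = [_LOG_BOUNDS, _LOG_BOUNDS] + ([_J_BOUNDS] if free_j else [])

    best = None
    any_success = False
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B", bounds=bounds)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    model = unpack(best.x)
    lnL = -float(best.fun)
    return FitResult(
        model=model,
        lnL=lnL,
        k=k,
        n=n,
        aicc=aicc(lnL, k, n),
        converged=any_success and lnL > -1e11,
        n_starts=len(starts),
        with_j=with_j,
        data_fingerprint=engine.fingerprint(),
        start_values=tuple(tuple(s) for s in starts),
    )


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the same data by AICc (ties broken toward fewer parameters)."""
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were made on different data (fingerprint mismatch)")
    rows = [f.to_dict() for f in fits]
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "k"], kind="stable", ignore_index=True
    )
    df["delta_AICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["best"] = [i == 0 for i in range(len(df))]
    return df
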
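"""Independent brute-force oracles used only by the test suite.

Everything here is written directly from the model definitions with plain
loops, dicts, and scipy.linalg.expm -- no code shared with the package's
pruning engine -- so likelihoods and marginals can be checked by exhaustive
enumeration over all internal-state and cladogenetic-outcome assignments on
tiny instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.linalg


def bits(mask):
    return [i for i in range(mask.bit_length()) if mask >> i & 1]


def oracle_Q(space, model, mult):
    """Gain/loss rate matrix built from the definition with dict loops."""
    S = len(space)
    Q = np.zeros((S, S))
    for i, R in enumerate(space.states):
        if R == 0:
            continue
        if len(bits(R)) < space.max_range_size:
            for b in range(space.n_areas):
                if R >> b & 1:
                    continue
                rate = model.d * sum(mult[a][b] for a in bits(R))
                Q[i, space.index_of(R | 1 << b)] += rate
        for a in bits(R):
            Q[i, space.index_of(R & ~(1 << a))] += model.e
    for i in range(S):
        Q[i, i] = -Q[i].sum()
    return Q


def oracle_branch_P(space, model, epochs, start_age, end_age, n_slices=None):
    """Piecewise expm product; optionally over a fine uniform slicing."""
    if n_slices:
        ages = np.linspace(start_age, end_age, n_slices + 1)
        P = np.eye(len(space))
        for hi, lo in zip(ages, ages[1:]):
            mid = 0.5 * (hi + lo)
            Q = oracle_Q(space, model, epochs.matrix_at(mid))
            P = P @ scipy.linalg.expm(Q * (hi - lo))
        return P
    cuts = [start_age] + [b for b in epochs.boundaries if end_age < b < start_age] + [end_age]
    P = np.eye(len(space))
    for hi, lo in zip(cuts, cuts[1:]):
        Q = oracle_Q(space, model, epochs.matrix_at(0.5 * (hi + lo)))
        P = P @ scipy.linalg.expm(Q * (hi - lo))
    return P


def oracle_clado(space, model, mult):
    """parent mask -> {(left mask, right mask): probability}, from the definition."""
    out = {}
    for P in space.states:
        if P == 0:
            continue
        table = {}
        if model.family == "BAYAREALIKE" or len(bits(P)) == 1:
            table[(P, P)] = 1.0
        else:
            for a in bits(P):
                s, comp = 1 << a, P & ~(1 << a)
                for pair in ((P, s), (s, P), (s, comp), (comp, s)):
                    table[pair] = 1.0
        if model.j > 0:
            for b in range(space.n_areas):
                if P >> b & 1:
                    continue
                if not any(mult[a][b] > 0 for a in bits(P)):
                    continue
                for pair in ((P, 1 << b), (1 << b, P)):
                    table.setdefault(pair, model.j)
        tot = sum(table.values())
        out[P] = {k: v / tot for k, v in table.items()}
    return out


def oracle_loglik(tree, tip_ranges, space, model, epochs, root_prior=None):
    """Exhaustive-enumeration likelihood: sum over every assignment of states to
    internal nodes and cladogenetic outcomes, times branch transition factors."""
    S = len(space)
    if root_prior is None:
        root_prior = np.full(S, 1.0 / (S - 1))
        root_prior[0] = 0.0
    internal = [n for n in tree.preorder() if not n.is_leaf()]
    P_edges = {}
    for n in tree.preorder():
        if n.parent_node is not None:
            P_edges[n] = oracle_branch_P(
                space, model, epochs, tree.age(n.parent_node), tree.age(n)
            )
    clado_by_epoch = [
        oracle_clado(space, model, m) for m in epochs.multipliers
    ]
    options = []
    for n in internal:
        clado = clado_by_epoch[epochs.epoch_index(tree.age(n))]
        opts = []
        for state, table in clado.items():
            for (l, r), w in table.items():
                opts.append((state, l, r, w))
        options.append(opts)

    total = 0.0
    for combo in itertools.product(*options):
        assign = dict(zip(internal, combo))
        root_state = assign[internal[0]][0]
        prob = root_prior[space.index_of(root_state)]
        if prob == 0:
            continue
        ok = True
        for n, (state, l, r, w) in assign.items():
            prob *= w
            for child, corner in zip(n.child_nodes(), (l, r)):
                if child.is_leaf():
                    child_state = tip_ranges[tree.id_of(child)]
                else:
                    child_state = assign[child][0]
                p = P_edges[child][space.index_of(corner), space.index_of(child_state)]
                prob *= p
                if prob == 0.0:
                    ok = False
                    break
            if not ok:
                break
        total += prob
    return math.log(total) if total > 0 else -math.inf


def oracle_marginals(tree, tip_ranges, space, model, epochs, root_prior=None):
    """Per-node marginal state posteriors by the same exhaustive enumeration."""
    S = len(space)
    if root_prior is None:
        root_prior = np.full(S, 1.0 / (S - 1))
        root_prior[0] = 0.0
    internal = [n for n in tree.preorder() if not n.is_leaf()]
    P_edges = {
        n: oracle_branch_P(space, model, epochs, tree.age(n.parent_node), tree.age(n))
        for n in tree.preorder()
        if n.parent_node is not None
    }
    clado_by_epoch = [oracle_clado(space, model, m) for m in epochs.multipliers]
    options = []
    for n in internal:
        clado = clado_by_epoch[epochs.epoch_index(tree.age(n))]
        options.append(
            [(s, l, r, w) for s, tab in clado.items() for (l, r), w in tab.items()]
        )
    sums = {tree.id_of(n): np.zeros(S) for n in internal}
    total = 0.0
    for combo in itertools.product(*options):
        assign = dict(zip(internal, combo))
        prob = root_prior[space.index_of(assign[internal[0]][0])]
        if prob == 0:
            continue
        for n, (state, l, r, w) in assign.items():
            prob *= w
            for child, corner in zip(n.child_nodes(), (l, r)):
                child_state = (
                    tip_ranges[tree.id_of(child)]
                    if child.is_leaf()
                    else assign[child][0]
                )
                prob *= P_edges[child][
                    space.index_of(corner), space.index_of(child_state)
                ]
        if prob == 0.0:
            continue
        total += prob
        for n, (state, *_rest) in assign.items():
            sums[tree.id_of(n)][space.index_of(state)] += prob
    return {k: v / total for k, v in sums.items()}, math.log(total)
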
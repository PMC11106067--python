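"""Rate matrices, cladogenesis, pruning likelihood, fitting, and AICc ranking."""

import math

import numpy as np
import pytest
import scipy.linalg

import epochdec as ed
from _oracle import oracle_loglik

from conftest import random_instance


@pytest.fixture(scope="module")
def abc_space():
    return ed.StateSpace(ed.AreaSet(("A", "B", "C")))


class TestBuildQ:
    def test_two_area_rates(self, space2):
        model = ed.BiogeoModel("DEC", 0.1, 0.05)
        Q = ed.build_Q(space2, model, np.ones((2, 2)))
        iA, iAB, iNull = space2.index_of(1), space2.index_of(3), 0
        assert Q[iA, iAB] == pytest.approx(0.1)
        assert Q[iA, iNull] == pytest.approx(0.05)
        assert Q[iAB, iA] == pytest.approx(0.05)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert np.all(Q[0] == 0.0)  # null range absorbing

    def test_zero_multiplier_closes_corridor(self, space2):
        m = np.ones((2, 2))
        m[0, 1] = 0.0
        Q = ed.build_Q(space2, ed.BiogeoModel("DEC", 0.1, 0.0), m)
        assert Q[space2.index_of(1), space2.index_of(3)] == 0.0

    def test_gain_rate_sums_over_source_areas(self, abc_space):
        m = np.ones((3, 3))
        m[0, 2], m[1, 2] = 1.0, 0.5
        Q = ed.build_Q(abc_space, ed.BiogeoModel("DEC", 0.02, 0.0), m)
        assert Q[abc_space.index_of(0b011), abc_space.index_of(0b111)] == pytest.approx(0.03)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ed.BiogeoModel("DEC", -0.1, 0.05)

    def test_max_range_size_caps_gains(self):
        space = ed.StateSpace(ed.AreaSet(("A", "B", "C")), max_range_size=2)
        Q = ed.build_Q(space, ed.BiogeoModel("DEC", 0.1, 0.0), np.ones((3, 3)))
        assert np.all(Q[space.index_of(0b011)] <= 0.0)  # size-2 states cannot grow


class TestBranchTransition:
    def test_single_epoch_equals_expm(self, space2):
        model = ed.BiogeoModel("DEC", 0.1, 0.02)
        epochs = ed.EpochSchedule.uniform(2)
        P = ed.branch_transition(space2, model, epochs, 7.0, 3.0)
        Q = ed.build_Q(space2, model, epochs.multipliers[0])
        assert np.allclose(P, scipy.linalg.expm(Q * 4.0), atol=1e-12)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-9

    def test_identical_multipliers_collapse_epochs(self, space2):
        model = ed.BiogeoModel("DEC", 0.08, 0.03)
        m = np.full((2, 2), 0.7)
        multi = ed.EpochSchedule((30.0, 5.0), (m, m, m))
        single = ed.EpochSchedule.single(m)
        P1 = ed.branch_transition(space2, model, multi, 32.0, 2.0)
        P2 = ed.branch_transition(space2, model, single, 32.0, 2.0)
        assert np.allclose(P1, P2, atol=1e-12)

    def test_boundary_crossing_matches_fine_sliced_product(self, abc_space):
        from _oracle import oracle_branch_P

        r = np.random.default_rng(5)
        epochs = ed.EpochSchedule(
            (30.0,), (r.uniform(0.3, 1, (3, 3)), r.uniform(0.3, 1, (3, 3)))
        )
        model = ed.BiogeoModel("DEC", 0.15, 0.04)
        P = ed.branch_transition(abc_space, model, epochs, 32.0, 28.0)
        P_fine = oracle_branch_P(abc_space, model, epochs, 32.0, 28.0, n_slices=1000)
        assert np.abs(P - P_fine).max() < 1e-9

    def test_inverted_ages_rejected(self, space2):
        with pytest.raises(ValueError):
            ed.branch_transition(
                space2, ed.BiogeoModel("DEC", 0.1, 0.0), ed.EpochSchedule.uniform(2), 3.0, 7.0
            )


class TestCladogenesis:
    def test_single_area_parent_is_copied(self, space2):
        dist = ed.cladogenesis_distribution(space2, ed.BiogeoModel("DEC", 0.1, 0.0), 1)
        assert dist == {(1, 1): 1.0}

    def test_dec_two_area_parent_enumerates_both_daughter_orders(self, space2):
        # classic DEC: subset sympatry in both orders plus both vicariant
        # orders, six equally weighted ordered outcomes
        dist = ed.cladogenesis_distribution(space2, ed.BiogeoModel("DEC", 0.1, 0.0), 3)
        expected = {(3, 1), (1, 3), (3, 2), (2, 3), (1, 2), (2, 1)}
        assert set(dist) == expected
        assert all(p == pytest.approx(1 / 6) for p in dist.values())
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_bayarealike_copies_parent(self, space2):
        dist = ed.cladogenesis_distribution(
            space2, ed.BiogeoModel("BAYAREALIKE", 0.1, 0.0), 3
        )
        assert dist == {(3, 3): 1.0}

    def test_founder_targets_gated_by_multipliers(self, abc_space):
        model = ed.BiogeoModel("DEC", 0.1, 0.0, j=1.0)
        m = np.ones((3, 3))
        m[:, 2] = 0.0  # area C unreachable
        dist = ed.cladogenesis_distribution(abc_space, model, 1, multipliers=m)
        founder_targets = {l | r for l, r in dist} - {1, 3}
        assert 0b100 not in founder_targets  # no jump into C
        assert (1, 2) in dist and (2, 1) in dist  # jump into B allowed

    def test_null_parent_rejected(self, space2):
        with pytest.raises(ValueError):
            ed.cladogenesis_distribution(space2, ed.BiogeoModel("DEC", 0.1, 0.0), 0)


class TestPruneLikelihood:
    def test_frozen_chain_reduces_to_root_prior(self, space2):
        tree = ed.Chronogram.from_newick("(X:4,Y:4);")
        model = ed.BiogeoModel("DEC", 0.0, 0.0)
        lnl = ed.prune_likelihood(
            tree, {"X": 1, "Y": 1}, space2, model, ed.EpochSchedule.uniform(2)
        )
        assert lnl == pytest.approx(math.log(1 / 3))  # uniform over 3 non-null states

    @pytest.mark.parametrize("family", ["DEC", "BAYAREALIKE"])
    def test_zero_founder_weight_drops_founder_outcomes_exactly(self, family, space2):
        # j=0 founder outcomes are removed, not carried at zero weight, so the
        # +J computation degenerates to the base family bit for bit
        base = ed.cladogenesis_distribution(space2, ed.BiogeoModel(family, 0.1, 0.0, 0.0), 1)
        with_j = ed.cladogenesis_distribution(
            space2, ed.BiogeoModel(family, 0.1, 0.0, 1.0), 1, multipliers=np.ones((2, 2))
        )
        assert set(base) == {(1, 1)}
        assert (1, 2) in with_j and (2, 1) in with_j

    @pytest.mark.parametrize("seed", [2, 9, 23])
    def test_matches_exhaustive_enumeration(self, seed):
        tree, tips, space, model, epochs = random_instance(seed)
        lnl = ed.prune_likelihood(tree, tips, space, model, epochs)
        assert lnl == pytest.approx(oracle_loglik(tree, tips, space, model, epochs), abs=1e-8)

    def test_area_relabeling_invariance(self):
        r = np.random.default_rng(3)
        areas = ed.AreaSet(("A", "B", "C"), frozenset([frozenset(("A", "C"))]))
        space = ed.StateSpace(areas)
        tree = ed.simulate_tree(0.3, 0.0, 5, seed=4)
        model = ed.BiogeoModel("DEC", 0.1, 0.03, 0.5)
        m = r.uniform(0.2, 1.0, (3, 3))
        epochs = ed.EpochSchedule.single(m)
        tips = {l: int(r.integers(1, 8)) for l in tree.tip_labels}
        perm = [2, 0, 1]  # old index -> new index

        def pmask(mask):
            return sum(1 << perm[a] for a in range(3) if mask >> a & 1)

        areas_p = ed.AreaSet(
            tuple(np.array(["A", "B", "C"])[np.argsort(perm)]),
            frozenset([frozenset(("A", "C"))]),
        )
        m_p = np.empty_like(m)
        for a in range(3):
            for b in range(3):
                m_p[perm[a], perm[b]] = m[a, b]
        lnl = ed.prune_likelihood(tree, tips, space, model, epochs)
        lnl_p = ed.prune_likelihood(
            tree,
            {k: pmask(v) for k, v in tips.items()},
            ed.StateSpace(areas_p),
            model,
            ed.EpochSchedule.single(m_p),
        )
        assert lnl_p == pytest.approx(lnl, abs=1e-9)

    def test_missing_tip_listed_in_error(self, space2):
        tree = ed.Chronogram.from_newick("((X:1,Y:1):1,Z:2);")
        with pytest.raises(ValueError, match="Z"):
            ed.prune_likelihood(
                tree, {"X": 1, "Y": 2}, space2,
                ed.BiogeoModel("DEC", 0.1, 0.0), ed.EpochSchedule.uniform(2),
            )


class TestFitAndCompare:
    def test_aicc_formula_and_ranking(self):
        # k=2 at lnL -100 vs k=3 at -99 on n=54: the 2-parameter model wins
        assert ed.aicc(-100, 2, 54) == pytest.approx(204.2353, abs=1e-3)
        assert ed.aicc(-99, 3, 54) == pytest.approx(204.48, abs=1e-3)
        with pytest.raises(ValueError):
            ed.aicc(-10, 3, 4)

    def test_compare_models_orders_and_flags_best(self):
        f1 = _fit_stub("DEC", lnL=-100, k=2, n=54)
        f2 = _fit_stub("DEC+J", lnL=-99, k=3, n=54, with_j=True)
        table = ed.compare_models([f2, f1])
        assert list(table["model"]) == ["DEC", "DEC+J"]
        assert table["delta_AICc"].iloc[0] == 0.0
        assert bool(table["best"].iloc[0])

    def test_compare_single_fit_and_aicc_tie_break(self):
        single = ed.compare_models([_fit_stub("DEC", -100, 2, 54)])
        assert single["delta_AICc"].iloc[0] == 0.0
        # equal AICc: fewer parameters first
        lnl3 = -(ed.aicc(-100, 2, 54) - 2 * 3 - 2 * 3 * 4 / 50) / 2
        tie = ed.compare_models(
            [_fit_stub("DEC+J", lnl3, 3, 54, with_j=True), _fit_stub("DEC", -100, 2, 54)]
        )
        assert list(tie["model"]) == ["DEC", "DEC+J"]

    def test_compare_rejects_different_data(self):
        with pytest.raises(ValueError, match="fingerprint"):
            ed.compare_models(
                [_fit_stub("DEC", -10, 2, 54, fp="a"), _fit_stub("DEC", -11, 2, 54, fp="b")]
            )

    def test_fit_drives_d_to_lower_bound_on_static_data(self, space2):
        # every tip still carries the known root range: any d > 0 wastes
        # probability on ranges never observed, so the MLE sits at the bound
        tree = ed.simulate_tree(0.3, 0.0, 8, seed=2)
        tips = {l: 1 for l in tree.tip_labels}
        epochs = ed.EpochSchedule.uniform(2)
        prior = np.zeros(len(space2))
        prior[space2.index_of(1)] = 1.0
        fit = ed.fit_ml(tree, tips, space2, "BAYAREALIKE", epochs, seed=0, root_prior=prior)
        assert fit.model.d < 1e-6
        assert fit.converged
        assert fit.lnL == pytest.approx(0.0, abs=1e-4)  # frozen chain, prob ~1
        lnl_alt = ed.prune_likelihood(
            tree, tips, space2,
            ed.BiogeoModel("BAYAREALIKE", 0.1, fit.model.e), epochs, root_prior=prior,
        )
        assert fit.lnL >= lnl_alt


def _fit_stub(name, lnL, k, n, with_j=False, fp="same"):
    family = name.replace("+J", "")
    return ed.FitResult(
        model=ed.BiogeoModel(family, 0.01, 0.01, 0.1 if with_j else 0.0),
        lnL=lnL,
        k=k,
        n=n,
        aicc=ed.aicc(lnL, k, n),
        converged=True,
        n_starts=1,
        with_j=with_j,
        data_fingerprint=fp,
    )
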
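"""Marginal reconstruction, event extraction, densities, and period tables."""

import numpy as np
import pytest

import epochdec as ed
from epochdec.ancestral_events import (
    DISPERSAL,
    EXTINCTION,
    VICARIANCE,
    AncestralReconstruction,
    event_density,
    events_to_frame,
    extract_events,
    period_summary,
)
from epochdec.paleoclimate import Period
from _oracle import oracle_marginals
from conftest import random_instance


def _fit(model, n=4):
    return ed.FitResult(
        model=model, lnL=0.0, k=2, n=n, aicc=0.0, converged=True,
        n_starts=1, with_j=False, data_fingerprint="t",
    )


class TestMarginalRanges:
    def test_frozen_chain_gives_point_masses(self, space2):
        tree = ed.Chronogram.from_newick("((X:1,Y:1):1,Z:2);")
        model = ed.BiogeoModel("DEC", 0.0, 0.0)
        rec = ed.marginal_ranges(
            tree, {t: 1 for t in "XYZ"}, _fit(model, 3), space2, ed.EpochSchedule.uniform(2)
        )
        for nid, marg in rec.marginals.items():
            assert marg[space2.index_of(1)] == pytest.approx(1.0)
            assert rec.node_map[nid] == 1

    def test_cherry_root_map_is_union_for_small_e(self, space2):
        tree = ed.Chronogram.from_newick("(X:5,Y:5);")
        model = ed.BiogeoModel("DEC", 0.3, 0.001)
        tips = {"X": 1, "Y": 2}
        rec = ed.marginal_ranges(tree, tips, _fit(model, 2), space2, ed.EpochSchedule.uniform(2))
        root_id = tree.id_of(tree.root)
        assert rec.node_map[root_id] == 3  # {A,B}
        om, _ = oracle_marginals(tree, tips, space2, model, ed.EpochSchedule.uniform(2))
        assert np.allclose(rec.marginals[root_id], om[root_id], atol=1e-8)

    @pytest.mark.parametrize("seed", [12, 31])
    def test_marginals_match_enumeration(self, seed):
        tree, tips, space, model, epochs = random_instance(seed)
        rec = ed.marginal_ranges(tree, tips, _fit(model, len(tips)), space, epochs)
        om, _ = oracle_marginals(tree, tips, space, model, epochs)
        for nid, expected in om.items():
            assert np.allclose(rec.marginals[nid], expected, atol=1e-8)

    def test_marginals_sum_to_one_and_map_is_argmax(self):
        tree, tips, space, model, epochs = random_instance(44)
        rec = ed.marginal_ranges(tree, tips, _fit(model, len(tips)), space, epochs)
        for nid, marg in rec.marginals.items():
            assert marg.sum() == pytest.approx(1.0, abs=1e-9)
            assert rec.node_map[nid] == space.state_at(int(np.argmax(marg)))

    def test_refuses_unconverged_fit(self, space2):
        tree = ed.Chronogram.from_newick("(X:5,Y:5);")
        bad = ed.FitResult(
            model=ed.BiogeoModel("DEC", 0.1, 0.0), lnL=0, k=2, n=2, aicc=0,
            converged=False, n_starts=1, with_j=False, data_fingerprint="t",
        )
        with pytest.raises(ValueError, match="converged"):
            ed.marginal_ranges(tree, {"X": 1, "Y": 2}, bad, space2, ed.EpochSchedule.uniform(2))


def _recon(areas, tree, node_map, corner_map, paths=None):
    space = ed.StateSpace(areas)
    marginals = {}
    for nid, s in node_map.items():
        v = np.zeros(len(space))
        v[space.index_of(s)] = 1.0
        marginals[nid] = v
    return AncestralReconstruction(
        tree=tree, space=space, marginals=marginals, node_map=node_map,
        corner_map=corner_map, branch_paths=paths,
    )


class TestExtractEvents:
    def test_vicariant_node_yields_one_intercontinental_event(self, areas6):
        # ancestor spanning East Asia and Europe splits at 5 Ma
        tree = ed.Chronogram.from_newick("(X:5,Y:5);")
        root_id = tree.id_of(tree.root)
        ea, eu = areas6.mask("EA"), areas6.mask("EU")
        rec = _recon(
            areas6, tree,
            {root_id: ea | eu, "X": ea, "Y": eu},
            {"X": ea, "Y": eu},
        )
        events = extract_events(rec, areas6)
        assert len(events) == 1
        ev = events[0]
        assert (ev.event_type, ev.scope) == (VICARIANCE, "intercontinental")
        assert ev.time == pytest.approx(5.0)
        assert ev.detail == "EA|EU"

    def test_anagenetic_gain_at_branch_midpoint(self, areas6):
        # WNA corner gains EA along a 42->36 Ma branch: dispersal at 39 Ma
        tree = ed.Chronogram.from_newick("((Y:30,Z:36):6,X:42);")
        root_id = tree.id_of(tree.root)
        inner = [n for n in tree.preorder() if not n.is_leaf() and n is not tree.root][0]
        inner_id = tree.id_of(inner)
        assert tree.age(inner) == pytest.approx(36.0)
        wna, ea = areas6.mask("WNA"), areas6.mask("EA")
        rec = _recon(
            areas6, tree,
            {root_id: wna, inner_id: wna | ea, "X": wna, "Y": wna | ea, "Z": wna | ea},
            {inner_id: wna, "X": wna, "Y": wna | ea, "Z": wna | ea},
        )
        events = extract_events(rec, areas6)
        gains = [e for e in events if e.event_type == DISPERSAL]
        assert len(gains) == 1 and len(events) == 1
        assert gains[0].time == pytest.approx(39.0)
        assert gains[0].scope == "intercontinental"
        assert gains[0].detail == "EA"

    def test_no_change_gives_empty_list(self, areas6):
        tree = ed.Chronogram.from_newick("(X:5,Y:5);")
        wna = areas6.mask("WNA")
        rec = _recon(areas6, tree, {tree.id_of(tree.root): wna, "X": wna, "Y": wna},
                     {"X": wna, "Y": wna})
        assert extract_events(rec, areas6) == []

    def test_founder_corner_reads_as_dispersal_at_node_age(self, areas6):
        tree = ed.Chronogram.from_newick("(X:5,Y:5);")
        wna, ea = areas6.mask("WNA"), areas6.mask("EA")
        rec = _recon(areas6, tree, {tree.id_of(tree.root): wna, "X": wna, "Y": ea},
                     {"X": wna, "Y": ea})
        events = extract_events(rec, areas6)
        assert [e.event_type for e in events] == [DISPERSAL]
        assert events[0].time == pytest.approx(5.0)
        assert events[0].source == wna

    def test_losses_become_extinction_events(self, areas6):
        tree = ed.Chronogram.from_newick("(X:10,Y:10);")
        wna_ena = areas6.mask("WNA,ENA")
        wna = areas6.mask("WNA")
        rec = _recon(areas6, tree,
                     {tree.id_of(tree.root): wna_ena, "X": wna, "Y": wna_ena},
                     {"X": wna_ena, "Y": wna_ena})
        events = extract_events(rec, areas6)
        assert [e.event_type for e in events] == [EXTINCTION]
        assert events[0].scope == "n/a"
        assert events[0].time == pytest.approx(5.0)


class TestEventDensity:
    def test_single_event_peaks_at_its_time_and_integrates_to_one(self):
        ev = [_event(10.0)]
        c = event_density(ev, bandwidth=1.0, grid_step=0.05)
        assert c.grid[np.argmax(c.density)] == pytest.approx(10.0, abs=0.06)
        assert c.integral() == pytest.approx(1.0, abs=0.02)

    def test_clustered_events_peak_higher_than_spread(self):
        tight = event_density([_event(10.0), _event(10.1)], bandwidth=1.0, grid_step=0.05)
        loose = event_density([_event(10.0), _event(30.0)], bandwidth=1.0, grid_step=0.05)
        assert tight.density.max() > loose.density.max()

    def test_uniform_events_integral_matches_count(self):
        r = np.random.default_rng(8)
        events = [_event(float(t)) for t in r.uniform(0, 15, size=25)]
        c = event_density(events, bandwidth=1.5, grid_step=0.05)
        assert c.integral() == pytest.approx(25.0, rel=0.02)

    def test_empty_event_list_is_empty_curve_not_error(self):
        c = event_density([], bandwidth=1.0, grid_step=0.1, event_type=DISPERSAL)
        assert c.count == 0 and c.grid.size == 0

    def test_reflection_keeps_mass_above_zero_age(self):
        c = event_density([_event(0.3)], bandwidth=1.0, grid_step=0.02)
        assert c.integral() == pytest.approx(1.0, abs=0.02)


def _event(t, etype=DISPERSAL, scope="intercontinental", detail="EA"):
    from epochdec.ancestral_events import BiogeoEvent

    return BiogeoEvent(etype, t, scope if etype != EXTINCTION else "n/a", 1, detail, "b")


class TestPeriodSummary:
    def test_counts_events_into_periods(self):
        periods = [Period("Warm I", 52, 34), Period("Cold I", 34, 0)]
        events = [_event(36.0), _event(35.0), _event(10.0, VICARIANCE)]
        table = period_summary(events, periods)
        assert table.loc["Warm I", (DISPERSAL, "intercontinental")] == 2
        assert table.loc["Cold I", (VICARIANCE, "intercontinental")] == 1
        assert int(table.to_numpy().sum()) == 3

    def test_empty_events_gives_zero_table(self):
        table = period_summary([], [Period("all", 50, 0)])
        assert int(table.to_numpy().sum()) == 0

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            period_summary([], [Period("a", 50, 20), Period("b", 30, 0)])

    def test_simulated_log_matches_hand_tally(self, areas6, space6):
        ep = ed.EpochSchedule.uniform(6)
        tree = ed.simulate_tree(0.15, 0.0, 10, seed=3)
        hist = ed.simulate_ranges(
            tree, ed.BiogeoModel("DEC", 0.03, 0.01), ep, areas6.mask("WNA"), seed=9, space=space6
        )
        half = tree.root_age / 2
        periods = [Period("old", tree.root_age, half), Period("young", half, 0)]
        table = period_summary(hist.true_events, periods)
        expected = sum(
            1 for e in hist.true_events
            if e.event_type in (DISPERSAL, VICARIANCE)
        )
        assert int(table.to_numpy().sum()) == expected
        old = sum(
            1 for e in hist.true_events
            if e.event_type in (DISPERSAL, VICARIANCE) and e.time > half
        )
        assert int(table.loc["old"].sum()) == old


def test_events_frame_has_stable_columns(areas6):
    df = events_to_frame([_event(3.0)], areas6)
    assert list(df.columns) == ["time_ma", "type", "scope", "source_range", "detail", "branch_id"]
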
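"""Shared fixtures and random-instance generators for the suite."""

from __future__ import annotations

import numpy as np
import pytest

import epochdec as ed


@pytest.fixture(scope="session")
def areas6() -> ed.AreaSet:
    return ed.northern_hemisphere_areas()


@pytest.fixture(scope="session")
def space6(areas6) -> ed.StateSpace:
    return ed.StateSpace(areas6)


@pytest.fixture(scope="session")
def areas2() -> ed.AreaSet:
    return ed.AreaSet(("A", "B"), frozenset())


@pytest.fixture(scope="session")
def space2(areas2) -> ed.StateSpace:
    return ed.StateSpace(areas2)


def random_instance(seed: int, max_tips: int = 4, max_areas: int = 3, min_tips: int = 2):
    """A random small likelihood instance: tree (fossils possible), tip ranges,
    state space, model (DEC/BAYAREALIKE, optional +J), and 1-3 epoch slices."""
    r = np.random.default_rng(seed)
    n_areas = int(r.integers(2, max_areas + 1))
    adjacent = (
        frozenset([frozenset(("A", "B"))]) if n_areas >= 2 and r.uniform() < 0.5 else frozenset()
    )
    areas = ed.AreaSet(tuple("ABC"[:n_areas]), adjacent)
    space = ed.StateSpace(areas)
    n_tips = int(r.integers(min_tips, max_tips + 1))
    tree = ed.simulate_tree(0.3, 0.1, n_tips, fossil_sampling=0.5, seed=int(r.integers(1 << 30)))
    family = "DEC" if r.uniform() < 0.6 else "BAYAREALIKE"
    j = float(r.choice([0.0, 0.5, 2.0]))
    model = ed.BiogeoModel(
        family, float(r.uniform(0.01, 0.3)), float(r.uniform(0.0, 0.1)), j
    )
    n_epochs = int(r.integers(1, 4))
    if n_epochs > 1:
        bounds = tuple(
            sorted(r.uniform(0.2, max(tree.root_age, 1.0), size=n_epochs - 1), reverse=True)
        )
    else:
        bounds = ()
    mults = tuple(r.uniform(0.2, 1.0, size=(n_areas, n_areas)) for _ in range(n_epochs))
    epochs = ed.EpochSchedule(bounds, mults)
    tip_ranges = {l: int(r.integers(1, 1 << n_areas)) for l in tree.tip_labels}
    return tree, tip_ranges, space, model, epochs


def cenozoic_toy_trend():
    """Flat/steep alternating temperature trend over (0, 50] Ma for power tests."""
    return [(50, 12), (40, 12), (35, 6), (25, 6), (20, 11), (12, 11), (8, 4), (0, 4)]
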
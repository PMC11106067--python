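"""Configuration-driven orchestration of the full analysis.

``run_full`` wires the stages together -- model fitting and AICc comparison,
ancestral-range reconstruction, event extraction, event-density curves,
lineage-through-time, period summaries, and the climate correlation -- reading
file-based inputs named in a single YAML config and writing plain-text outputs
(TSV/JSON) plus a run log that echoes the fully materialized configuration.
Every stage is also runnable in isolation (see :mod:`epochdec.cli`); given the
same config and seed, outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronogram import ltt, read_newick, read_newick_list, write_newick
from .range_space import AreaSet, StateSpace
from .biogeo_models import (
    BiogeoModel,
    EpochSchedule,
    FitResult,
    compare_models,
    fit_ml,
)
from .ancestral_events import (
    DISPERSAL,
    VICARIANCE,
    AncestralReconstruction,
    event_density,
    events_to_frame,
    extract_events,
    period_summary,
)
from .paleoclimate import TemperatureSeries, correlate, fit_loess, segment_periods
from .synthetic_data import (
    SimulatedHistory,
    simulate_ranges,
    simulate_temperature,
    simulate_tree,
)

__all__ = [
    "AnalysisConfig",
    "load_config",
    "run_full",
    "read_tip_ranges",
    "write_tip_ranges",
    "write_history",
    "read_history",
    "default_epochs",
    "generate_study",
    "CENOZOIC_TREND",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.10g"


def default_epochs(areas: AreaSet) -> EpochSchedule:
    """Three Cenozoic connectivity slices for the six-region system.

    Before 30 Ma the Bering and North Atlantic land bridges are treated as
    fully open (all multipliers 1); during 30-5 Ma the North Atlantic bridge
    weakens (EU-WNA multiplier 0.5); after 5 Ma the North Atlantic route is
    nearly severed and the Bering route weaker (ENA-EU 0.25, WNA-EA 0.5).
    """
    n = len(areas)
    full = np.ones((n, n))

    def with_pairs(pairs):
        m = full.copy()
        for (a, b), v in pairs.items():
            ia, ib = areas.index(a), areas.index(b)
            m[ia, ib] = m[ib, ia] = v
        return m

    mid = with_pairs({("EU", "WNA"): 0.5})
    late = with_pairs({("ENA", "EU"): 0.25, ("WNA", "EA"): 0.5})
    return EpochSchedule((30.0, 5.0), (full, mid, late))


# -- tip ranges -------------------------------------------------------------


def read_tip_ranges(path, areas: AreaSet) -> dict[str, int]:
    """Tip-to-range table: 'tip<TAB>EA,JP' rows (optional 'tip<TAB>range' header)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            tip, codes = parts
            if lineno == 1 and codes.strip().lower() == "range":
                continue
            if tip in out:
                raise ValueError(f"{path}:{lineno}: duplicate tip {tip!r}")
            out[tip] = areas.mask(codes)
    return out


def write_tip_ranges(tip_ranges: dict[str, int], areas: AreaSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("tip\trange\n")
        for tip in sorted(tip_ranges):
            fh.write(f"{tip}\t{','.join(areas.names(tip_ranges[tip])) or '0'}\n")


# -- configuration ----------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Validated, fully materialized analysis settings."""

    tree: Path
    tip_ranges: Path
    temperature: Path
    areas: AreaSet
    max_range_size: int
    epochs: EpochSchedule
    models: list[dict]  # [{"family": "DEC", "founder": True}, ...]
    seed: int
    output: Path
    root_prior: str = "uniform"
    event_times: str = "midpoint"
    density_bandwidth: float = 2.0
    density_grid_step: float = 0.25
    loess_span: float = 0.25
    slope_delta: float = 0.1
    period_boundaries: tuple[float, ...] = ()
    period_labels: tuple[str, ...] = ("all",)
    raw: dict = field(default_factory=dict, repr=False)

    def space(self) -> StateSpace:
        return StateSpace(self.areas, self.max_range_size)

    def echo(self) -> dict:
        """Materialized settings, sufficient to re-run the analysis exactly."""
        d = dict(self.raw)
        d.update(
            {
                "tree": str(self.tree),
                "tip_ranges": str(self.tip_ranges),
                "temperature": str(self.temperature),
                "areas": list(self.areas.codes),
                "adjacent_pairs": sorted(sorted(p) for p in self.areas.adjacent_pairs),
                "max_range_size": self.max_range_size,
                "epoch_boundaries": list(self.epochs.boundaries),
                "epoch_multipliers": [m.tolist() for m in self.epochs.multipliers],
                "models": self.models,
                "seed": self.seed,
                "root_prior": self.root_prior,
                "event_times": self.event_times,
                "density_bandwidth": self.density_bandwidth,
                "density_grid_step": self.density_grid_step,
                "loess_span": self.loess_span,
                "slope_delta": self.slope_delta,
                "period_boundaries": list(self.period_boundaries),
                "period_labels": list(self.period_labels),
                "output": str(self.output),
                "epochdec_version": __version__,
            }
        )
        return d


def _parse_slice_multipliers(slice_spec: dict, areas: AreaSet) -> np.ndarray:
    n = len(areas)
    m = np.ones((n, n))
    seen: set[frozenset[str]] = set()
    for a, row in (slice_spec.get("multipliers") or {}).items():
        for b, v in row.items():
            ia, ib = areas.index(a), areas.index(b)
            if ia == ib:
                raise ValueError(f"self-pair multiplier {a}-{b} is meaningless")
            m[ia, ib] = m[ib, ia] = float(v)
            seen.add(frozenset((a, b)))
    expected = {
        frozenset((a, b))
        for i, a in enumerate(areas.codes)
        for b in areas.codes[i + 1 :]
    }
    missing = expected - seen
    if missing:
        names = ", ".join("-".join(sorted(p)) for p in sorted(missing, key=sorted))
        raise ValueError(
            f"epoch slice {slice_spec.get('name', '?')!r} is missing multipliers "
            f"for pairs: {names} (every pair must be stated explicitly)"
        )
    return m


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML analysis config; fails before any computation."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(key):
        p = Path(raw[key])
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise FileNotFoundError(f"config {key!r} points to a missing file: {p}")
        return p

    areas = AreaSet(
        tuple(raw["areas"]),
        frozenset(frozenset(p) for p in raw.get("adjacent_pairs", [])),
    )
    max_range_size = int(raw.get("max_range_size", len(areas)))
    ep = raw["epochs"]
    boundaries = tuple(float(b) for b in ep.get("boundaries", []))
    slices = ep["slices"]
    if len(slices) != len(boundaries) + 1:
        raise ValueError(
            f"{len(boundaries)} boundaries require {len(boundaries) + 1} epoch "
            f"slices, got {len(slices)}"
        )
    epochs = EpochSchedule(
        boundaries, tuple(_parse_slice_multipliers(s, areas) for s in slices)
    )
    models = [
        {"family": str(m["family"]), "founder": bool(m.get("founder", False))}
        for m in raw.get(
            "models",
            [
                {"family": "DEC", "founder": False},
                {"family": "DEC", "founder": True},
                {"family": "BAYAREALIKE", "founder": False},
                {"family": "BAYAREALIKE", "founder": True},
            ],
        )
    ]
    periods = raw.get("periods", {}) or {}
    out = Path(raw.get("output", "out"))
    cfg = AnalysisConfig(
        tree=resolve("tree"),
        tip_ranges=resolve("tip_ranges"),
        temperature=resolve("temperature"),
        areas=areas,
        max_range_size=max_range_size,
        epochs=epochs,
        models=models,
        seed=int(raw.get("seed", 0)),
        output=out if out.is_absolute() else base / out,
        root_prior=str(raw.get("root_prior", "uniform")),
        event_times=str(raw.get("event_times", "midpoint")),
        density_bandwidth=float(raw.get("density", {}).get("bandwidth", 2.0)),
        density_grid_step=float(raw.get("density", {}).get("grid_step", 0.25)),
        loess_span=float(raw.get("loess_span", 0.25)),
        slope_delta=float(raw.get("slope_delta", 0.1)),
        period_boundaries=tuple(float(b) for b in periods.get("boundaries", [])),
        period_labels=tuple(periods.get("labels", []) or ["all"]),
        raw=raw,
    )
    if cfg.root_prior != "uniform":
        raise ValueError("only the 'uniform' root prior is currently supported")
    if cfg.event_times != "midpoint":
        raise ValueError("only the 'midpoint' event-time rule is currently supported")
    if len(cfg.period_labels) != len(cfg.period_boundaries) + 1:
        raise ValueError("periods need exactly one more label than boundaries")
    # eagerly validate the data files against each other
    tree = read_newick(cfg.tree)
    ranges = read_tip_ranges(cfg.tip_ranges, areas)
    missing = set(tree.tip_labels) - set(ranges)
    if missing:
        raise ValueError(f"tips missing from the range table: {sorted(missing)}")
    series = TemperatureSeries.from_csv(cfg.temperature)
    lo, hi = series.age_range
    if lo > 1e-9 or hi < tree.root_age:
        raise ValueError(
            f"temperature series spans [{lo:g}, {hi:g}] Ma but must cover "
            f"[0, {tree.root_age:g}] Ma (the tree's root age)"
        )
    return cfg


# -- pipeline stages --------------------------------------------------------


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def fit_stage(cfg: AnalysisConfig, tree, tip_ranges, space) -> tuple[list[FitResult], pd.DataFrame]:
    fits = [
        fit_ml(
            tree,
            tip_ranges,
            space,
            spec["family"],
            cfg.epochs,
            with_j=spec["founder"],
            seed=cfg.seed,
        )
        for spec in cfg.models
    ]
    return fits, compare_models(fits)


def run_full(cfg: AnalysisConfig, out_dir=None) -> dict[str, Path]:
    """Run every stage and write the result bundle; returns output paths."""
    out = Path(out_dir) if out_dir is not None else cfg.output
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_lines = [f"epochdec {__version__}", f"seed {cfg.seed}", "config:"]
    log_lines += ["  " + l for l in json.dumps(cfg.echo(), indent=2, sort_keys=True).splitlines()]

    def stage(name):
        log_lines.append(f"stage {name}")

    try:
        stage("load")
        trees = read_newick_list(cfg.tree)
        tree = trees[0]
        space = cfg.space()
        tip_ranges = read_tip_ranges(cfg.tip_ranges, cfg.areas)
        series = TemperatureSeries.from_csv(cfg.temperature)

        stage("fit")
        fits, table = fit_stage(cfg, tree, tip_ranges, space)
        best = next(f for f in fits if f.name == table.iloc[0]["model"])
        _write_json(
            {
                "fits": [f.to_dict() for f in fits],
                "table": table.to_dict(orient="records"),
                "best": best.name,
            },
            out / "fits.json",
        )
        paths["fits"] = out / "fits.json"

        stage("ancestral")
        from .ancestral_events import marginal_ranges

        recon = marginal_ranges(tree, tip_ranges, best, space, cfg.epochs)
        frame = recon.to_frame()
        frame["corner_range"] = [
            cfg.areas.format_range(recon.corner_map[nid])
            if nid in recon.corner_map
            else ""
            for nid in frame["node_id"]
        ]
        _write_tsv(frame, out / "ancestral.tsv")
        paths["ancestral"] = out / "ancestral.tsv"

        stage("events")
        events = extract_events(recon, cfg.areas)
        _write_tsv(events_to_frame(events, cfg.areas), out / "events.tsv")
        paths["events"] = out / "events.tsv"

        stage("density")
        curves = {
            t: event_density(
                events, cfg.density_bandwidth, cfg.density_grid_step, event_type=t
            )
            for t in (DISPERSAL, VICARIANCE)
        }
        dens_rows = []
        for t, c in curves.items():
            for a, d in zip(c.grid, c.density):
                dens_rows.append({"type": t, "age_ma": a, "density": d})
        _write_tsv(
            pd.DataFrame(dens_rows, columns=["type", "age_ma", "density"]),
            out / "density.tsv",
        )
        paths["density"] = out / "density.tsv"

        stage("ltt")
        curves_ltt = ltt(trees)
        ltt_rows = []
        for idx, c in enumerate(curves_ltt):
            for a0, a1, cnt in c.rows():
                ltt_rows.append(
                    {"tree_index": idx, "age_start": a0, "age_end": a1, "count": cnt}
                )
        _write_tsv(pd.DataFrame(ltt_rows), out / "ltt.tsv")
        paths["ltt"] = out / "ltt.tsv"

        stage("periods")
        periods = segment_periods(
            tree.root_age, cfg.period_boundaries, cfg.period_labels
        )
        ptable = period_summary(events, periods)
        flat = ptable.copy()
        flat.columns = [f"{t}_{s}" for t, s in flat.columns]
        _write_tsv(flat.reset_index(), out / "periods.tsv")
        paths["periods"] = out / "periods.tsv"

        stage("correlate")
        loess = fit_loess(series, cfg.loess_span)
        corr = {}
        points = []
        for t in (DISPERSAL, VICARIANCE):
            cc = correlate(events, curves[t], loess, cfg.slope_delta, event_type=t)
            corr[t] = cc.to_dict()
            if cc.table is not None:
                points.append(cc.table)
        _write_json(corr, out / "correlation.json")
        paths["correlation"] = out / "correlation.json"
        if points:
            _write_tsv(pd.concat(points, ignore_index=True), out / "correlation_points.tsv")
            paths["correlation_points"] = out / "correlation_points.tsv"
    except Exception as exc:
        log_lines.append(f"FAILED at stage {log_lines[-1].split()[-1]}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    log_lines.append("status ok")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = out / "run.log"
    return paths


# -- synthetic study generation ---------------------------------------------

#: Cenozoic-style deep-sea temperature anchors (age Ma, degC): early-Eocene
#: optimum, the sharp terminal-Eocene drop near 34 Ma, a mid-Miocene bump,
#: then decline into the Plio-Pleistocene.
CENOZOIC_TREND = [
    (300.0, 8.0),  # flat deep-time plateau so tall simulated trees stay covered
    (150.0, 8.5),
    (70.0, 9.0),
    (60.0, 10.5),
    (52.0, 13.0),
    (50.0, 13.5),
    (40.0, 9.5),
    (34.2, 8.5),
    (33.5, 5.0),
    (26.0, 6.0),
    (15.0, 7.0),
    (13.0, 5.0),
    (7.0, 3.0),
    (3.0, 2.0),
    (0.0, 1.0),
]


def _epochs_to_yaml(epochs: EpochSchedule, areas: AreaSet) -> dict:
    slices = []
    for k, m in enumerate(epochs.multipliers):
        mult: dict[str, dict[str, float]] = {}
        for i, a in enumerate(areas.codes):
            row = {b: float(m[i, areas.index(b)]) for b in areas.codes[i + 1 :]}
            if row:
                mult[a] = row
        slices.append({"name": f"slice_{k}", "multipliers": mult})
    return {"boundaries": list(epochs.boundaries), "slices": slices}


def generate_study(
    out_dir,
    seed: int,
    areas: AreaSet | None = None,
    epochs: EpochSchedule | None = None,
    n_extant: int = 20,
    birth: float = 0.09,
    death: float = 0.03,
    fossil_sampling: float = 0.1,
    family: str = "DEC",
    d: float = 0.015,
    e: float = 0.005,
    j: float = 0.0,
    root_range: str = "WNA",
    noise_sd: float = 0.7,
    temp_step: float = 0.25,
    period_boundaries: tuple[float, ...] = (34.0, 15.0, 5.0),
    period_labels: tuple[str, ...] = ("Warm I", "Cold I", "Warm II", "Cold II"),
    models: list[dict] | None = None,
) -> tuple[Path, SimulatedHistory]:
    """Generate a complete, self-contained synthetic study directory.

    Produces a fossil-bearing chronogram, forward-simulated tip ranges with
    their ground-truth event log, a noisy Cenozoic-style temperature series,
    and a ready-to-run ``config.yaml``.  Retries the range simulation with
    derived seeds until every tip is observable (no dead, null-range tips).
    Returns the config path and the simulated history.
    """
    from .range_space import northern_hemisphere_areas

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if areas is None:
        areas = northern_hemisphere_areas()
    if epochs is None:
        epochs = default_epochs(areas)
    space = StateSpace(areas)
    tree = simulate_tree(birth, death, n_extant, fossil_sampling, seed=seed)
    model = BiogeoModel(family, d, e, j)
    # dead (null-range) lineages are unobservable: the analysis inputs are the
    # tree and ranges pruned to observable tips, while the fixture keeps the
    # full ground truth alongside
    history = None
    for attempt in range(20):
        cand = simulate_ranges(
            tree, model, epochs, areas.mask(root_range), seed=seed + 1000 + attempt,
            space=space,
        )
        if len(cand.observable_tip_ranges()) >= max(4, n_extant // 2):
            history = cand
            break
    if history is None:
        raise RuntimeError("simulated histories kept losing most tips; lower e or raise d")
    write_history(history, out)
    observed_tree, observed_ranges = history.pruned_to_observable()
    write_newick(observed_tree, out / "tree.nwk")
    write_tip_ranges(observed_ranges, areas, out / "tip_ranges.tsv")
    series = simulate_temperature(
        CENOZOIC_TREND,
        noise_sd=noise_sd,
        step=temp_step,
        seed=seed + 2,
        age_max=min(300.0, tree.root_age + 5.0),
    )
    series.to_csv(out / "temperature.csv")
    cfg = {
        "tree": "tree.nwk",
        "tip_ranges": "tip_ranges.tsv",
        "temperature": "temperature.csv",
        "areas": list(areas.codes),
        "adjacent_pairs": sorted(sorted(p) for p in areas.adjacent_pairs),
        "max_range_size": space.max_range_size,
        "epochs": _epochs_to_yaml(epochs, areas),
        "models": models
        or [
            {"family": "DEC", "founder": False},
            {"family": "DEC", "founder": True},
            {"family": "BAYAREALIKE", "founder": False},
            {"family": "BAYAREALIKE", "founder": True},
        ],
        "seed": seed,
        "root_prior": "uniform",
        "event_times": "midpoint",
        "density": {"bandwidth": 2.0, "grid_step": 0.25},
        "loess_span": 0.25,
        "slope_delta": 0.1,
        "periods": {
            "boundaries": [b for b in period_boundaries if b < tree.root_age],
            "labels": list(
                period_labels[len(period_boundaries)
                              - len([b for b in period_boundaries if b < tree.root_age]):]
            ),
        },
        "output": "out",
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out / "config.yaml", history


# -- simulated-history (fixture) serialization ------------------------------


def write_history(history: SimulatedHistory, out_dir) -> dict[str, Path]:
    """Write a simulated history as a plain-text fixture directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    areas = history.areas
    write_newick(history.tree, out / "true_tree.nwk")
    write_tip_ranges(history.observable_tip_ranges(), areas, out / "tip_ranges.tsv")
    _write_tsv(events_to_frame(history.true_events, areas), out / "true_events.tsv")
    for name, mapping in (
        ("node_states.tsv", history.node_states),
        ("corner_states.tsv", history.corner_states),
    ):
        rows = [
            {"node_id": k, "range": ",".join(areas.names(v)) or "0"}
            for k, v in sorted(mapping.items())
        ]
        _write_tsv(pd.DataFrame(rows, columns=["node_id", "range"]), out / name)
    path_rows = []
    for bid, path in sorted(history.branch_paths.items()):
        for age, state in path:
            path_rows.append(
                {"branch_id": bid, "age_ma": age, "range": ",".join(areas.names(state)) or "0"}
            )
    _write_tsv(
        pd.DataFrame(path_rows, columns=["branch_id", "age_ma", "range"]),
        out / "branch_paths.tsv",
    )
    manifest = {
        "schema": SCHEMA_VERSION,
        "seed": history.seed,
        "family": history.model.family,
        "d": history.model.d,
        "e": history.model.e,
        "j": history.model.j,
        "root_range": ",".join(areas.names(history.root_range)),
        "areas": list(areas.codes),
        "adjacent_pairs": sorted(sorted(p) for p in areas.adjacent_pairs),
        "max_range_size": history.space.max_range_size,
        "epoch_boundaries": list(history.epochs.boundaries),
        "epoch_multipliers": [m.tolist() for m in history.epochs.multipliers],
    }
    _write_json(manifest, out / "manifest.json")
    return {p.stem: p for p in out.iterdir()}


def read_history(fixture_dir) -> AncestralReconstruction:
    """Load a fixture directory back as a true-history reconstruction."""
    d = Path(fixture_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("schema") != SCHEMA_VERSION:
        raise ValueError(
            f"fixture schema {manifest.get('schema')!r} does not match the "
            f"supported schema {SCHEMA_VERSION}"
        )
    areas = AreaSet(
        tuple(manifest["areas"]),
        frozenset(frozenset(p) for p in manifest["adjacent_pairs"]),
    )
    space = StateSpace(areas, manifest["max_range_size"])
    tree = read_newick(d / "true_tree.nwk")
    node_states = {
        r.node_id: areas.mask(r.range)
        for r in pd.read_csv(d / "node_states.tsv", sep="\t", dtype=str)
        .fillna("0")
        .itertuples()
        if r.range != "0"
    } | {
        r.node_id: 0
        for r in pd.read_csv(d / "node_states.tsv", sep="\t", dtype=str)
        .fillna("0")
        .itertuples()
        if r.range == "0"
    }
    corner_states = {}
    for r in pd.read_csv(d / "corner_states.tsv", sep="\t", dtype=str).fillna("0").itertuples():
        corner_states[r.node_id] = 0 if r.range == "0" else areas.mask(r.range)
    paths: dict[str, list[tuple[float, int]]] = {}
    for r in pd.read_csv(d / "branch_paths.tsv", sep="\t", dtype=str).fillna("0").itertuples():
        mask = 0 if r.range == "0" else areas.mask(r.range)
        paths.setdefault(r.branch_id, []).append((float(r.age_ma), mask))
    marginals = {}
    for nid, state in node_states.items():
        v = np.zeros(len(space))
        v[space.index_of(state)] = 1.0
        marginals[nid] = v
    return AncestralReconstruction(
        tree=tree,
        space=space,
        marginals=marginals,
        node_map=node_states,
        corner_map=corner_states,
        model_name="true-history",
        branch_paths=paths,
    )
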
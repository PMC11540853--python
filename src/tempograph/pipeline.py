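"""End-to-end orchestration: simulate -> preprocess -> classify -> decode ->
geometry -> replay, from a single config with one root seed.

Every stochastic stage draws from a named substream of the root seed
(``np.random.SeedSequence(seed, spawn_key)``), so stages can be re-run in
isolation and a full rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphs, popgeom, preprocess, replay, synthdata, tuning
from .sequences import PHASES
from .synthdata import SessionData, SimulationConfig

log = logging.getLogger("tempograph")

STAGE_KEYS = {"sequence": 0, "simulation": 1, "classify": 2, "decode": 3,
              "geometry": 4, "replay": 5, "injection": 6}

PHASE_GROUPS_WITH_PRE = {"PRE": ("PRE",), **tuning.PHASE_GROUPS}

__all__ = ["RunConfig", "run_pipeline", "load_session", "stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],)))


@dataclass
class RunConfig:
    graph: str = "pyramid"  # or "diamond"
    simulation: dict = field(default_factory=dict)
    gamma: float = 0.15  # discounted successor template
    templates: tuple = ("geodesic", "euclidean", "successor")
    n_perm_nodes: int = 2000
    n_perm_replay: int = 1000
    replay_injection: list = field(default_factory=list)
    run_classify: bool = True
    run_decode: bool = True
    run_geometry: bool = True
    run_replay: bool = True
    seed: int = 0
    outdir: str | None = None

    def to_yaml(self) -> str:
        d = asdict(self)
        d["templates"] = list(d["templates"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "templates" in d:
            d["templates"] = tuple(d["templates"])
        return cls(**d)


def _build_graph(name: str) -> graphs.GraphSpec:
    if name == "pyramid":
        return graphs.build_pyramid()
    if name == "diamond":
        return graphs.build_diamond()
    raise ValueError(f"unknown graph {name!r}")


def _make_templates(cfg: RunConfig, g: graphs.GraphSpec) -> dict:
    builders = {
        "geodesic": lambda: graphs.geodesic_template(g),
        "euclidean": lambda: graphs.euclidean_template(g),
        "successor": lambda: graphs.successor_template(g),
        "discounted": lambda: graphs.discounted_successor_template(g, cfg.gamma),
    }
    return {name: builders[name]() for name in cfg.templates}


def drop_first_trial_per_phase(b: preprocess.BinnedResponses) -> preprocess.BinnedResponses:
    """Discard the first trial of each phase (the start of a sequence has no
    preceding transition), leaving 120 analysed trials per 121-trial phase."""
    first = b.events.groupby("phase", sort=False)["trial"].transform("min")
    return b.select_trials((b.events["trial"] != first).to_numpy())


def load_session(spikes_path, events_path, breaks_path=None) -> SessionData:
    """Load and validate a session from spikes.csv / events.csv (+ breaks.json)."""
    spikes = pd.read_csv(spikes_path)
    events = pd.read_csv(events_path)
    problems = []
    for col in ("neuron", "region", "hemisphere", "time"):
        if col not in spikes.columns:
            problems.append(f"spikes missing column {col!r}")
    for col in ("trial", "phase", "onset", "node"):
        if col not in events.columns:
            problems.append(f"events missing column {col!r}")
    if problems:
        raise ValueError("; ".join(problems))
    bad = spikes.index[~np.isfinite(spikes["time"])]
    if len(bad):
        raise ValueError(f"non-finite spike time at rows {list(bad[:5])}")
    unknown = set(events["phase"]) - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phase labels {sorted(unknown)}")
    missing = set(PHASES) - set(events["phase"])
    if missing:
        log.warning("events cover only part of the study: missing %s", sorted(missing))
    if not spikes.groupby("neuron")["time"].apply(
        lambda s: bool(np.all(np.diff(s) >= 0))
    ).all():
        log.warning("spike times unsorted; sorting")
        spikes = spikes.sort_values(["neuron", "time"], kind="stable").reset_index(drop=True)
    breaks = {}
    if breaks_path is not None:
        breaks = {
            k: tuple(v) for k, v in json.loads(Path(breaks_path).read_text()).items()
        }
    return SessionData(spikes, events, breaks).validate()


def run_pipeline(cfg: RunConfig, session: SessionData | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    When ``cfg.outdir`` is set, stage artifacts (CSV/JSON) and the report
    are written there as each stage completes, so a failing stage leaves
    the earlier artifacts on disk.
    """
    g = _build_graph(cfg.graph)
    out = Path(cfg.outdir) if cfg.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg.to_yaml())
        (out / "graph.json").write_text(g.to_json())
    report = {"config": json.loads(json.dumps(asdict(cfg), default=list)), "stages": {}}

    def finish_stage(name, payload):
        report["stages"][name] = payload
        if out:
            (out / "report.json").write_text(
                json.dumps(report, indent=1, default=_default)
            )

    # --- simulate ---
    sim_cfg = SimulationConfig.from_dict(
        {**cfg.simulation, "seed": int(stage_rng(cfg.seed, "simulation").integers(2**31))}
    )
    if session is None:
        session = synthdata.simulate_session(sim_cfg, g)
        inj_rng = stage_rng(cfg.seed, "injection")
        for spec in cfg.replay_injection:
            session = synthdata.inject_replays(
                session,
                tuple(spec["triplet"]),
                spec["latency_direct_ms"],
                spec["latency_indirect_ms"],
                spec["repetitions"],
                spec["break_ids"],
                rng_seed=int(inj_rng.integers(2**31)),
            )
        if out:
            session.save(out)
    finish_stage(
        "simulate",
        {
            "n_neurons": int(len(session.neuron_ids)),
            "n_trials": int(len(session.events)),
            "n_spikes": int(len(session.spikes)),
        },
    )
    info = session.neuron_info()

    # --- preprocess + classify ---
    labels = None
    if cfg.run_classify:
        b_sel = preprocess.preprocess(session.spikes, session.events, "selection")
        b_sel = drop_first_trial_per_phase(b_sel)
        labels = tuning.classify_neurons(b_sel, g, info)
        ldf = tuning.labels_frame(labels)
        if out:
            ldf.drop(columns=["flags"]).to_csv(out / "labels.csv", index=False)
        finish_stage(
            "classify",
            {
                "n_selective": int(ldf["is_selective"].sum()),
                "n_relational": int(ldf["is_relational"].sum()),
                "n_diminishing": int(ldf["is_diminishing"].sum()),
                "n_excluded": int(ldf["excluded"].sum()),
            },
        )

    # --- decode ---
    posteriors = None
    if cfg.run_decode:
        b_dec = preprocess.bin_spikes(session.spikes, session.events)
        b_dec = preprocess.smooth_moving_sum(b_dec, 0.25)
        b_dec = drop_first_trial_per_phase(b_dec)
        posteriors = popgeom.decode_session(b_dec, g)
        if out:
            posteriors.to_csv(out / "posteriors.csv", index=False)
        cdf_stats = {}
        for grp, phs in tuning.PHASE_GROUPS.items():
            for cat, direction in (
                ("actual", "decrease"),
                ("direct", "increase"),
                ("indirect", "increase"),
            ):
                d, p = popgeom.posterior_cdf_compare(
                    posteriors, "PRE", phs, cat, direction
                )
                cdf_stats[f"{cat}_{grp}"] = {"D": d, "p": p, "direction": direction}
        finish_stage(
            "decode",
            {
                "accuracy_PRE": popgeom.decoding_accuracy(posteriors, "PRE"),
                "chance_level": 1.0 / g.n_nodes,
                "cdf_vs_PRE": cdf_stats,
            },
        )
    else:
        finish_stage("decode", "skipped")

    # --- geometry ---
    if cfg.run_geometry:
        b_dist = preprocess.preprocess(session.spikes, session.events, "distance")
        b_dist = drop_first_trial_per_phase(b_dist)
        ndms = {
            grp: popgeom.neural_distance_matrix(b_dist, phs)
            for grp, phs in PHASE_GROUPS_WITH_PRE.items()
        }
        templates = _make_templates(cfg, g)
        rng = stage_rng(cfg.seed, "geometry")
        fits = {}
        for name, tmpl in templates.items():
            res = popgeom.node_permutation_test(
                ndms, tmpl, cfg.n_perm_nodes, rng
            )
            fits[name] = res.to_dict(orient="records")
            if out:
                (out / f"ndm_fit_{name}.csv").write_text(res.to_csv(index=False))
        if out:
            for grp, ndm in ndms.items():
                np.savetxt(out / f"ndm_{grp}.csv", ndm.matrix, delimiter=",")
        finish_stage("geometry", {"template_fits": fits, "n_perm": cfg.n_perm_nodes})
    else:
        finish_stage("geometry", "skipped")

    # --- replay ---
    if cfg.run_replay:
        if labels is None:
            raise RuntimeError("replay stage requires the classify stage")
        scanned = replay.scan_session(session, labels, g)
        if scanned:
            rng = stage_rng(cfg.seed, "replay")
            props = replay.replay_proportion_test(scanned, cfg.n_perm_replay, rng)
            if out:
                props.to_csv(out / "replays.csv", index=False)
            finish_stage(
                "replay",
                {
                    "n_candidates": len(scanned),
                    "proportions": props.to_dict(orient="records"),
                },
            )
        else:
            finish_stage("replay", {"n_candidates": 0})
    else:
        finish_stage("replay", "skipped")

    return report


def _default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
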
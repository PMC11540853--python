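"""Synthetic session generator with known ground truth.

Emulates the study design: eight phases (PRE, E1..E6, POST) of 121 image
presentations each, separated by breaks (B1..B7); Poisson-spiking neurons
with one preferred stimulus whose tuning gradually spreads to graph-adjacent
("direct") stimuli while peak selectivity decays; background spiking during
breaks, into which ordered triplet replays can be injected.

Every downstream stage (classification, decoding, geometry, replay) can be
validated against the generator's ground truth: the planted preferred node
and relational flag per neuron, and the list of injected replays.

Default parameters follow the task description where one is given (121
stimuli/phase, 60/60 direct/indirect transitions in PRE and POST, 60
mirrored images per exposure phase, ITI uniform on 1-3 s, 0.5 s feedback,
self-paced stimulus duration modelled lognormal with 0.9 s median); effect
sizes of the tuning remap are not reported for the recordings, so defaults
(baseline 2 Hz, preferred gain 8 Hz, direct gain rising to 0.6 of the
preferred gain by E5) are chosen to give single-session statistical power
comparable to the published population effects, and are all configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .graphs import GraphSpec, DistanceTemplate, shift_positive
from .sequences import (
    PHASES,
    EXPOSURE_PHASES,
    assign_mirror_flags,
    generate_pseudorandom,
    generate_random_walk,
)

BREAKS = ("B1", "B2", "B3", "B4", "B5", "B6", "B7")

__all__ = [
    "SimulationConfig",
    "SessionData",
    "simulate_session",
    "simulate_null_session",
    "inject_replays",
    "simulate_template_population",
]

# per-phase schedules: (PRE, E1, E2, E3, E4, E5, E6, POST)
DEFAULT_DECAY = (1.0, 0.95, 0.85, 0.75, 0.65, 0.6, 0.55, 0.55)
DEFAULT_DIRECT = (0.0, 0.05, 0.15, 0.3, 0.45, 0.6, 0.6, 0.6)
FLAT_DECAY = (1.0,) * 8
FLAT_DIRECT = (0.0,) * 8


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated recording session."""

    n_neurons: dict = field(
        default_factory=lambda: {"H": 24, "EC": 18, "other": 12}
    )
    baseline_rate: float = 2.0  # Hz, homogeneous background
    preferred_gain: float = 8.0  # Hz added on preferred-stimulus trials (PRE)
    direct_gain_schedule: tuple = DEFAULT_DIRECT  # fraction of preferred_gain
    selectivity_decay_schedule: tuple = DEFAULT_DECAY
    indirect_gain: float = 0.0  # fraction of preferred_gain, constant
    remap_profile: str = "adjacency"  # or "successor": gain spread ∝ e^A closeness
    fraction_tuned: float = 0.8  # remaining neurons are pure background
    kernel_onset: float = 0.1  # s after stimulus onset
    kernel_offset: float = 1.0
    iti_range: tuple = (1.0, 3.0)
    rt_median: float = 0.9  # lognormal stimulus-duration model (self-paced)
    rt_sigma: float = 0.3
    feedback_duration: float = 0.5
    break_duration: float = 60.0
    n_trials: int = 121
    n_direct: int = 60
    n_indirect: int = 60
    n_mirrored: int = 60
    seed: int = 0

    def __post_init__(self):
        if len(self.direct_gain_schedule) != len(PHASES):
            raise ValueError(f"direct_gain_schedule must have {len(PHASES)} entries")
        if len(self.selectivity_decay_schedule) != len(PHASES):
            raise ValueError(
                f"selectivity_decay_schedule must have {len(PHASES)} entries"
            )
        if self.baseline_rate < 0 or self.preferred_gain < 0:
            raise ValueError("rates must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("direct_gain_schedule", "selectivity_decay_schedule", "iti_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SessionData:
    """A simulated (or loaded) recording session.

    ``spikes``: columns neuron, region, hemisphere, time (s, sorted per neuron).
    ``events``: columns trial, phase, onset, node, mirrored, response, rt.
    ``breaks``: dict break id -> (start, end) seconds.
    ``ground_truth``: generator-side truth (may be empty for loaded data).
    """

    spikes: pd.DataFrame
    events: pd.DataFrame
    breaks: dict
    ground_truth: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.unique(self.spikes["neuron"])

    def neuron_info(self) -> pd.DataFrame:
        return (
            self.spikes.groupby("neuron")[["region", "hemisphere"]]
            .first()
            .reset_index()
        )

    def spike_times(self, neuron) -> np.ndarray:
        return self.spikes.loc[self.spikes["neuron"] == neuron, "time"].to_numpy()

    def validate(self):
        t = self.spikes.groupby("neuron")["time"]
        if not (t.apply(lambda s: bool(np.all(np.diff(s) >= 0)))).all():
            raise ValueError("spike times must be non-decreasing per neuron")
        for b, (s, e) in self.breaks.items():
            if e <= s:
                raise ValueError(f"break {b} has non-positive duration")
        return self

    def save(self, outdir):
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        (out / "breaks.json").write_text(
            json.dumps({k: list(v) for k, v in self.breaks.items()}, indent=1)
        )
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=1, default=_jsonable)
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _phase_sequences(cfg: SimulationConfig, g: GraphSpec, rng):
    seqs = []
    for phase in PHASES:
        if phase in ("PRE", "POST"):
            seq = generate_pseudorandom(
                g,
                cfg.n_direct,
                cfg.n_indirect,
                rng_seed=rng.integers(2**31),
                phase=phase,
            )
        else:
            seq = generate_random_walk(
                g, cfg.n_trials, rng_seed=rng.integers(2**31), phase=phase
            )
            seq = assign_mirror_flags(seq, cfg.n_mirrored, rng_seed=rng.integers(2**31))
        seqs.append(seq)
    return seqs


def _homogeneous_poisson(rate, t0, t1, rng):
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def simulate_session(cfg: SimulationConfig, g: GraphSpec) -> SessionData:
    """Simulate one full session on graph ``g``.

    Per neuron and trial, the firing rate inside the response kernel
    (boxcar from ``kernel_onset`` to ``kernel_offset`` after stimulus onset)
    is ``baseline + preferred_gain * m`` where the multiplier ``m`` depends
    on the presented stimulus relative to the neuron's preferred node:
    the selectivity-decay schedule for the preferred stimulus itself, the
    direct-gain schedule for graph neighbours, and a constant for indirect
    stimuli.  Outside kernels the neuron fires at baseline (including breaks
    and inter-trial intervals).
    """
    rng = np.random.default_rng(cfg.seed)
    seqs = _phase_sequences(cfg, g, rng)

    # --- timing ---
    events_rows = []
    breaks = {}
    t = 0.0
    trial = 0
    for p_idx, seq in enumerate(seqs):
        for pos, node in enumerate(seq.nodes):
            rt = cfg.rt_median * np.exp(rng.normal(0.0, cfg.rt_sigma))
            events_rows.append(
                {
                    "trial": trial,
                    "phase": seq.phase,
                    "onset": t,
                    "node": int(node),
                    "mirrored": bool(seq.mirrored[pos]) if seq.mirrored else False,
                    "response": bool(rng.random() < 0.95),
                    "rt": float(rt),
                }
            )
            t += rt + cfg.feedback_duration + rng.uniform(*cfg.iti_range)
            trial += 1
        if p_idx < len(seqs) - 1:
            breaks[BREAKS[p_idx]] = (t, t + cfg.break_duration)
            t += cfg.break_duration
    t_end = t
    events = pd.DataFrame(events_rows)

    # --- neuron population ---
    regions = [r for r, n in cfg.n_neurons.items() for _ in range(n)]
    n_total = len(regions)
    hemis = rng.choice(["L", "R"], size=n_total)
    tuned = rng.random(n_total) < cfg.fraction_tuned
    preferred = np.array(
        [g.node_ids[i % g.n_nodes] for i in range(n_total)], dtype=int
    )
    rng.shuffle(preferred)

    decay = np.asarray(cfg.selectivity_decay_schedule)
    direct = np.asarray(cfg.direct_gain_schedule)
    if cfg.remap_profile == "successor":
        # graded spread: non-preferred gain weight ∝ e^A closeness to the
        # preferred node, normalised so the closest non-preferred node gets
        # the full direct-gain schedule
        from scipy.linalg import expm

        closeness = expm(g.adjacency)
        np.fill_diagonal(closeness, 0.0)
        weight = closeness / closeness.max(axis=1, keepdims=True)
    elif cfg.remap_profile == "adjacency":
        weight = None
    else:
        raise ValueError(f"unknown remap_profile {cfg.remap_profile!r}")
    phase_idx = {p: i for i, p in enumerate(PHASES)}
    onsets = events["onset"].to_numpy()
    nodes = events["node"].to_numpy()
    pidx = events["phase"].map(phase_idx).to_numpy()
    k_len = cfg.kernel_offset - cfg.kernel_onset

    spike_frames = []
    gt_neurons = []
    for i in range(n_total):
        times = [_homogeneous_poisson(cfg.baseline_rate, 0.0, t_end, rng)]
        if tuned[i]:
            pref = preferred[i]
            if weight is None:
                nbrs = set(g.neighbors(pref))
                spread = np.where(
                    np.isin(nodes, list(nbrs)), direct[pidx], cfg.indirect_gain
                )
            else:
                pi = g.index(pref)
                node_pos = np.array([g.index(n) for n in nodes])
                spread = direct[pidx] * weight[pi, node_pos]
            mult = np.where(nodes == pref, decay[pidx], spread)
            rates = cfg.preferred_gain * mult
            n_extra = rng.poisson(rates * k_len)
            for j in np.flatnonzero(n_extra):
                lo = onsets[j] + cfg.kernel_onset
                times.append(rng.uniform(lo, lo + k_len, n_extra[j]))
        all_t = np.sort(np.concatenate(times))
        spike_frames.append(
            pd.DataFrame(
                {
                    "neuron": i,
                    "region": regions[i],
                    "hemisphere": hemis[i],
                    "time": all_t,
                }
            )
        )
        gt_neurons.append(
            {
                "neuron": i,
                "region": regions[i],
                "hemisphere": hemis[i],
                "tuned": bool(tuned[i]),
                "preferred_node": int(preferred[i]) if tuned[i] else None,
                "relational": bool(
                    tuned[i] and (direct[5:7].mean() - direct[0]) > 0.2
                ),
                "diminishing": bool(
                    tuned[i] and (decay[0] - decay[5:7].mean()) > 0.2
                ),
            }
        )

    spikes = pd.concat(spike_frames, ignore_index=True)
    gt = {
        "neurons": gt_neurons,
        "config": asdict(cfg),
        "injected_replays": [],
    }
    return SessionData(spikes, events, breaks, gt).validate()


def simulate_null_session(cfg: SimulationConfig, g: GraphSpec) -> SessionData:
    """Session with flat learning schedules: selective tuning is static,
    nothing remaps.  Calibration fixture for false-positive rates."""
    cfg = replace(
        cfg,
        direct_gain_schedule=FLAT_DIRECT,
        selectivity_decay_schedule=FLAT_DECAY,
    )
    return simulate_session(cfg, g)


def inject_replays(
    session: SessionData,
    triplet: tuple,
    latency_direct_ms: float,
    latency_indirect_ms: float,
    repetitions: int,
    break_ids,
    jitter_ms: float = 1.0,
    rng_seed=None,
) -> SessionData:
    """Inject ordered triplet replays into the named breaks.

    Adds ``repetitions`` seed-neuron spikes (split across ``break_ids``),
    each followed by one direct-neuron spike at ``latency_direct_ms`` and
    one indirect-neuron spike at ``latency_indirect_ms`` (each jittered
    within (0, 30) ms).  Returns a new SessionData; the injection is
    recorded in ``ground_truth['injected_replays']``.
    """
    for name, lat in (("direct", latency_direct_ms), ("indirect", latency_indirect_ms)):
        if not 0 < lat < 30:
            raise ValueError(
                f"{name} latency {lat} ms outside the (0, 30) ms detection window"
            )
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    seed_n, direct_n, indirect_n = triplet
    known = set(session.spikes["neuron"].unique())
    if not {seed_n, direct_n, indirect_n} <= known:
        raise ValueError("triplet neurons must exist in the session")
    rng = np.random.default_rng(rng_seed)
    info = session.neuron_info().set_index("neuron")

    rows = []
    for k in range(repetitions):
        b = break_ids[k % len(break_ids)]
        b0, b1 = session.breaks[b]
        t_seed = rng.uniform(b0 + 0.1, b1 - 0.1)
        for n_id, lat in ((seed_n, 0.0), (direct_n, latency_direct_ms), (indirect_n, latency_indirect_ms)):
            jit = 0.0 if n_id == seed_n else np.clip(
                lat + rng.uniform(-jitter_ms, jitter_ms), 0.1, 29.9
            )
            rows.append(
                {
                    "neuron": n_id,
                    "region": info.loc[n_id, "region"],
                    "hemisphere": info.loc[n_id, "hemisphere"],
                    "time": t_seed + jit / 1000.0,
                }
            )
    spikes = (
        pd.concat([session.spikes, pd.DataFrame(rows)], ignore_index=True)
        .sort_values(["neuron", "time"], kind="stable")
        .reset_index(drop=True)
    )
    gt = dict(session.ground_truth)
    gt = {**gt, "injected_replays": list(gt.get("injected_replays", []))}
    gt["injected_replays"].append(
        {
            "triplet": [int(x) for x in triplet],
            "latency_direct_ms": float(latency_direct_ms),
            "latency_indirect_ms": float(latency_indirect_ms),
            "repetitions": int(repetitions),
            "break_ids": list(break_ids),
        }
    )
    return SessionData(spikes, session.events.copy(), dict(session.breaks), gt)


def simulate_template_population(
    template: DistanceTemplate,
    n_neurons: int = 60,
    n_trials_per_node: int = 40,
    rate_scale: float = 4.0,
    baseline: float = 1.0,
    rng_seed=None,
):
    """Poisson population whose mean response geometry follows a template.

    The (positive-shifted) template is embedded exactly by classical MDS
    after an additive-constant correction (the smallest constant added to
    the off-diagonal distances that makes them Euclidean-embeddable; rank
    order is unchanged).  Each neuron takes one embedding dimension as its
    tuning axis, so the expected population distance matrix over node
    mean-responses is rank-faithful to the template.  Returns
    ``(counts, node_labels)``: a neuron x trial integer count matrix and
    the per-trial node id.
    """
    d = shift_positive(template.matrix, 0.1)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - 1.0 / n

    def gram(c):
        dd = d + c
        np.fill_diagonal(dd, 0.0)
        return -0.5 * j @ (dd**2) @ j

    lo, hi = 0.0, 10.0 * d.max()
    for _ in range(80):  # additive-constant bisection
        mid = 0.5 * (lo + hi)
        if np.linalg.eigvalsh(gram(mid)).min() < -1e-12:
            lo = mid
        else:
            hi = mid
    b = gram(hi)
    w, v = np.linalg.eigh(b)
    keep = w > 1e-10
    x = v[:, keep] * np.sqrt(w[keep])  # nodes x dims
    x = x - x.min(axis=0)  # non-negative coordinates
    rng = np.random.default_rng(rng_seed)
    dims = rng.integers(x.shape[1], size=n_neurons)
    signs = rng.choice([1.0, -1.0], size=n_neurons)
    # per-neuron rate profile across nodes; sign flips keep distances while
    # varying the tuning direction
    span = x.max(axis=0)
    profiles = np.where(
        signs[:, None] > 0, x.T[dims], (span[dims])[:, None] - x.T[dims]
    )  # neurons x nodes
    rates = baseline + rate_scale * profiles
    node_labels = np.repeat(template.node_ids, n_trials_per_node)
    order = rng.permutation(node_labels.size)
    node_labels = np.asarray(node_labels)[order]
    node_index = {nd: k for k, nd in enumerate(template.node_ids)}
    idx = np.array([node_index[nd] for nd in node_labels])
    counts = rng.poisson(rates[:, idx])
    return counts, node_labels
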
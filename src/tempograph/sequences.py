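"""Phase-wise stimulus sequence generation.

Each study phase presents 121 stimuli.  During the six exposure phases
(E1–E6) the order is a random walk on the experiment graph, so every
transition is a graph edge ("direct").  During the baseline (PRE) and
read-out (POST) phases the order is a constrained pseudo-random shuffle
containing exactly 60 direct and 60 indirect (non-edge) transitions, with
no immediate repeats.  Exposure-phase stimuli additionally carry a
mirrored/normal flag (60 mirrored, 61 normal, random placement) for the
behavioural mirror task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graphs import GraphSpec

PHASES = ("PRE", "E1", "E2", "E3", "E4", "E5", "E6", "POST")
EXPOSURE_PHASES = PHASES[1:7]

DIRECT = "direct"
INDIRECT = "indirect"

__all__ = [
    "StimulusSequence",
    "PHASES",
    "EXPOSURE_PHASES",
    "generate_random_walk",
    "generate_pseudorandom",
    "assign_mirror_flags",
    "label_transitions",
]


@dataclass(frozen=True)
class StimulusSequence:
    phase: str
    nodes: tuple
    mirrored: tuple = None  # per-position boolean, exposure phases only

    def __post_init__(self):
        if self.mirrored is not None and len(self.mirrored) != len(self.nodes):
            raise ValueError("mirrored flags must match sequence length")

    def __len__(self):
        return len(self.nodes)

    def to_frame(self, g: GraphSpec | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "phase": self.phase,
                "position": np.arange(len(self.nodes)),
                "node": self.nodes,
                "mirrored": self.mirrored
                if self.mirrored is not None
                else [False] * len(self.nodes),
            }
        )
        if g is not None:
            labels = label_transitions(self, g)
            df["transition_label"] = [""] + list(labels)
        return df


def label_transitions(seq: StimulusSequence, g: GraphSpec) -> list:
    """Label each consecutive node pair direct (edge) or indirect (non-edge)."""
    labels = []
    for u, v in zip(seq.nodes[:-1], seq.nodes[1:]):
        if u == v:
            raise ValueError(f"self-repeat {u}->{v}: transition is neither direct nor indirect")
        labels.append(DIRECT if g.is_edge(u, v) else INDIRECT)
    return labels


def generate_random_walk(
    g: GraphSpec, n: int = 121, rng_seed=None, phase: str = "E1"
) -> StimulusSequence:
    """Simple random walk: uniform start, each step uniform over the
    current node's neighbours.  All transitions are edges."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(rng_seed)
    nodes = [g.node_ids[rng.integers(g.n_nodes)]]
    for _ in range(n - 1):
        nodes.append(rng.choice(g.neighbors(nodes[-1])))
    return StimulusSequence(phase, tuple(int(v) for v in nodes))


def _balanced(g: GraphSpec, pair_counts: dict, n_direct: int, n_indirect: int) -> bool:
    """Max-min per-pair spread <= 2 within each used transition category."""
    for is_edge, n_cat in ((True, n_direct), (False, n_indirect)):
        if n_cat == 0:
            continue
        vals = [
            pair_counts.get(frozenset((u, v)), 0)
            for i, u in enumerate(g.node_ids)
            for v in g.node_ids[i + 1 :]
            if g.is_edge(u, v) == is_edge
        ]
        if max(vals) - min(vals) > 2:
            return False
    return True


def generate_pseudorandom(
    g: GraphSpec,
    n_direct: int = 60,
    n_indirect: int = 60,
    rng_seed=None,
    phase: str = "PRE",
    balance_pairs: bool = True,
    max_retries: int = 200,
) -> StimulusSequence:
    """Pseudo-random sequence of ``n_direct + n_indirect + 1`` stimuli whose
    transitions contain exactly ``n_direct`` edges and ``n_indirect``
    non-edges, with no immediate repeats.

    Construction is a randomised greedy walk: at each step the transition
    category is drawn with probability proportional to its remaining budget,
    and the next node is drawn from that category's candidates.  With
    ``balance_pairs`` the draw favours the least-used undirected pairs so
    per-pair presentation counts stay within a spread of ~2.  Dead ends
    trigger a restart; failure after ``max_retries`` raises with the seed.
    """
    rng = np.random.default_rng(rng_seed)
    n_steps = n_direct + n_indirect
    # per-pair presentation caps (ceil of the category average) keep the
    # spread small; attempts exceeding a max-min spread of 2 are rejected
    n_edges = int(g.adjacency.sum() // 2)
    n_nonedges = g.n_nodes * (g.n_nodes - 1) // 2 - n_edges
    caps = {
        DIRECT: int(np.ceil(n_direct / n_edges)) if n_direct else 0,
        INDIRECT: int(np.ceil(n_indirect / n_nonedges)) if n_indirect else 0,
    }
    for _attempt in range(max_retries):
        nodes = [g.node_ids[rng.integers(g.n_nodes)]]
        remaining = {DIRECT: n_direct, INDIRECT: n_indirect}
        pair_counts = {}
        ok = True
        for _ in range(n_steps):
            cur = nodes[-1]
            options = []
            if remaining[DIRECT] > 0:
                options += [(DIRECT, v) for v in g.neighbors(cur)]
            if remaining[INDIRECT] > 0:
                options += [(INDIRECT, v) for v in g.non_neighbors(cur)]
            if not options:
                ok = False
                break
            # draw the category with probability ∝ its remaining budget …
            cats = sorted({c for c, _ in options})
            budgets = np.array([remaining[c] for c in cats], dtype=float)
            cat = cats[rng.choice(len(cats), p=budgets / budgets.sum())]
            cands = [v for c, v in options if c == cat]
            if balance_pairs:
                # … then the least-presented pair within it (random ties),
                # preferring pairs under the category cap
                counts = np.array(
                    [pair_counts.get(frozenset((cur, v)), 0) for v in cands]
                )
                under = counts < caps[cat]
                if under.any():
                    cands = [v for v, u in zip(cands, under) if u]
                    counts = counts[under]
                cands = [v for v, c in zip(cands, counts) if c == counts.min()]
            nxt = cands[rng.integers(len(cands))]
            remaining[cat] -= 1
            pair_counts[frozenset((cur, nxt))] = pair_counts.get(frozenset((cur, nxt)), 0) + 1
            nodes.append(nxt)
        if ok and remaining[DIRECT] == 0 and remaining[INDIRECT] == 0:
            if balance_pairs and not _balanced(g, pair_counts, n_direct, n_indirect):
                continue
            return StimulusSequence(phase, tuple(int(v) for v in nodes))
    raise RuntimeError(
        f"pseudo-random sequence construction failed after {max_retries} "
        f"retries (seed={rng_seed!r}, n_direct={n_direct}, n_indirect={n_indirect})"
    )


def assign_mirror_flags(
    seq: StimulusSequence, n_mirrored: int = 60, rng_seed=None
) -> StimulusSequence:
    """Flag exactly ``n_mirrored`` positions as mirrored, uniformly at random."""
    n = len(seq)
    if n_mirrored > n:
        raise ValueError(f"n_mirrored={n_mirrored} exceeds sequence length {n}")
    rng = np.random.default_rng(rng_seed)
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_mirrored, replace=False)] = True
    return replace(seq, mirrored=tuple(bool(f) for f in flags))
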
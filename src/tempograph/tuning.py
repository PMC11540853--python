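"""Single-neuron classification and receptive-field analyses.

A neuron's *preferred* stimulus is the image with the strongest mean
response-window activity during the baseline phase (PRE).  Relative to the
preferred node, the remaining graph nodes are *direct* (adjacent) or
*indirect* (non-adjacent); those labels are held fixed across phases.

Classification criteria (all one-sided rank tests at alpha = 0.05):

selective
    (1) preferred-stimulus response window > baseline, and
    (2) preferred-stimulus responses > remaining stimuli combined,
    both during PRE.
relational
    selective, and (2) direct > indirect stimuli during E5+E6, and
    (3) direct responses during E5+E6 > during E1+E2.  PRE and POST are
    never used, so PRE-vs-POST contrasts remain unbiased by selection.
diminishing
    selective, and preferred response weaker in E5+E6 than in E1+E2.

Region-level inference uses label permutations: the classification is
re-run under random stimulus (selectivity) or phase (relational,
diminishing) label permutations and the empirical P value is the
proportion of permutations detecting more neurons of the type than
actually observed.

The Wilcoxon signed-rank test needs paired samples; where the two
conditions have unequal trial counts, each trial of the smaller sample is
paired with the mean of a consecutive temporal chunk of the larger one
(an unpaired rank-sum alternative is available via ``method="rank_sum"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests

from .graphs import GraphSpec, INNER, OUTER
from .preprocess import BinnedResponses, response_window_mean

ALPHA = 0.05
PHASE_GROUPS = {
    "E1E2": ("E1", "E2"),
    "E3E4": ("E3", "E4"),
    "E5E6": ("E5", "E6"),
    "POST": ("POST",),
}

__all__ = [
    "NeuronLabel",
    "find_preferred_stimulus",
    "test_selective",
    "test_relational",
    "test_diminishing",
    "classify_neurons",
    "labels_frame",
    "region_proportion_test",
    "relational_population_summary",
    "rf_asymmetry",
    "rf_asymmetry_test",
    "paired_rank_test",
]


@dataclass
class NeuronLabel:
    neuron: int
    region: str
    hemisphere: str
    preferred_node: int | None
    is_selective: bool = False
    is_relational: bool = False
    is_diminishing: bool = False
    p_resp_vs_baseline: float = np.nan
    p_pref_vs_rest: float = np.nan
    p_direct_vs_indirect: float = np.nan
    p_direct_late_vs_early: float = np.nan
    p_pref_late_vs_early: float = np.nan
    direct_nodes: tuple = ()
    indirect_nodes: tuple = ()
    tie: bool = False
    excluded: bool = False
    flags: tuple = ()


def labels_frame(labels) -> pd.DataFrame:
    return pd.DataFrame([vars(l) for l in labels])


def _chunk_means(x: np.ndarray, n: int) -> np.ndarray:
    return np.array([c.mean() for c in np.array_split(x, n)])


def paired_rank_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater",
    method: str = "signed_rank",
) -> float:
    """One-sided test that ``x`` responses exceed ``y`` responses.

    ``signed_rank`` pairs by temporal order, chunk-averaging the longer
    sample down to the shorter one's length; ``rank_sum`` is the unpaired
    Mann-Whitney U alternative.  Degenerate inputs (all differences zero,
    empty samples) return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        return 1.0
    if method == "rank_sum":
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            return 1.0
        return float(mannwhitneyu(x, y, alternative=alternative).pvalue)
    n = min(x.size, y.size)
    xm = _chunk_means(x, n) if x.size > n else x
    ym = _chunk_means(y, n) if y.size > n else y
    d = xm - ym
    if np.all(d == 0):
        return 1.0
    try:
        return float(wilcoxon(xm, ym, alternative=alternative).pvalue)
    except ValueError:
        return 1.0


def find_preferred_stimulus(resp_trials: np.ndarray, nodes: np.ndarray):
    """Preferred node = argmax of per-node mean response; ties broken by
    lowest node id.  Returns ``(node, tie_flag)``; ``(None, False)`` for a
    flat (information-free) neuron."""
    resp_trials = np.asarray(resp_trials, float)
    uniq = np.unique(nodes)
    means = np.array([resp_trials[nodes == u].mean() for u in uniq])
    if np.ptp(resp_trials) == 0:
        return None, False
    best = means.max()
    winners = uniq[np.isclose(means, best, rtol=0, atol=1e-12)]
    return int(winners.min()), len(winners) > 1


def test_selective(
    resp_pre: np.ndarray,
    base_pre: np.ndarray,
    nodes_pre: np.ndarray,
    preferred: int,
    alpha: float = ALPHA,
    method: str = "signed_rank",
):
    """Two-criterion selectivity test during PRE.

    Returns ``(is_selective, p_resp_vs_baseline, p_pref_vs_rest, evaluable)``.
    """
    mask = nodes_pre == preferred
    if mask.sum() < 5:
        return False, np.nan, np.nan, False
    d = resp_pre[mask] - base_pre[mask]
    if np.all(d == 0):
        p1 = 1.0
    else:
        try:
            p1 = float(
                wilcoxon(resp_pre[mask], base_pre[mask], alternative="greater").pvalue
            )
        except ValueError:
            p1 = 1.0
    p2 = paired_rank_test(resp_pre[mask], resp_pre[~mask], "greater", method)
    return bool(p1 < alpha and p2 < alpha), p1, p2, True


def test_relational(
    resp: np.ndarray,
    nodes: np.ndarray,
    phases: np.ndarray,
    direct_nodes,
    indirect_nodes,
    alpha: float = ALPHA,
    method: str = "signed_rank",
):
    """Relational criteria (2) and (3); PRE/POST trials are ignored.

    Returns ``(is_relational_given_selective, p_direct_vs_indirect,
    p_late_vs_early)``.
    """
    late = np.isin(phases, ("E5", "E6"))
    early = np.isin(phases, ("E1", "E2"))
    d_mask = np.isin(nodes, list(direct_nodes))
    i_mask = np.isin(nodes, list(indirect_nodes))
    x_late_direct = resp[late & d_mask]
    if x_late_direct.size == 0 or np.ptp(resp[late | early]) == 0:
        return False, 1.0, 1.0
    p2 = paired_rank_test(x_late_direct, resp[late & i_mask], "greater", method)
    p3 = paired_rank_test(x_late_direct, resp[early & d_mask], "greater", method)
    return bool(p2 < alpha and p3 < alpha), p2, p3


def test_diminishing(
    resp: np.ndarray,
    nodes: np.ndarray,
    phases: np.ndarray,
    preferred: int,
    alpha: float = ALPHA,
    method: str = "signed_rank",
):
    """Preferred response significantly weaker in E5+E6 than in E1+E2."""
    pref = nodes == preferred
    early = np.isin(phases, ("E1", "E2")) & pref
    late = np.isin(phases, ("E5", "E6")) & pref
    p = paired_rank_test(resp[early], resp[late], "greater", method)
    return bool(p < alpha), p


def classify_neurons(
    b: BinnedResponses,
    g: GraphSpec,
    neuron_info: pd.DataFrame,
    response_window: tuple = (0.1, 1.2),
    baseline_window: tuple = (-0.5, 0.0),
    alpha: float = ALPHA,
    method: str = "signed_rank",
) -> list:
    """Classify every neuron of a preprocessed session.

    ``b`` must contain all phases (selection preset); ``neuron_info`` maps
    neuron id -> region/hemisphere.
    """
    rw = response_window_mean(b, response_window, "mean")
    base = response_window_mean(b, baseline_window, "mean")
    nodes = b.events["node"].to_numpy()
    phases = b.events["phase"].to_numpy()
    pre = phases == "PRE"
    info = neuron_info.set_index("neuron")

    labels = []
    for i, nid in enumerate(b.neuron_ids):
        region = info.loc[nid, "region"] if nid in info.index else "unknown"
        hemi = info.loc[nid, "hemisphere"] if nid in info.index else "?"
        lab = NeuronLabel(int(nid), region, hemi, None)
        if nid in b.silent_neurons:
            lab.excluded = True
            lab.flags += ("silent",)
            labels.append(lab)
            continue
        preferred, tie = find_preferred_stimulus(rw[i, pre], nodes[pre])
        if preferred is None:
            lab.excluded = True
            lab.flags += ("flat_in_PRE",)
            labels.append(lab)
            continue
        lab.preferred_node = preferred
        lab.tie = tie
        lab.direct_nodes = tuple(g.neighbors(preferred))
        lab.indirect_nodes = tuple(g.non_neighbors(preferred))
        sel, p1, p2, ok = test_selective(
            rw[i, pre], base[i, pre], nodes[pre], preferred, alpha, method
        )
        lab.is_selective = sel
        lab.p_resp_vs_baseline, lab.p_pref_vs_rest = p1, p2
        if not ok:
            lab.flags += ("too_few_preferred_trials",)
        if sel:
            rel, pr2, pr3 = test_relational(
                rw[i], nodes, phases, lab.direct_nodes, lab.indirect_nodes,
                alpha, method,
            )
            lab.is_relational = rel
            lab.p_direct_vs_indirect, lab.p_direct_late_vs_early = pr2, pr3
            dim, pd_ = test_diminishing(rw[i], nodes, phases, preferred, alpha, method)
            lab.is_diminishing = dim
            lab.p_pref_late_vs_early = pd_
        labels.append(lab)
    return labels


@dataclass
class ProportionTestResult:
    region: str
    neuron_type: str
    n_detected: int
    n_region: int
    p_value: float
    n_perm: int

    @property
    def is_bound(self) -> bool:
        return self.p_value == 0.0

    @property
    def p_report(self) -> str:
        return f"P < {1 / self.n_perm}" if self.is_bound else f"P = {self.p_value}"


def region_proportion_test(
    b: BinnedResponses,
    g: GraphSpec,
    neuron_info: pd.DataFrame,
    region: str,
    neuron_type: str = "selective",
    n_perm: int = 1000,
    rng=None,
    alpha: float = ALPHA,
    method: str = "signed_rank",
    response_window: tuple = (0.1, 1.2),
    baseline_window: tuple = (-0.5, 0.0),
) -> ProportionTestResult:
    """Permutation test for an above-chance proportion of a neuron type.

    Stimulus labels are permuted for the selectivity criterion; exposure
    phase labels for the relational/diminishing criteria (selectivity is
    invariant under phase permutation and is therefore carried over).
    The empirical P value counts permutations detecting at least as many
    neurons as observed (ties included — detected counts are small
    integers, so the strict rule would be anticonservative); p = 0 means
    P < 1/n_perm.
    """
    if neuron_type not in ("selective", "relational", "diminishing"):
        raise ValueError(f"unknown neuron type {neuron_type!r}")
    rng = np.random.default_rng(rng)
    info = neuron_info.set_index("neuron")
    in_region = np.array(
        [info.loc[n, "region"] == region if n in info.index else False
         for n in b.neuron_ids]
    )
    if in_region.sum() == 0:
        raise ValueError(f"no neurons in region {region!r}")

    rw = response_window_mean(b, response_window, "mean")
    base = response_window_mean(b, baseline_window, "mean")
    nodes = b.events["node"].to_numpy()
    phases = b.events["phase"].to_numpy()
    pre = phases == "PRE"
    expo = np.isin(phases, ("E1", "E2", "E3", "E4", "E5", "E6"))
    idxs = np.flatnonzero(in_region)

    def selectivity(i, npre):
        if np.ptp(rw[i, pre]) == 0:
            return None
        preferred, _ = find_preferred_stimulus(rw[i, pre], npre)
        if preferred is None:
            return None
        sel, _, _, ok = test_selective(
            rw[i, pre], base[i, pre], npre, preferred, alpha, method
        )
        return preferred if (sel and ok) else None

    def count_selective(nodes_pre_by_neuron):
        return sum(
            selectivity(i, nodes_pre_by_neuron[i]) is not None for i in idxs
        )

    def count_phase_type(selective_pref, phases_by_neuron):
        n_hit = 0
        for i, preferred in selective_pref.items():
            ph = phases_by_neuron[i]
            if neuron_type == "relational":
                hit, _, _ = test_relational(
                    rw[i], nodes, ph,
                    g.neighbors(preferred), g.non_neighbors(preferred),
                    alpha, method,
                )
            else:
                hit, _ = test_diminishing(rw[i], nodes, ph, preferred, alpha, method)
            n_hit += hit
        return n_hit

    # ties between a permuted and the observed count are exceedances:
    # detected-neuron counts are small integers, and the strict rule would
    # be anticonservative when many permutations tie with the observation
    exceed = 0
    if neuron_type == "selective":
        observed = count_selective({i: nodes[pre] for i in idxs})
        for _ in range(n_perm):
            c = count_selective({i: rng.permutation(nodes[pre]) for i in idxs})
            exceed += c >= observed
    else:
        # selectivity uses PRE only, which phase permutations leave intact
        selective_pref = {}
        for i in idxs:
            preferred = selectivity(i, nodes[pre])
            if preferred is not None:
                selective_pref[i] = preferred
        observed = count_phase_type(selective_pref, {i: phases for i in selective_pref})
        for _ in range(n_perm):
            perm_phases = {}
            for i in selective_pref:
                ph = phases.copy()
                ph[expo] = rng.permutation(phases[expo])
                perm_phases[i] = ph
            exceed += count_phase_type(selective_pref, perm_phases) >= observed
    return ProportionTestResult(
        region, neuron_type, observed, int(in_region.sum()), exceed / n_perm, n_perm
    )


def relational_population_summary(
    b: BinnedResponses,
    labels,
    baseline_window: tuple = (-0.5, 0.0),
    summary_window: tuple = (0.1, 1.0),
) -> pd.DataFrame:
    """Per-neuron, per-phase normalised response differences.

    For every relational neuron and phase, the difference time course of
    mean responses (direct minus indirect, and preferred minus
    non-preferred) is baseline-corrected, peak-normalised (per neuron,
    across phases, so values lie in [-1, 1]) and averaged over the summary
    window.  Suitable for paired phase contrasts (two-sided signed-rank,
    FDR-corrected across phases).
    """
    nodes = b.events["node"].to_numpy()
    phases = b.events["phase"].to_numpy()
    base_sl = b.bin_slice(baseline_window)
    sum_sl = b.bin_slice(summary_window)
    nid_to_row = {n: i for i, n in enumerate(b.neuron_ids)}
    phase_list = list(dict.fromkeys(phases))
    rows = []
    for lab in labels:
        if not lab.is_relational:
            continue
        i = nid_to_row[lab.neuron]
        curves = {}
        for ph in phase_list:
            m = phases == ph
            d_curve = b.counts[i][m & np.isin(nodes, lab.direct_nodes)].mean(0)
            i_curve = b.counts[i][m & np.isin(nodes, lab.indirect_nodes)].mean(0)
            p_curve = b.counts[i][m & (nodes == lab.preferred_node)].mean(0)
            np_curve = b.counts[i][m & (nodes != lab.preferred_node)].mean(0)
            curves[ph] = (d_curve - i_curve, p_curve - np_curve)
        for k, name in enumerate(("direct_minus_indirect", "preferred_minus_rest")):
            stacked = np.array([curves[ph][k] for ph in phase_list])
            stacked = stacked - stacked[:, base_sl].mean(axis=1, keepdims=True)
            peak = np.abs(stacked).max()
            if peak == 0:
                continue
            stacked = stacked / peak
            for ph, curve in zip(phase_list, stacked):
                rows.append(
                    {
                        "neuron": lab.neuron,
                        "phase": ph,
                        "measure": name,
                        "value": curve[sum_sl].mean(),
                    }
                )
    return pd.DataFrame(rows)


def relational_phase_contrasts(summary: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Two-sided signed-rank contrasts of each phase group against PRE,
    FDR-corrected (Benjamini-Hochberg) across groups."""
    df = summary[summary["measure"] == measure].pivot(
        index="neuron", columns="phase", values="value"
    )
    out = []
    for grp, phs in PHASE_GROUPS.items():
        x = df[list(phs)].mean(axis=1)
        d = x - df["PRE"]
        if np.all(d == 0) or len(d) == 0:
            p = 1.0
        else:
            p = float(wilcoxon(x, df["PRE"]).pvalue)
        out.append({"contrast": f"{grp}_vs_PRE", "median_diff": float(d.median()), "p": p})
    res = pd.DataFrame(out)
    res["p_fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


def _mean_vector(counts_i, mask, sl):
    if mask.sum() == 0:
        return None
    return counts_i[mask][:, sl].mean(axis=0)


def rf_asymmetry(
    b: BinnedResponses,
    labels,
    g: GraphSpec,
    window: tuple = (0.1, 1.0),
    mode: str = "indirect_split",
) -> pd.DataFrame:
    """Receptive-field asymmetry distances per selective neuron.

    ``mode="indirect_split"``: for outer-preferring neurons, the Euclidean
    distance between mean response vectors to indirect-inner vs
    indirect-outer stimuli; for inner-preferring neurons (whose only
    indirect node is outer) the analogous direct-outer vs indirect-outer
    contrast.  ``mode="inner_outer_to_inner"``: distance between responses
    to inner nodes (inner-to-inner) vs between outer- and inner-node
    responses.  All series are centred on PRE (PRE value subtracted), so a
    growing value means a growing response asymmetry.  Expects a z-scored
    tensor.
    """
    nodes = b.events["node"].to_numpy()
    phases = b.events["phase"].to_numpy()
    sl = b.bin_slice(window)
    nid_to_row = {n: i for i, n in enumerate(b.neuron_ids)}
    groups = {"PRE": ("PRE",), **PHASE_GROUPS}
    rows = []
    for lab in labels:
        if not lab.is_selective or lab.excluded:
            continue
        i = nid_to_row[lab.neuron]
        role = g.role_of(lab.preferred_node)
        if mode == "indirect_split":
            if role == OUTER:
                cat_a = [n for n in lab.indirect_nodes if g.role_of(n) == INNER]
                cat_b = [n for n in lab.indirect_nodes if g.role_of(n) == OUTER]
            else:
                cat_a = [n for n in lab.direct_nodes if g.role_of(n) == OUTER]
                cat_b = [n for n in lab.indirect_nodes if g.role_of(n) == OUTER]
        elif mode == "inner_outer_to_inner":
            cat_a = [n for n in g.node_ids
                     if g.role_of(n) == INNER and n != lab.preferred_node]
            cat_b = [n for n in g.node_ids
                     if g.role_of(n) == OUTER and n != lab.preferred_node]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if not cat_a or not cat_b:
            continue
        series = {}
        for gname, phs in groups.items():
            m = np.isin(phases, phs)
            va = _mean_vector(b.counts[i], m & np.isin(nodes, cat_a), sl)
            vb = _mean_vector(b.counts[i], m & np.isin(nodes, cat_b), sl)
            if va is None or vb is None:
                series = None
                break
            series[gname] = float(np.linalg.norm(va - vb))
        if series is None:
            continue
        for gname in PHASE_GROUPS:
            rows.append(
                {
                    "neuron": lab.neuron,
                    "group": role,
                    "phase_pair": gname,
                    "distance": series[gname] - series["PRE"],
                }
            )
    df = pd.DataFrame(rows)
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("need selective neurons preferring both inner and outer nodes")
    return df


def rf_asymmetry_test(df: pd.DataFrame) -> pd.DataFrame:
    """Outer- vs inner-preferring group contrast per phase pair
    (two-sided rank-sum, FDR across phase pairs)."""
    out = []
    for gname in PHASE_GROUPS:
        sub = df[df["phase_pair"] == gname]
        a = sub.loc[sub["group"] == OUTER, "distance"]
        bvals = sub.loc[sub["group"] == INNER, "distance"]
        p = float(mannwhitneyu(a, bvals, alternative="two-sided").pvalue)
        out.append(
            {
                "phase_pair": gname,
                "median_outer": float(a.median()),
                "median_inner": float(bvals.median()),
                "p": p,
            }
        )
    res = pd.DataFrame(out)
    res["p_fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    return res
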
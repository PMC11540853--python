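"""Population decoding and representational geometry.

A Poisson naive-Bayes classifier, trained on summed response-window counts
from the baseline phase (PRE), decodes stimulus identity in every phase
(leave-one-trial-out within PRE).  The analyses then operate on the
decoder's posterior probabilities — pooled by the decoded node's relation
to the presented one (actual / direct / indirect) and compared across
phases with one-sided Kolmogorov–Smirnov tests — and on neural distance
matrices: Euclidean distances between population mean-response vectors per
node pair, compared against graph distance templates by Spearman
correlation (Fisher-transformed), with node-permutation null
distributions, region contrasts, and ablation-robustness curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, spearmanr
from statsmodels.stats.multitest import multipletests

from .graphs import DistanceTemplate, GraphSpec, INNER, OUTER
from .preprocess import BinnedResponses, response_window_mean

__all__ = [
    "PoissonNB",
    "train_poisson_nb",
    "decode",
    "decode_loo",
    "decode_session",
    "decoding_accuracy",
    "accuracy_timecourse",
    "posterior_cdf_compare",
    "node_pairwise_ks",
    "NeuralDistanceMatrix",
    "neural_distance_matrix",
    "pair_contributions",
    "template_fit",
    "fit_series",
    "node_permutation_test",
    "template_contrast",
    "region_contrast",
    "ablation_robustness",
]

CATEGORIES = ("actual", "direct", "indirect")


# --------------------------------------------------------------------------
# Poisson naive Bayes
# --------------------------------------------------------------------------


@dataclass
class PoissonNB:
    """Poisson naive-Bayes classifier with uniform class prior.

    ``rates[i, c]`` is the class-conditional mean summed count of neuron i
    for class c, floored at ``eps`` so zero-count classes keep finite
    log-likelihood.
    """

    classes: np.ndarray
    rates: np.ndarray  # neurons x classes
    eps: float = 0.01

    def log_posterior(self, x: np.ndarray) -> np.ndarray:
        """x: neurons x trials -> trials x classes log posterior."""
        x = np.atleast_2d(np.asarray(x, float))
        log_l = x.T @ np.log(self.rates) - self.rates.sum(axis=0)  # trials x classes
        log_l -= log_l.max(axis=1, keepdims=True)
        return log_l - np.log(np.exp(log_l).sum(axis=1, keepdims=True))

    def posterior(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_posterior(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.log_posterior(x), axis=1)]


def train_poisson_nb(
    counts: np.ndarray, labels: np.ndarray, eps: float = 0.01, classes=None
) -> PoissonNB:
    """Fit per-class Poisson rates from summed counts (neurons x trials).

    ``classes`` fixes the expected class set; a listed class with no
    training trials raises (by default classes are the observed labels).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    counts = np.atleast_2d(np.asarray(counts, float))
    rates = np.empty((counts.shape[0], classes.size))
    for c, cls in enumerate(classes):
        m = labels == cls
        if m.sum() == 0:
            raise ValueError(f"class {cls!r} has zero training trials")
        rates[:, c] = counts[:, m].mean(axis=1)
    return PoissonNB(classes, np.maximum(rates, eps), eps)


def decode(model: PoissonNB, counts: np.ndarray) -> np.ndarray:
    """Posterior probabilities (trials x classes) for test counts."""
    return model.posterior(counts)


def decode_loo(counts: np.ndarray, labels: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Leave-one-trial-out posteriors within one phase.

    Each trial is decoded by a model trained on all other trials, so the
    held-out trial never contributes to its own class rates.
    """
    labels = np.asarray(labels)
    n_trials = counts.shape[1]
    classes = np.unique(labels)
    post = np.empty((n_trials, classes.size))
    mask = np.ones(n_trials, dtype=bool)
    for t in range(n_trials):
        mask[t] = False
        model = train_poisson_nb(counts[:, mask], labels[mask], eps)
        if not np.array_equal(model.classes, classes):
            raise ValueError("a class vanished under leave-one-out")
        post[t] = model.posterior(counts[:, t : t + 1])[0]
        mask[t] = True
    return post


def _categorize(g: GraphSpec, actual: int) -> dict:
    out = {actual: "actual"}
    for n in g.neighbors(actual):
        out[n] = "direct"
    for n in g.non_neighbors(actual):
        out[n] = "indirect"
    return out


def decode_session(
    b: BinnedResponses,
    g: GraphSpec,
    window: tuple = (0.1, 1.0),
    eps: float = 0.01,
    neurons=None,
) -> pd.DataFrame:
    """Decode every trial of a session; long-format posterior table.

    Trains on PRE (leave-one-trial-out within PRE) and tests all phases.
    Returns one row per (trial, node): phase, actual node, posterior
    probability, and the node's category relative to the actual stimulus.
    """
    counts = response_window_mean(b, window, "sum")
    if neurons is not None:
        rows = np.isin(b.neuron_ids, neurons)
        counts = counts[rows]
    phases = b.events["phase"].to_numpy()
    nodes = b.events["node"].to_numpy()
    pre = phases == "PRE"
    classes = np.unique(nodes[pre])
    model = train_poisson_nb(counts[:, pre], nodes[pre], eps)
    post = np.empty((len(phases), classes.size))
    post[pre] = decode_loo(counts[:, pre], nodes[pre], eps)
    post[~pre] = model.posterior(counts[:, ~pre])

    recs = []
    trial_ids = b.events["trial"].to_numpy()
    for t in range(len(phases)):
        cats = _categorize(g, int(nodes[t]))
        for c, cls in enumerate(classes):
            recs.append(
                (trial_ids[t], phases[t], int(nodes[t]), int(cls), post[t, c],
                 cats[int(cls)])
            )
    return pd.DataFrame(
        recs, columns=["trial", "phase", "actual", "node", "probability", "category"]
    )


def decoding_accuracy(table: pd.DataFrame, phase: str = "PRE") -> float:
    """Fraction of trials whose maximum-posterior node is the actual one."""
    sub = table[table["phase"] == phase]
    best = sub.loc[sub.groupby("trial")["probability"].idxmax()]
    return float((best["node"] == best["actual"]).mean())


def accuracy_timecourse(
    b: BinnedResponses, phase: str = "PRE", eps: float = 0.01
) -> pd.DataFrame:
    """Leave-one-trial-out decoding accuracy per time bin within a phase."""
    m = (b.events["phase"] == phase).to_numpy()
    nodes = b.events["node"].to_numpy()[m]
    rows = []
    for k in range(b.n_bins):
        counts = b.counts[:, m, k]
        post = decode_loo(counts, nodes, eps)
        classes = np.unique(nodes)
        acc = float((classes[post.argmax(axis=1)] == nodes).mean())
        rows.append({"bin_start": b.bin_starts[k], "accuracy": acc})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Posterior-distribution comparisons
# --------------------------------------------------------------------------


def _pool(table: pd.DataFrame, phases, category: str) -> np.ndarray:
    if isinstance(phases, str):
        phases = (phases,)
    sub = table[table["phase"].isin(phases) & (table["category"] == category)]
    if sub.empty:
        raise ValueError(f"no posteriors for category {category!r} in {phases}")
    return sub["probability"].to_numpy()


def posterior_cdf_compare(
    table: pd.DataFrame,
    phase_a,
    phase_b,
    category: str,
    direction: str = "increase",
) -> tuple:
    """One-sided KS test between pooled posterior CDFs of two phase groups.

    ``direction="increase"`` tests whether the ``phase_b`` distribution is
    stochastically larger than ``phase_a`` (its CDF lies below);
    ``"decrease"`` tests the opposite.  Returns ``(D, p)``.
    """
    a = _pool(table, phase_a, category)
    bvals = _pool(table, phase_b, category)
    # scipy alternative='less': CDF of first sample <= CDF of second, i.e.
    # first sample stochastically larger
    alt = "less" if direction == "increase" else "greater"
    res = ks_2samp(bvals, a, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def _relative_position(g: GraphSpec, seed: int, node: int) -> str:
    role = g.role_of(node)
    if node == seed:
        return "seed"
    rel = "direct" if g.is_edge(seed, node) else "indirect"
    return f"{rel}-{role}"


def node_pairwise_ks(
    table: pd.DataFrame, g: GraphSpec, seed_role: str, phases
) -> pd.DataFrame:
    """Pairwise KS distances among posterior distributions of node
    positions relative to the presented (seed) node.

    Trials are restricted to those whose actual node has ``seed_role``;
    every posterior entry is labelled by its node's relation to the seed
    (seed / direct-inner / direct-outer / indirect-inner / indirect-outer,
    pooling symmetric positions).  For each pair of relative positions the
    KS z-statistic ``D * sqrt(mn/(m+n))`` and the smaller one-sided p
    (FDR-corrected across pairs) are reported.
    """
    if isinstance(phases, str):
        phases = (phases,)
    sub = table[table["phase"].isin(phases)].copy()
    sub = sub[sub["actual"].map(g.role_of) == seed_role]
    if sub.empty:
        raise ValueError(f"no trials with a {seed_role!r} seed in {phases}")
    sub["relpos"] = [
        _relative_position(g, a, n) for a, n in zip(sub["actual"], sub["node"])
    ]
    groups = {k: v["probability"].to_numpy() for k, v in sub.groupby("relpos")}
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for bname in names[i + 1 :]:
            x, y = groups[a], groups[bname]
            d = ks_2samp(x, y).statistic
            z = d * np.sqrt(len(x) * len(y) / (len(x) + len(y)))
            p_less = ks_2samp(x, y, alternative="less").pvalue
            p_greater = ks_2samp(x, y, alternative="greater").pvalue
            rows.append(
                {
                    "pos_a": a,
                    "pos_b": bname,
                    "ks_z": float(z),
                    "p": float(min(p_less, p_greater)),
                    "direction": "a_larger" if p_less < p_greater else "b_larger",
                }
            )
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# --------------------------------------------------------------------------
# Neural distance matrices and template fits
# --------------------------------------------------------------------------


@dataclass
class NeuralDistanceMatrix:
    phase: str
    matrix: np.ndarray  # node x node, z-scored over off-diagonals
    node_ids: tuple
    neurons_used: tuple
    zscored: bool = True

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], 1)
        return self.matrix[iu]


def pair_contributions(
    b: BinnedResponses, phases, window: tuple = (0.1, 1.0), neurons=None,
    unbiased: bool = True,
):
    """Per-neuron additive contributions to squared node-pair distances.

    Returns ``(contrib, node_ids, neuron_ids)`` where
    ``contrib[i, q] = sum_bins (v_i(node_a) - v_i(node_b))**2`` for pair q
    (upper-triangle order), so any neuron subset's distance matrix is
    ``sqrt(contrib[subset].sum(0))``.  Neurons silent over the selected
    trials (zero variance) are dropped.

    With ``unbiased`` (default) the sampling variance of each node mean is
    subtracted from the squared differences.  The naive estimator inflates
    distances to sparsely sampled nodes — under a random-walk schedule the
    outer (low-degree) nodes are presented about half as often as the inner
    ones, and that noise inflation masquerades as geometry; the correction
    removes it (``unbiased=False`` gives the plain mean-difference
    formula).
    """
    if isinstance(phases, str):
        phases = (phases,)
    m = b.events["phase"].isin(phases).to_numpy()
    nodes = b.events["node"].to_numpy()[m]
    sl = b.bin_slice(window)
    counts = b.counts[:, m, sl]
    if neurons is not None:
        keep = np.isin(b.neuron_ids, neurons)
        counts = counts[keep]
        neuron_ids = b.neuron_ids[keep]
    else:
        neuron_ids = b.neuron_ids
    uniq = np.unique(nodes)
    if uniq.size < 2:
        raise ValueError("need trials from at least 2 nodes")
    means = np.stack(
        [counts[:, nodes == u, :].mean(axis=1) for u in uniq], axis=1
    )  # neurons x nodes x bins
    # variance of each node-mean estimate, per neuron x node x bin
    sem2 = np.stack(
        [
            counts[:, nodes == u, :].var(axis=1, ddof=1) / (nodes == u).sum()
            if (nodes == u).sum() > 1
            else np.zeros(counts.shape[::2])
            for u in uniq
        ],
        axis=1,
    )
    active = counts.reshape(counts.shape[0], -1).std(axis=1) > 0
    means = means[active]
    sem2 = sem2[active]
    neuron_ids = neuron_ids[active]
    ia, ib = np.triu_indices(uniq.size, 1)
    diff = means[:, ia, :] - means[:, ib, :]
    contrib = (diff**2).sum(axis=2)  # neurons x pairs
    if unbiased:
        contrib = contrib - (sem2[:, ia, :] + sem2[:, ib, :]).sum(axis=2)
    return contrib, tuple(int(u) for u in uniq), tuple(neuron_ids)


def _signed_sqrt(x: np.ndarray) -> np.ndarray:
    # bias-corrected squared distances can dip below zero for truly
    # identical responses; the signed root keeps the ordering monotone
    return np.sign(x) * np.sqrt(np.abs(x))


def _zscore_offdiag(sq_dist_by_pair: np.ndarray, n_nodes: int) -> np.ndarray:
    d = _signed_sqrt(sq_dist_by_pair)
    z = (d - d.mean()) / d.std() if d.std() > 0 else d * 0.0
    out = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, 1)
    out[iu] = z
    return out + out.T


def neural_distance_matrix(
    b: BinnedResponses, phases, window: tuple = (0.1, 1.0), neurons=None
) -> NeuralDistanceMatrix:
    """Euclidean distances between population mean responses per node pair,
    z-scored over the off-diagonal entries (per phase group)."""
    contrib, node_ids, used = pair_contributions(b, phases, window, neurons)
    if len(used) < 2:
        raise ValueError("need at least 2 active neurons")
    mat = _zscore_offdiag(contrib.sum(axis=0), len(node_ids))
    phase_name = phases if isinstance(phases, str) else "+".join(phases)
    return NeuralDistanceMatrix(phase_name, mat, node_ids, used)


def _fisher_z(rho: float) -> float:
    rho = float(np.clip(rho, -1 + 1e-6, 1 - 1e-6))
    return float(np.arctanh(rho))


def template_fit(ndm, template: DistanceTemplate) -> float:
    """Fisher-transformed Spearman correlation between the off-diagonal
    entries of an empirical distance matrix and a template."""
    x = ndm.offdiag() if hasattr(ndm, "offdiag") else np.asarray(ndm)[
        np.triu_indices(len(template.node_ids), 1)
    ]
    rho = spearmanr(x, template.offdiag()).statistic
    return _fisher_z(rho)


def fit_series(ndms: dict, template: DistanceTemplate, subtract_pre: bool = True) -> dict:
    """Template fit per phase group, optionally as change from PRE."""
    fits = {ph: template_fit(m, template) for ph, m in ndms.items()}
    if subtract_pre:
        pre = fits["PRE"]
        return {ph: z - pre for ph, z in fits.items() if ph != "PRE"}
    return fits


def _permuted_offdiag(matrix: np.ndarray, perm: np.ndarray) -> np.ndarray:
    pm = matrix[np.ix_(perm, perm)]
    return pm[np.triu_indices(matrix.shape[0], 1)]


def node_permutation_test(
    ndms: dict, template: DistanceTemplate, n_perm: int = 10000, rng=None
) -> pd.DataFrame:
    """Node-relabelling null for PRE-subtracted template fits.

    The same random node permutation is applied to every phase's empirical
    matrix (PRE included) and the PRE-subtracted Fisher-z recomputed; the
    empirical p per phase is the exceedance proportion (p = 0 reported as a
    bound < 1/n_perm by callers).
    """
    rng = np.random.default_rng(rng)
    n = len(template.node_ids)
    t_off = template.offdiag()
    phases = [ph for ph in ndms if ph != "PRE"]
    mats = {ph: ndms[ph].matrix for ph in ndms}

    def fits_for(perm):
        out = {}
        for ph, m in mats.items():
            rho = spearmanr(_permuted_offdiag(m, perm), t_off).statistic
            out[ph] = _fisher_z(rho)
        return {ph: out[ph] - out["PRE"] for ph in phases}

    observed = fits_for(np.arange(n))
    exceed = {ph: 0 for ph in phases}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f = fits_for(perm)
        for ph in phases:
            exceed[ph] += f[ph] > observed[ph]
    return pd.DataFrame(
        {
            "phase": phases,
            "fit_change": [observed[ph] for ph in phases],
            "p": [exceed[ph] / n_perm for ph in phases],
            "n_perm": n_perm,
        }
    )


def template_contrast(
    ndms: dict,
    template_a: DistanceTemplate,
    template_b: DistanceTemplate,
    n_perm: int = 10000,
    rng=None,
) -> pd.DataFrame:
    """Permutation test that template_a fits the (PRE-subtracted) data
    better than template_b, per phase, FDR-corrected across phases."""
    rng = np.random.default_rng(rng)
    n = len(template_a.node_ids)
    phases = [ph for ph in ndms if ph != "PRE"]
    mats = {ph: ndms[ph].matrix for ph in ndms}
    offs = {"a": template_a.offdiag(), "b": template_b.offdiag()}

    def contrast_for(perm):
        z = {}
        for key, t_off in offs.items():
            f = {
                ph: _fisher_z(spearmanr(_permuted_offdiag(m, perm), t_off).statistic)
                for ph, m in mats.items()
            }
            z[key] = {ph: f[ph] - f["PRE"] for ph in phases}
        return {ph: z["a"][ph] - z["b"][ph] for ph in phases}

    observed = contrast_for(np.arange(n))
    exceed = {ph: 0 for ph in phases}
    for _ in range(n_perm):
        c = contrast_for(rng.permutation(n))
        for ph in phases:
            # ties count as exceedances (conservative; the degenerate
            # equal-template contrast is then correctly non-significant)
            exceed[ph] += c[ph] >= observed[ph]
    df = pd.DataFrame(
        {
            "phase": phases,
            "contrast": [observed[ph] for ph in phases],
            "p": [exceed[ph] / n_perm for ph in phases],
            "n_perm": n_perm,
        }
    )
    df["p_fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def _fit_from_contrib(contrib_sum: np.ndarray, t_off: np.ndarray) -> float:
    return _fisher_z(spearmanr(_signed_sqrt(contrib_sum), t_off).statistic)


def region_contrast(
    b: BinnedResponses,
    neuron_info: pd.DataFrame,
    template: DistanceTemplate,
    phases,
    regions: tuple = ("H", "EC"),
    window: tuple = (0.1, 1.0),
    n_subsample: int = 10000,
    n_perm: int = 10000,
    rng=None,
) -> dict:
    """Between-region difference in template fit, neuron-count balanced.

    The larger region is repeatedly subsampled to the smaller one's size;
    the observed statistic is the mean subsampled fit difference
    (regions[0] minus regions[1]).  The null permutes region labels.
    Spearman fits use the additivity of squared Euclidean distances over
    neurons, so each draw is a sum, not a full recomputation.
    """
    rng = np.random.default_rng(rng)
    contrib, node_ids, used = pair_contributions(b, phases, window)
    info = neuron_info.set_index("neuron")
    reg = np.array([info.loc[n, "region"] for n in used])
    idx_a = np.flatnonzero(reg == regions[0])
    idx_b = np.flatnonzero(reg == regions[1])
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"both regions {regions} must contain active neurons")
    t_off = template.offdiag()
    n_small = min(idx_a.size, idx_b.size)

    def statistic(ia, ib, n_draws):
        diffs = np.empty(n_draws)
        for k in range(n_draws):
            sa = ia if ia.size == n_small else rng.choice(ia, n_small, replace=False)
            sb = ib if ib.size == n_small else rng.choice(ib, n_small, replace=False)
            diffs[k] = _fit_from_contrib(contrib[sa].sum(0), t_off) - _fit_from_contrib(
                contrib[sb].sum(0), t_off
            )
        return diffs.mean()

    observed = statistic(idx_a, idx_b, n_subsample)
    pooled = np.concatenate([idx_a, idx_b])
    exceed = 0
    # a lighter subsample average inside the null loop keeps the test
    # unbiased (the null statistic is noisier, which is conservative)
    n_sub_null = max(20, n_subsample // 100)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        exceed += statistic(perm[: idx_a.size], perm[idx_a.size :], n_sub_null) > observed
    return {
        "regions": regions,
        "statistic": float(observed),
        "p": exceed / n_perm,
        "n_perm": n_perm,
        "n_balanced": int(n_small),
    }


def ablation_robustness(
    b: BinnedResponses,
    neuron_info: pd.DataFrame,
    template: DistanceTemplate,
    phases,
    regions: tuple = ("H", "EC"),
    window: tuple = (0.1, 1.0),
    step: float = 0.01,
    max_removed: float = 0.5,
    n_draws: int = 10000,
    n_perm: int = 1000,
    rng=None,
) -> dict:
    """Template-fit degradation under random neuron removal, per region.

    For every removal fraction (multiples of ``step`` up to
    ``max_removed``) random neuron subsets are drawn ``n_draws`` times and
    the template fit recomputed; curves are reported relative to the first
    step.  Regions are compared on the third quartile of the pooled
    step-normalised fit values, with a region-label permutation p value.
    """
    rng = np.random.default_rng(rng)
    contrib, node_ids, used = pair_contributions(b, phases, window)
    info = neuron_info.set_index("neuron")
    reg = np.array([info.loc[n, "region"] for n in used])
    t_off = template.offdiag()
    n_small = min((reg == r).sum() for r in regions)
    if n_small < 4:
        raise ValueError("too few neurons for ablation analysis")
    fracs = np.arange(step, max_removed + 1e-9, step)

    def curves(indices):
        vals = np.empty((fracs.size, n_draws))
        for fi, f in enumerate(fracs):
            keep = max(2, int(round(n_small * (1 - f))))
            for k in range(n_draws):
                sub = rng.choice(indices, keep, replace=False)
                vals[fi, k] = _fit_from_contrib(contrib[sub].sum(0), t_off)
        return vals

    def q3_stat(vals):
        rel = vals - np.median(vals[0])  # relative to the first step
        return float(np.percentile(rel[1:], 75))

    idx = {r: np.flatnonzero(reg == r) for r in regions}
    # balance counts before removal
    idx = {
        r: (v if v.size == n_small else rng.choice(v, n_small, replace=False))
        for r, v in idx.items()
    }
    vals = {r: curves(idx[r]) for r in regions}
    observed = q3_stat(vals[regions[0]]) - q3_stat(vals[regions[1]])
    pooled = np.concatenate([idx[r] for r in regions])
    exceed = 0
    perm_draws = max(50, n_draws // 10)  # lighter draws inside the null loop
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        a, bb = perm[:n_small], perm[n_small : 2 * n_small]

        def light(indices):
            v = np.empty((fracs.size, perm_draws))
            for fi, f in enumerate(fracs):
                keep = max(2, int(round(n_small * (1 - f))))
                for k in range(perm_draws):
                    sub = rng.choice(indices, keep, replace=False)
                    v[fi, k] = _fit_from_contrib(contrib[sub].sum(0), t_off)
            return v

        exceed += abs(q3_stat(light(a)) - q3_stat(light(bb))) > abs(observed)
    summary = {
        r: pd.DataFrame(
            {
                "fraction_removed": fracs,
                "median": np.median(vals[r], axis=1),
                "q1": np.percentile(vals[r], 25, axis=1),
                "q3": np.percentile(vals[r], 75, axis=1),
            }
        )
        for r in regions
    }
    return {
        "curves": summary,
        "statistic": float(observed),
        "p": exceed / n_perm,
        "n_perm": n_perm,
    }
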
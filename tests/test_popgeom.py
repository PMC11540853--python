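import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tempograph import pipeline, popgeom, preprocess
from tempograph.graphs import (
    euclidean_template,
    geodesic_template,
    successor_template,
)
from tempograph.synthdata import simulate_template_population


def brute_force_posterior(rates, x):
    """Independent oracle: enumerate Poisson log-likelihoods per class."""
    from math import lgamma

    n_classes = rates.shape[1]
    logp = np.zeros(n_classes)
    for c in range(n_classes):
        for i in range(rates.shape[0]):
            lam = rates[i, c]
            logp[c] += x[i] * np.log(lam) - lam - lgamma(x[i] + 1)
    w = np.exp(logp - logp.max())
    return w / w.sum()


class TestPoissonNB:
    def test_closed_form_two_class(self):
        model = popgeom.PoissonNB(np.array([1, 2]), np.array([[1.0, 2.0]]))
        post = model.posterior(np.array([[0.0]]))[0]
        assert post[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_identical_rates_uniform_posterior(self):
        model = popgeom.PoissonNB(np.arange(6), np.full((4, 6), 2.5))
        post = model.posterior(np.random.default_rng(0).poisson(2.5, (4, 10)))
        assert np.allclose(post, 1.0 / 6)

    def test_rate_recovery(self):
        rng = np.random.default_rng(0)
        lam = np.array([[1.0, 4.0], [2.0, 0.5]])
        labels = np.repeat([0, 1], 100)
        counts = np.column_stack(
            [rng.poisson(lam[:, c]) for c in labels]
        )
        model = popgeom.train_poisson_nb(counts, labels)
        se = np.sqrt(lam / 100)
        assert np.all(np.abs(model.rates - lam) < 3 * se + 1e-9)

    def test_zero_trial_class_rejected(self):
        with pytest.raises(ValueError, match="zero training trials"):
            popgeom.train_poisson_nb(
                np.ones((2, 3)), np.array([0, 0, 0]), classes=[0, 1]
            )

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            rates = rng.uniform(0.1, 8.0, size=(5, 6))
            model = popgeom.PoissonNB(np.arange(6), rates)
            x = rng.poisson(3.0, 5).astype(float)
            fast = model.posterior(x[:, None])[0]
            slow = brute_force_posterior(rates, x)
            assert np.abs(fast - slow).max() <= 1e-10

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = popgeom.PoissonNB(np.arange(6), rng.uniform(0.5, 5, (8, 6)))
        post = model.posterior(rng.poisson(2, (8, 50)).astype(float))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_neuron_order(self):
        rng = np.random.default_rng(2)
        rates = rng.uniform(0.5, 5, (8, 6))
        x = rng.poisson(2, (8, 20)).astype(float)
        p1 = popgeom.PoissonNB(np.arange(6), rates).posterior(x)
        perm = rng.permutation(8)
        p2 = popgeom.PoissonNB(np.arange(6), rates[perm]).posterior(x[perm])
        assert np.allclose(p1, p2)


class TestLeaveOneOut:
    def test_held_out_trial_excluded_from_rates(self):
        # one extreme outlier trial: with LOO its own value cannot inflate
        # its class rate; verify against a manual refit
        counts = np.array([[1.0, 1.0, 1.0, 50.0, 1.0, 1.0]])
        labels = np.array([0, 1, 0, 1, 0, 1])
        post = popgeom.decode_loo(counts, labels)
        mask = np.ones(6, bool)
        mask[3] = False
        manual = popgeom.train_poisson_nb(counts[:, mask], labels[mask]).posterior(
            counts[:, 3:4]
        )[0]
        assert np.allclose(post[3], manual)

    def test_untuned_population_at_chance(self):
        rng = np.random.default_rng(3)
        labels = np.tile(np.arange(6), 40)
        counts = rng.poisson(3.0, (20, labels.size)).astype(float)
        post = popgeom.decode_loo(counts, labels)
        acc = (np.arange(6)[post.argmax(1)] == labels).mean()
        assert abs(acc - 1 / 6) < 0.08


@pytest.fixture(scope="module")
def posteriors(planted_session, pyramid):
    b = preprocess.bin_spikes(planted_session.spikes, planted_session.events)
    b = preprocess.smooth_moving_sum(b, 0.25)
    b = pipeline.drop_first_trial_per_phase(b)
    return popgeom.decode_session(b, pyramid)


class TestDecodeSession:
    def test_tuned_population_beats_chance_in_pre(self, posteriors):
        assert popgeom.decoding_accuracy(posteriors, "PRE") > 0.5

    def test_posteriors_normalised_per_trial(self, posteriors):
        sums = posteriors.groupby("trial")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_categories_consistent_with_graph(self, posteriors, pyramid):
        row = posteriors.iloc[0]
        sub = posteriors[posteriors["trial"] == row["trial"]]
        actual = sub["actual"].iloc[0]
        for _, r in sub.iterrows():
            if r["node"] == actual:
                assert r["category"] == "actual"
            elif pyramid.is_edge(actual, r["node"]):
                assert r["category"] == "direct"
            else:
                assert r["category"] == "indirect"

    def test_remapping_shifts_posterior_cdfs(self, posteriors):
        d, p = popgeom.posterior_cdf_compare(
            posteriors, "PRE", ("E5", "E6"), "direct", "increase"
        )
        assert p < 0.01
        d2, p2 = popgeom.posterior_cdf_compare(
            posteriors, "PRE", ("E5", "E6"), "actual", "decrease"
        )
        assert p2 < 0.01
        # direction reversal kills significance
        _, p3 = popgeom.posterior_cdf_compare(
            posteriors, "PRE", ("E5", "E6"), "direct", "decrease"
        )
        assert p3 > 0.5

    def test_identical_distributions_not_significant(self, posteriors):
        _, p = popgeom.posterior_cdf_compare(posteriors, "PRE", "PRE", "direct")
        assert p > 0.9


class TestAccuracyTimecourse:
    def test_prestimulus_at_chance_response_above(self, planted_session):
        b = preprocess.bin_spikes(planted_session.spikes, planted_session.events)
        b = preprocess.smooth_moving_sum(b, 0.25)
        b = pipeline.drop_first_trial_per_phase(b)
        tc = popgeom.accuracy_timecourse(b, "PRE")
        pre_onset = tc[tc["bin_start"] < -0.4]["accuracy"].mean()
        response = tc[(tc["bin_start"] >= 0.2) & (tc["bin_start"] < 0.8)][
            "accuracy"
        ].mean()
        assert abs(pre_onset - 1 / 6) < 0.12
        assert response > pre_onset + 0.3


class TestNeuralDistanceMatrix:
    def make_binned(self, counts, nodes, phases):
        n_trials = counts.shape[1]
        events = pd.DataFrame(
            {
                "trial": np.arange(n_trials),
                "phase": phases,
                "onset": np.arange(n_trials) * 5.0,
                "node": nodes,
            }
        )
        tensor = np.repeat(counts[:, :, None], 30, axis=2).astype(float)
        return preprocess.BinnedResponses(
            tensor, 0.1, (-1.0, 2.0), np.arange(counts.shape[0]), events
        )

    def test_one_hot_population_distances_degenerate(self):
        # each neuron fires to exactly one node: all off-diagonal distances
        # equal, so the z-scored matrix is ~0
        nodes = np.tile(np.arange(1, 7), 10)
        counts = np.stack([(nodes == n) * 5.0 for n in range(1, 7)])
        b = self.make_binned(counts, nodes, "PRE")
        ndm = popgeom.neural_distance_matrix(b, "PRE")
        assert np.abs(ndm.offdiag()).max() < 1e-9

    def test_silent_neuron_excluded(self):
        nodes = np.tile(np.arange(1, 7), 10)
        counts = np.stack([(nodes == n) * 5.0 for n in range(1, 7)] + [nodes * 0.0])
        b = self.make_binned(counts, nodes, "PRE")
        ndm = popgeom.neural_distance_matrix(b, "PRE")
        assert 6 not in ndm.neurons_used

    def test_planted_template_recovered(self, pyramid):
        t = successor_template(pyramid)
        counts, nodes = simulate_template_population(t, 120, 40, rng_seed=0)
        b = self.make_binned(counts / 30.0, nodes, "E5")
        ndm = popgeom.neural_distance_matrix(b, "E5")
        rho = spearmanr(ndm.offdiag(), t.offdiag()).statistic
        assert rho > 0.8


class TestTemplateFit:
    def test_monotone_map_gives_max_fit(self, pyramid):
        t = geodesic_template(pyramid)
        warped = np.exp(t.matrix)  # monotone transform preserves ranks
        z = popgeom.template_fit(warped, t)
        assert z == pytest.approx(np.arctanh(1 - 1e-6), rel=1e-6)

    def test_random_matrix_near_zero(self, pyramid):
        rng = np.random.default_rng(0)
        zs = []
        for _ in range(50):
            m = rng.normal(size=(6, 6))
            m = m + m.T
            zs.append(popgeom.template_fit(m, geodesic_template(pyramid)))
        assert abs(np.mean(zs)) < 0.15

    def test_subtract_pre_of_identical_series_is_zero(self, pyramid):
        t = successor_template(pyramid)
        rng = np.random.default_rng(1)
        m = rng.normal(size=(6, 6))
        m = m + m.T
        ndms = {"PRE": m, "E1E2": m.copy()}

        class Wrap:
            def __init__(self, mat):
                self.matrix = mat

            def offdiag(self):
                return self.matrix[np.triu_indices(6, 1)]

        fits = popgeom.fit_series({k: Wrap(v) for k, v in ndms.items()}, t)
        assert fits["E1E2"] == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def planted_ndms(pyramid):
    t = successor_template(pyramid)
    rng = np.random.default_rng(7)
    ndms = {}
    for ph in ["PRE", "E1E2", "E3E4", "E5E6", "POST"]:
        if ph == "PRE":
            m = rng.normal(size=(6, 6))
            m = m + m.T
            np.fill_diagonal(m, 0)
        else:
            m = t.matrix + rng.normal(scale=0.1, size=(6, 6))
            m = (m + m.T) / 2
        ndms[ph] = popgeom.NeuralDistanceMatrix(ph, m, pyramid.node_ids, ())
    return ndms


class TestPermutationTests:
    def test_planted_successor_significant(self, planted_ndms, pyramid):
        res = popgeom.node_permutation_test(
            planted_ndms, successor_template(pyramid), n_perm=1000, rng=0
        )
        assert (res.loc[res["phase"] == "E5E6", "p"] <= 0.001 + 1e-12).all()

    def test_null_p_values_not_extreme(self, pyramid):
        rng = np.random.default_rng(8)
        t = successor_template(pyramid)
        ps = []
        for _ in range(30):
            ndms = {}
            for ph in ["PRE", "E5E6"]:
                m = rng.normal(size=(6, 6))
                m = m + m.T
                ndms[ph] = popgeom.NeuralDistanceMatrix(ph, m, tuple(range(6)), ())
            res = popgeom.node_permutation_test(ndms, t, n_perm=60, rng=rng)
            ps.append(res["p"].iloc[0])
        assert np.mean(ps) > 0.3
        assert np.mean(np.array(ps) <= 0.05) <= 0.2

    def test_template_contrast_detects_planted_difference(self, planted_ndms, pyramid):
        res = popgeom.template_contrast(
            planted_ndms,
            successor_template(pyramid),
            geodesic_template(pyramid),
            n_perm=500,
            rng=0,
        )
        assert res.loc[res["phase"] == "E5E6", "p"].iloc[0] < 0.05

    def test_equal_templates_not_significant(self, planted_ndms, pyramid):
        t = successor_template(pyramid)
        res = popgeom.template_contrast(planted_ndms, t, t, n_perm=100, rng=0)
        assert (res["p"] > 0.5).all()


class TestRegionAnalyses:
    def test_region_contrast_detects_planted_difference(self, pyramid):
        # H neurons carry successor geometry, EC neurons are noise
        t = successor_template(pyramid)
        counts_h, nodes = simulate_template_population(t, 40, 30, rng_seed=0)
        rng = np.random.default_rng(1)
        counts_ec = rng.poisson(3.0, (40, nodes.size))
        counts = np.vstack([counts_h, counts_ec])
        events = pd.DataFrame(
            {
                "trial": np.arange(nodes.size),
                "phase": "E5",
                "onset": np.arange(nodes.size) * 5.0,
                "node": nodes,
            }
        )
        tensor = np.repeat(counts[:, :, None] / 30.0, 30, axis=2).astype(float)
        b = preprocess.BinnedResponses(
            tensor, 0.1, (-1.0, 2.0), np.arange(80), events
        )
        info = pd.DataFrame(
            {
                "neuron": np.arange(80),
                "region": ["H"] * 40 + ["EC"] * 40,
                "hemisphere": "L",
            }
        )
        res = popgeom.region_contrast(
            b, info, t, "E5", n_subsample=100, n_perm=200, rng=2
        )
        assert res["statistic"] > 0
        assert res["p"] < 0.05

    def test_ablation_curves_degrade_with_removal(self, pyramid):
        t = successor_template(pyramid)
        counts_h, nodes = simulate_template_population(t, 40, 30, rng_seed=3)
        counts_ec, _ = simulate_template_population(t, 40, 30, rng_seed=4)
        counts = np.vstack([counts_h, counts_ec])
        events = pd.DataFrame(
            {
                "trial": np.arange(nodes.size),
                "phase": "E5",
                "onset": np.arange(nodes.size) * 5.0,
                "node": nodes,
            }
        )
        tensor = np.repeat(counts[:, :, None] / 30.0, 30, axis=2).astype(float)
        b = preprocess.BinnedResponses(
            tensor, 0.1, (-1.0, 2.0), np.arange(80), events
        )
        info = pd.DataFrame(
            {
                "neuron": np.arange(80),
                "region": ["H"] * 40 + ["EC"] * 40,
                "hemisphere": "L",
            }
        )
        res = popgeom.ablation_robustness(
            b, info, t, "E5", step=0.1, max_removed=0.5,
            n_draws=100, n_perm=30, rng=5,
        )
        curve = res["curves"]["H"]
        # median fit roughly non-increasing with removal fraction
        assert curve["median"].iloc[-1] <= curve["median"].iloc[0] + 0.05


class TestNodePairwiseKs:
    def test_static_tuning_pattern_in_pre(self, planted_session, pyramid):
        b = preprocess.bin_spikes(planted_session.spikes, planted_session.events)
        b = preprocess.smooth_moving_sum(b, 0.25)
        b = pipeline.drop_first_trial_per_phase(b)
        post = popgeom.decode_session(b, pyramid)
        df = popgeom.node_pairwise_ks(post, pyramid, "outer", "PRE")
        seed_rows = df[(df["pos_a"] == "seed") | (df["pos_b"] == "seed")]
        other_rows = df[(df["pos_a"] != "seed") & (df["pos_b"] != "seed")]
        assert seed_rows["ks_z"].min() > other_rows["ks_z"].max()

    def test_missing_role_rejected(self, planted_session, pyramid):
        b = preprocess.bin_spikes(planted_session.spikes, planted_session.events)
        b = preprocess.smooth_moving_sum(b, 0.25)
        b = pipeline.drop_first_trial_per_phase(b)
        post = popgeom.decode_session(b, pyramid)
        with pytest.raises(ValueError):
            popgeom.node_pairwise_ks(
                post[post["phase"] == "MISSING"], pyramid, "outer", "PRE"
            )
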
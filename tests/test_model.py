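"""EDR/CDR sampler behavior: determinism, stopping rule, length laws,
weight distribution, and CSV round trips."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp, kstest, shapiro

from edrnet import Connectome, EDRParameters, fit_decay, sample_cdr, sample_edr
from edrnet.model import realized_lengths


@pytest.fixture(scope="module")
def mouse_D(mouse_fixture):
    return mouse_fixture.distances


def params_for(lam, m=None, rho=None, binwidth=0.4):
    return EDRParameters(
        lambda_=lam, binwidth=binwidth, target_edges=m, target_density=rho
    )


class TestSamplerContracts:
    def test_same_seed_bitwise_identical(self, mouse_D):
        p = params_for(0.78, rho=0.68)
        g1 = sample_edr(mouse_D, p, seed=7)
        g2 = sample_edr(mouse_D, p, seed=7)
        np.testing.assert_array_equal(g1.weights, g2.weights)

    def test_realized_density_exact(self, mouse_D):
        for lam, rho in [(0.78, 0.68), (0.2, 0.3), (0.0, 0.5)]:
            g = sample_edr(mouse_D, params_for(lam, rho=rho), seed=3)
            assert g.n_edges == round(rho * 33 * 32)

    def test_cdr_small_complete_graph_forced(self):
        pts = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        from edrnet import DistanceMatrix

        D = DistanceMatrix.from_coordinates(("a", "b", "c"), pts)
        g = sample_cdr(D, params_for(0.0, m=6), seed=0)
        assert g.n_edges == 6
        assert (g.adjacency + np.eye(3) == 1).all()

    def test_edge_budget_validation(self, mouse_D):
        with pytest.raises(ValueError):
            sample_edr(mouse_D, params_for(0.78, m=33 * 32 + 1), seed=0)

    def test_fln_columns_sum_to_one(self, mouse_fixture):
        g = mouse_fixture.connectome
        fln = g.fln()
        connected = g.weights.sum(axis=0) > 0
        np.testing.assert_allclose(
            fln[:, connected].sum(axis=0), 1.0, atol=1e-9
        )


class TestLengthLaws:
    def test_lambda_zero_is_cdr(self, mouse_D):
        # lambda = 0 encodes the constant distance rule: pooled
        # edge-length samples from the two samplers are indistinguishable
        p = params_for(0.0, rho=0.5)
        le = np.concatenate(
            [
                realized_lengths(sample_edr(mouse_D, p, seed=s), mouse_D)
                for s in range(10)
            ]
        )
        lc = np.concatenate(
            [
                realized_lengths(sample_cdr(mouse_D, p, seed=100 + s), mouse_D)
                for s in range(10)
            ]
        )
        assert ks_2samp(le, lc).pvalue > 0.01

    def test_cdr_lengths_match_interareal_distribution(self, mouse_D):
        # each CDR insertion picks a uniform pair, so edge lengths follow q(d)
        rng = np.random.default_rng(5)
        p = params_for(0.0, rho=0.6)
        lengths = np.concatenate(
            [
                realized_lengths(sample_cdr(mouse_D, p, seed=rng), mouse_D)
                for _ in range(30)
            ]
        )
        pair_d = mouse_D.offdiagonal()
        edges = np.linspace(0, pair_d.max() + 1e-9, 11)
        obs, _ = np.histogram(lengths, bins=edges)
        pair_frac, _ = np.histogram(pair_d, bins=edges)
        expected = pair_frac / pair_frac.sum() * obs.sum()
        keep = expected > 5
        res = chisquare(obs[keep], expected[keep] * obs[keep].sum() / expected[keep].sum())
        assert res.pvalue > 0.01

    def test_cdr_expected_in_degree_binomial(self, mouse_D):
        rho = 0.3
        p = params_for(0.0, rho=rho)
        rng = np.random.default_rng(11)
        degs = np.concatenate(
            [
                sample_cdr(mouse_D, p, seed=rng).adjacency.sum(axis=0)
                for _ in range(1000)
            ]
        )
        expect = 32 * rho
        se = degs.std() / np.sqrt(degs.size)
        assert abs(degs.mean() - expect) < 3 * se + 1e-9

    def test_edr_decay_rate_recovered_from_realized_lengths(self, mouse_D):
        # pooled multiplicity-weighted connection lengths follow the
        # generating exponential law
        rng = np.random.default_rng(17)
        p = params_for(0.78, rho=0.68)
        pool = []
        total = 0
        while total < 100_000:
            x = realized_lengths(sample_edr(mouse_D, p, seed=rng), mouse_D)
            pool.append(x)
            total += x.size
        fit = fit_decay(np.concatenate(pool), binwidth=0.5)
        assert fit.lambda_hat == pytest.approx(0.78, abs=0.05)

    def test_memoryless_survival(self):
        # empirical S(a+b)/S(a) ~ S(b) for the sampler's length law
        from edrnet import sample_axon_lengths

        lam = 0.78
        x = sample_axon_lengths(lam, 500_000, 10.1, seed=19)

        def surv(t):
            return np.mean(x > t)

        for a in (0.5 / lam, 1.0 / lam):
            for b in (0.5 / lam, 1.0 / lam):
                assert surv(a + b) == pytest.approx(surv(a) * surv(b), abs=0.01)

    def test_high_gamma_shortens_mean_length(self, mouse_D):
        p_edr = params_for(1.5, rho=0.4)
        p_cdr = params_for(0.0, rho=0.4)
        me = realized_lengths(sample_edr(mouse_D, p_edr, seed=2), mouse_D).mean()
        mc = realized_lengths(sample_cdr(mouse_D, p_cdr, seed=2), mouse_D).mean()
        assert me < mc


class TestWeights:
    def test_log_weights_more_normal_than_raw(self, mouse_fixture):
        w = mouse_fixture.connectome.weights
        w = w[w > 0]
        stat_raw = shapiro(np.asarray(w, dtype=float)).statistic
        stat_log = shapiro(np.log(w)).statistic
        # Shapiro W closer to 1 indicates a better normal fit
        assert stat_log > stat_raw

    def test_weight_span_macaque_like(self):
        from edrnet import macaque_like, make_flne_table

        sp = macaque_like(seed=4)
        fln = make_flne_table(sp.connectome).to_numpy()
        f = fln[np.isfinite(fln) & (fln > 0)]
        assert np.log10(f.max() / f.min()) >= 3.0


class TestRoundTrips:
    def test_dense_csv(self, mouse_fixture, tmp_path):
        g = mouse_fixture.connectome
        g.to_csv(tmp_path / "w.csv")
        g2 = Connectome.from_csv(tmp_path / "w.csv")
        assert g2.labels == g.labels
        np.testing.assert_allclose(g2.weights, g.weights)

    def test_edgelist_csv(self, mouse_fixture, tmp_path):
        g = mouse_fixture.connectome
        g.to_edgelist(tmp_path / "e.csv")
        g2 = Connectome.from_edgelist(tmp_path / "e.csv", g.labels)
        np.testing.assert_allclose(g2.weights, g.weights)
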
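"""Model plumbing: preprocessing, Rhat gating, small-data sampler contracts.

Full-size parameter-recovery checks live in the acceptance suite; here the
fits are deliberately small and test structure, determinism and arithmetic.
"""

import numpy as np
import pytest

from demres import models, phylo, synthetic
from demres.models import (
    ModelConfig,
    ModelError,
    PosteriorSamples,
    check_convergence,
    fit_lifehistory_model,
    fit_residual_correlation_model,
    fit_signal_model,
    phylogenetic_signal,
    preprocess_responses,
)


class TestPreprocess:
    def test_log_then_zscore(self):
        out = preprocess_responses(np.array([1.0, np.e, np.e**2]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=200)
        out = preprocess_responses(x)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_values_named(self):
        with pytest.raises(ModelError, match="pop_b"):
            preprocess_responses([1.0, 0.0, 2.0], ids=["pop_a", "pop_b", "pop_c"])

    def test_constant_vector(self):
        with pytest.raises(ModelError, match="zero variance"):
            preprocess_responses([2.0, 2.0, 2.0])


def _posterior_from(draws: dict) -> PosteriorSamples:
    cfg = ModelConfig(iterations=20, warmup=10, chains=next(iter(draws.values())).shape[0])
    return PosteriorSamples(draws, cfg)


class TestConvergence:
    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(11)
        post = _posterior_from({"x": rng.standard_normal((4, 4000))})
        passed, rh = check_convergence(post)
        assert passed and rh["x"] < 1.01

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(12)
        draws = np.stack([rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)])
        post = _posterior_from({"x": draws})
        passed, rh = check_convergence(post)
        assert not passed and rh["x"] > 1.1
        # plain split-Rhat formula as an order-of-magnitude oracle
        halves = draws.reshape(4, 1000)
        W = halves.var(axis=1, ddof=1).mean()
        B = 1000 * halves.mean(axis=1).var(ddof=1)
        rhat_plain = np.sqrt(((999 / 1000) * W + B / 1000) / W)
        assert rhat_plain > 1.1

    def test_single_chain_rejected(self):
        post = _posterior_from({"x": np.random.default_rng(0).standard_normal((1, 100))})
        with pytest.raises(ModelError, match="2 chains"):
            check_convergence(post)


class TestVarianceDecomposition:
    def test_hand_computed_shares(self):
        draws = {
            "sigma_phylo": np.array([[1.0, 2.0, 0.0]]),
            "sigma_species": np.array([[1.0, 0.0, 1.0]]),
            "sigma_state": np.array([[0.0, 0.0, 0.0]]),
            "sigma_resid": np.array([[np.sqrt(2.0), 1.0, 1.0]]),
            "beta0": np.array([[0.0, 0.0, 0.0]]),
            "phylo_share": np.array([[0.25, 0.8, 0.0]]),
        }
        post = PosteriorSamples(draws, ModelConfig(iterations=4, warmup=1, chains=1))
        dec, summary = phylogenetic_signal(post)
        np.testing.assert_allclose(dec.shares["phylogeny"], [[0.25, 0.8, 0.0]])
        total = sum(dec.shares.values())
        np.testing.assert_allclose(total, 1.0)

    def test_state_can_be_dropped_from_denominator(self):
        draws = {
            "sigma_phylo": np.array([[1.0]]),
            "sigma_species": np.array([[0.0]]),
            "sigma_state": np.array([[1.0]]),
            "sigma_resid": np.array([[1.0]]),
            "beta0": np.array([[0.0]]),
            "phylo_share": np.array([[1 / 3]]),
        }
        post = PosteriorSamples(draws, ModelConfig(iterations=2, warmup=1, chains=1))
        dec, _ = phylogenetic_signal(post, include_state=False)
        np.testing.assert_allclose(dec.shares["phylogeny"], [[0.5]])


@pytest.fixture(scope="module")
def small_signal_data():
    tree = synthetic.generate_yule_tree(25, seed=4)
    vcv = phylo.vcv_from_tree(tree)
    tab, truth = synthetic.simulate_phylo_traits(
        tree, synthetic.TraitSimConfig(sigma2_phylo=0.5, sigma2_resid=0.5, seed=4)
    )
    return tab, vcv


class TestSignalModel:
    def test_seeded_fit_is_reproducible(self, small_signal_data):
        tab, vcv = small_signal_data
        cfg = ModelConfig(iterations=3000, warmup=600, chains=2, seed=99)
        args = (tab["y"].to_numpy(), tab["species_name"].tolist(), tab["state_variable"].tolist(), vcv)
        a = fit_signal_model(*args, cfg)
        b = fit_signal_model(*args, cfg)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])
        assert a.n_draws == cfg.iterations - cfg.warmup

    def test_shares_are_probabilities(self, small_signal_data):
        tab, vcv = small_signal_data
        cfg = ModelConfig(iterations=2000, warmup=500, chains=2, seed=1)
        post = fit_signal_model(
            tab["y"].to_numpy(), tab["species_name"].tolist(), tab["state_variable"].tolist(), vcv, cfg
        )
        dec, _ = phylogenetic_signal(post)
        for arr in dec.shares.values():
            assert ((arr >= 0) & (arr <= 1)).all()

    def test_prior_predictive_intercept_moments(self, small_signal_data):
        tab, vcv = small_signal_data
        cfg = ModelConfig(iterations=60_000, warmup=10_000, chains=2, seed=3)
        post = fit_signal_model(
            tab["y"].to_numpy(),
            tab["species_name"].tolist(),
            tab["state_variable"].tolist(),
            vcv,
            cfg,
            prior_only=True,
        )
        b0 = post.stacked("beta0")
        assert b0.mean() == pytest.approx(0.0, abs=0.6)
        assert b0.std() == pytest.approx(10.0, rel=0.1)

    def test_misaligned_inputs_rejected(self, small_signal_data):
        tab, vcv = small_signal_data
        with pytest.raises(ModelError):
            fit_signal_model(
                tab["y"].to_numpy()[:-3],
                tab["species_name"].tolist(),
                tab["state_variable"].tolist(),
                vcv,
            )

    def test_unknown_species_rejected(self, small_signal_data):
        tab, vcv = small_signal_data
        bad = ["Unknownus ignotus"] * len(tab)
        with pytest.raises(ModelError, match="absent"):
            fit_signal_model(tab["y"].to_numpy(), bad, tab["state_variable"].tolist(), vcv)


@pytest.fixture(scope="module")
def small_trivariate_data():
    table, tree, truth = synthetic.simulate_correlated_components(
        60, np.eye(3), seed=6, populations_per_species=3
    )
    vcv = phylo.vcv_from_tree(tree)
    Y = table[["compensation", "resistance", "recovery_time"]].to_numpy()
    return table, vcv, Y


class TestTrivariateModels:
    def test_residual_correlation_fit_contract(self, small_trivariate_data):
        table, vcv, Y = small_trivariate_data
        cfg = ModelConfig(iterations=400, warmup=150, chains=2, seed=8)
        post, rc = fit_residual_correlation_model(
            Y, table["species_name"].tolist(), table["state_variable"].tolist(), vcv, cfg
        )
        assert post.n_draws == 250
        for name in post.names:
            if name.startswith("rho_"):
                assert (np.abs(post.draws[name]) <= 1).all()
            if name.startswith("sigma_"):
                assert (post.draws[name] > 0).all()
        assert (post.draws["nu"] > 1).all()
        assert set(rc.table.index) == {
            "compensation_resistance",
            "compensation_recovery_time",
            "resistance_recovery_time",
        }

    def test_residual_correlation_determinism(self, small_trivariate_data):
        table, vcv, Y = small_trivariate_data
        cfg = ModelConfig(iterations=200, warmup=80, chains=2, seed=5)
        args = (Y, table["species_name"].tolist(), table["state_variable"].tolist(), vcv)
        a, _ = fit_residual_correlation_model(*args, cfg)
        b, _ = fit_residual_correlation_model(*args, cfg)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_regression_near_collinear_predictors_warn(self, small_trivariate_data):
        table, vcv, Y = small_trivariate_data
        n = len(table)
        rng = np.random.default_rng(0)
        G = rng.standard_normal(n)
        R = G + 1e-3 * rng.standard_normal(n)
        D = rng.standard_normal(n)
        cfg = ModelConfig(iterations=150, warmup=60, chains=2, seed=2)
        with pytest.warns(UserWarning, match="collinear"):
            fit_lifehistory_model(
                Y, G, R, D,
                table["species_name"].tolist(), table["state_variable"].tolist(), vcv, cfg,
            )

    def test_regression_intercept_near_zero_for_centered_data(self, small_trivariate_data):
        table, vcv, Y = small_trivariate_data
        n = len(table)
        rng = np.random.default_rng(9)
        G = rng.standard_normal(n)
        R = rng.standard_normal(n)
        D = rng.standard_normal(n)
        Yc = Y - Y.mean(axis=0)
        cfg = ModelConfig(iterations=1200, warmup=300, chains=2, seed=4)
        post = fit_lifehistory_model(
            Yc, G, R, D,
            table["species_name"].tolist(), table["state_variable"].tolist(), vcv, cfg,
        )
        for rn in models.RESPONSE_NAMES:
            assert abs(post.stacked(f"beta0_{rn}").mean()) < 0.25

    def test_nonfinite_responses_rejected(self, small_trivariate_data):
        table, vcv, Y = small_trivariate_data
        bad = Y.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ModelError, match="non-finite"):
            fit_residual_correlation_model(
                bad, table["species_name"].tolist(), table["state_variable"].tolist(), vcv
            )
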
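"""Component-contribution estimator: exactness on clean data, first-law
additivity of means and covariances, covariance factorization, sampling
and confidence geometry."""

import numpy as np
import pytest
from scipy import stats

from thermoscribe import (
    AqueousConditions,
    CompoundEnsemble,
    EstimationError,
    Pseudoisomer,
    ReactionSpec,
    TrainingSet,
    GroupIncidence,
    ValidationError,
    confidence_ball_constraint,
    predict_multi,
    predict_reaction,
    reaction_transform_offset,
    sample_dg,
    sqrt_covariance,
    standard_dg_prime_multi,
    train,
)
from thermoscribe.fixtures import make_toy_universe


class TestTrain:
    def test_noise_free_predictions_exact(self, noisefree_universe):
        u = noisefree_universe
        model = train(u.ts, u.gi)
        est = predict_multi(model, u.registry, u.reactions)
        assert np.abs(est.mu - u.ts.b).max() <= 1e-8
        assert np.abs(np.diag(est.sigma)).max() <= 1e-8

    def test_one_by_one_system(self):
        ts = TrainingSet(S=np.array([[1.0]]), b=np.array([-10.0]), compound_ids=["local:c"])
        gi = GroupIncidence(G=np.array([[1.0]]), group_names=["g"])
        model = train(ts, gi)
        assert model.f_cc[0] == pytest.approx(-10.0)

    def test_duplicating_all_measurements_is_invariant(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        ts2 = TrainingSet(
            S=np.hstack([u.ts.S, u.ts.S]),
            b=np.concatenate([u.ts.b, u.ts.b]),
            compound_ids=u.ts.compound_ids,
        )
        model2 = train(ts2, u.gi)
        assert np.allclose(model.f_cc, model2.f_cc, atol=1e-8)
        assert np.allclose(model.g_gc, model2.g_gc, atol=1e-8)

    def test_measurement_permutation_invariance(self, noisy_universe):
        u = noisy_universe
        rng = np.random.default_rng(5)
        perm = rng.permutation(u.ts.b.size)
        model = train(u.ts, u.gi)
        model_p = train(
            TrainingSet(S=u.ts.S[:, perm], b=u.ts.b[perm], compound_ids=u.ts.compound_ids),
            u.gi,
        )
        assert np.allclose(model.f_cc, model_p.f_cc, atol=1e-8)
        assert model.mse_rc == pytest.approx(model_p.mse_rc)

    def test_compound_permutation_permutes_outputs(self, noisy_universe):
        u = noisy_universe
        rng = np.random.default_rng(6)
        perm = rng.permutation(u.ts.S.shape[0])
        model = train(u.ts, u.gi)
        model_p = train(
            TrainingSet(
                S=u.ts.S[perm],
                b=u.ts.b,
                compound_ids=[u.ts.compound_ids[i] for i in perm],
            ),
            GroupIncidence(G=u.gi.G[perm], group_names=u.gi.group_names),
        )
        assert np.allclose(model.f_cc[perm], model_p.f_cc, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            TrainingSet(S=np.ones((2, 3)), b=np.zeros(2))
        with pytest.raises(ValidationError):
            train(
                TrainingSet(S=np.ones((2, 1)), b=np.zeros(1)),
                GroupIncidence(G=np.ones((3, 1))),
            )


class TestPredict:
    def test_duplicated_reaction_perfectly_correlated(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        rxn = u.reactions[0]
        est = predict_multi(model, u.registry, [rxn, rxn])
        assert est.sigma[0, 0] == pytest.approx(est.sigma[1, 1], rel=1e-10)
        assert est.sigma[0, 1] == pytest.approx(est.sigma[0, 0], rel=1e-10)

    def test_first_law_additivity(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        r1, r2 = u.reactions[3], u.reactions[7]
        r3 = r1 + r2
        est = predict_multi(model, u.registry, [r1, r2, r3])
        assert est.mu[2] == pytest.approx(est.mu[0] + est.mu[1], abs=1e-8)
        var3 = est.sigma[0, 0] + est.sigma[1, 1] + 2 * est.sigma[0, 1]
        assert est.sigma[2, 2] == pytest.approx(var3, abs=1e-8)

    def test_empty_reaction_zero(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        est = predict_multi(model, u.registry, [ReactionSpec({})])
        assert est.mu[0] == 0.0
        assert est.sigma[0, 0] == 0.0

    def test_group_vector_compound_scored_on_the_fly(self, noisefree_universe):
        """A novel compound defined only by its group vector gets the
        group-additive estimate without retraining."""
        u = noisefree_universe
        model = train(u.ts, u.gi)
        gv = tuple(int(v) for v in u.gi.G[0])
        novel = CompoundEnsemble(
            primary_id="local:novel",
            pseudoisomers=(Pseudoisomer(dgf_chemical=0.0, n_h=0),),
            group_vector=gv,
        )
        u.registry.register(novel)
        # novel is group-identical to compound 0: the exchange reaction is
        # energetically neutral under the group model
        rxn = ReactionSpec({u.ts.compound_ids[0]: -1, "local:novel": 1})
        mu, _sd = predict_reaction(model, u.registry, rxn)
        assert mu == pytest.approx(0.0, abs=1e-8)

    def test_unscorable_compound_named_in_error(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        orphan = CompoundEnsemble(
            primary_id="local:orphan",
            pseudoisomers=(Pseudoisomer(dgf_chemical=0.0, n_h=0),),
        )
        u.registry.register(orphan)
        with pytest.raises(EstimationError, match="orphan"):
            predict_reaction(model, u.registry, ReactionSpec({"local:orphan": 1}))

    def test_out_of_span_reaction_gets_infinite_variance(self):
        """A direction unseen by both layers carries ~mse_inf variance."""
        ids = ["local:c0", "local:c1"]
        ts = TrainingSet(
            S=np.array([[-1.0], [0.0]]), b=np.array([-10.0]), compound_ids=ids
        )
        gi = GroupIncidence(G=np.eye(2), group_names=["g0", "g1"])
        model = train(ts, gi)
        reg = _registry_for(ids)
        _mu, sd = predict_reaction(model, reg, ReactionSpec({"local:c1": 1}))
        assert sd >= np.sqrt(model.mse_inf) * (1 - 1e-9)

    def test_training_reaction_variance_below_mse_inf(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        est = predict_multi(model, u.registry, u.reactions)
        assert np.diag(est.sigma).max() < model.mse_inf


def _registry_for(ids):
    from thermoscribe import CompoundRegistry

    reg = CompoundRegistry()
    for cid in ids:
        reg.register(
            CompoundEnsemble(
                primary_id=cid,
                pseudoisomers=(Pseudoisomer(dgf_chemical=0.0, n_h=0),),
            )
        )
    return reg


class TestTransformedPredictions:
    def test_trivial_universe_matches_chemical(self, noisy_universe):
        u = noisy_universe  # single neutral pseudoisomers everywhere
        model = train(u.ts, u.gi)
        cond = AqueousConditions(ionic_strength=0.0)
        chem = predict_multi(model, u.registry, u.reactions[:4])
        prime = standard_dg_prime_multi(model, u.registry, u.reactions[:4], cond)
        assert np.allclose(chem.mu, prime.mu)
        assert np.allclose(chem.sigma, prime.sigma)

    def test_prime_shift_equals_legendre_offset(self, atp_world):
        """Cross-module consistency: prime minus chemical estimate equals
        the independently computed transform offset."""
        from thermoscribe import parse_reaction

        ids = [c.primary_id for c in atp_world if not c.is_proton]
        rxn = parse_reaction(atp_world, "atp + h2o = adp + pi")
        s_col = np.zeros((len(ids), 1))
        for key, coeff in rxn:
            s_col[ids.index(key), 0] = float(coeff)
        ts = TrainingSet(S=s_col, b=np.array([-35.0]), compound_ids=ids)
        gi = GroupIncidence(G=np.ones((len(ids), 1)), group_names=["g"])
        model = train(ts, gi)
        cond = AqueousConditions(p_h=7.0, p_mg=3.0, ionic_strength=0.1)
        chem = predict_multi(model, atp_world, [rxn])
        prime = standard_dg_prime_multi(model, atp_world, [rxn], cond)
        offset = reaction_transform_offset(atp_world, rxn, cond)
        assert prime.mu[0] - chem.mu[0] == pytest.approx(offset, abs=1e-9)
        assert prime.sigma[0, 0] == pytest.approx(chem.sigma[0, 0])


class TestCovarianceFactorization:
    def test_identity(self):
        q = sqrt_covariance(np.eye(3))
        assert np.allclose(q @ q.T, np.eye(3))

    def test_diagonal(self):
        q = sqrt_covariance(np.diag([4.0, 1.0]))
        assert np.allclose(q @ q.T, np.diag([4.0, 1.0]))
        # columns ordered by descending eigenvalue
        assert np.linalg.norm(q[:, 0]) == pytest.approx(2.0)

    def test_rank_one(self):
        v = np.array([1.0, -2.0, 0.5])
        q = sqrt_covariance(np.outer(v, v))
        assert q.shape == (3, 1)
        assert np.allclose(q @ q.T, np.outer(v, v), atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            sqrt_covariance(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_model_sigma_psd_and_reconstructed(self, noisy_universe):
        u = noisy_universe
        model = train(u.ts, u.gi)
        est = predict_multi(model, u.registry, u.reactions[:10])
        eigvals = np.linalg.eigvalsh(est.sigma)
        assert eigvals.min() >= -1e-6 * max(eigvals.max(), 1.0)
        recon = est.sigma_sqrt @ est.sigma_sqrt.T
        scale = 1.0 + np.abs(est.sigma).max()
        assert np.abs(recon - est.sigma).max() <= 1e-6 * scale


class TestSampling:
    def _correlated_estimate(self, rho=0.8):
        sigma = np.array([[4.0, rho * 2 * 3], [rho * 2 * 3, 9.0]])
        from thermoscribe import EstimateWithUncertainty

        return EstimateWithUncertainty(
            mu=np.array([-10.0, 5.0]),
            sigma=sigma,
            sigma_sqrt=sqrt_covariance(sigma),
        )

    def test_zero_covariance_samples_equal_mu(self):
        from thermoscribe import EstimateWithUncertainty

        est = EstimateWithUncertainty(
            mu=np.array([1.0, 2.0]),
            sigma=np.zeros((2, 2)),
            sigma_sqrt=np.zeros((2, 0)),
        )
        samples = sample_dg(est, 10, seed=0)
        assert np.all(samples == est.mu)

    def test_seed_determinism(self):
        est = self._correlated_estimate()
        assert np.array_equal(sample_dg(est, 100, seed=42), sample_dg(est, 100, seed=42))
        assert not np.array_equal(
            sample_dg(est, 100, seed=42), sample_dg(est, 100, seed=43)
        )

    def test_empirical_correlation(self):
        est = self._correlated_estimate(rho=0.8)
        samples = sample_dg(est, 200_000, seed=7)
        emp = np.corrcoef(samples.T)[0, 1]
        assert emp == pytest.approx(0.8, abs=0.01)
        assert samples.mean(axis=0) == pytest.approx(est.mu, abs=0.05)


class TestConfidenceBall:
    def test_rank_one_sigma_level(self):
        est = TestSampling()._correlated_estimate()
        est.sigma_sqrt = est.sigma_sqrt[:, :1]
        r = confidence_ball_constraint(est, 0.6827)
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_vanishing_confidence(self):
        est = TestSampling()._correlated_estimate()
        assert confidence_ball_constraint(est, 1e-12) < 1e-5

    def test_rank_three_quantile(self):
        from thermoscribe import EstimateWithUncertainty

        est = EstimateWithUncertainty(
            mu=np.zeros(3), sigma=np.eye(3), sigma_sqrt=np.eye(3)
        )
        # independent numeric oracle via the chi-square quantile
        expected = np.sqrt(stats.chi2.ppf(0.95, df=3))
        assert confidence_ball_constraint(est, 0.95) == pytest.approx(expected, rel=1e-9)

    def test_invalid_confidence(self):
        est = TestSampling()._correlated_estimate()
        with pytest.raises(ValidationError):
            confidence_ball_constraint(est, 1.5)


class TestParameterRecovery:
    def test_group_energies_within_two_se(self):
        """With sigma = 1 kJ/mol noise and >=5x measurements per group,
        ~95% of group energies should fall within +/-2 estimated SE."""
        hits, total = 0, 0
        for seed in range(10):
            u = make_toy_universe(
                n_groups=8, n_compounds=24, n_reactions=60, noise_sd=1.0, seed=seed
            )
            model = train(u.ts, u.gi)
            se = np.sqrt(model.mse_gc * np.diag(model.inv_GSGS))
            hits += int(np.sum(np.abs(model.g_gc - u.g_true) <= 2 * se))
            total += u.g_true.size
        assert hits / total >= 0.90
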
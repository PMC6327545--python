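"""Forward-product likelihood against closed forms and path enumeration."""

import numpy as np
import pytest

import reassurehmm as rh
from reassurehmm.core import stationary_distribution
from reassurehmm.likelihood import BatchedLikelihood

from conftest import brute_force_loglik, make_session, random_homogeneous_params


class TestSessionLogLikelihood:
    def test_single_observation_indistinguishable_states(self):
        spec = rh.ModelSpec(n_states=2, initial="estimated")
        params = rh.HMMParameters(
            pis=[0.5, 0.5],
            tpms=np.array([[0.5, 0.5], [0.5, 0.5]]),
            deltas=np.array([0.5, 0.5]),
        )
        ll = rh.session_log_likelihood(make_session([1]), params, spec)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_equal_emissions_reduce_to_bernoulli_product(self):
        # when both states emit with the same probability the latent chain
        # is irrelevant and the likelihood is a plain Bernoulli product
        spec = rh.ModelSpec(n_states=2)
        params = rh.HMMParameters(
            pis=[0.6, 0.6], tpms=np.array([[0.7, 0.3], [0.4, 0.6]])
        )
        ll = rh.session_log_likelihood(make_session([1, 0, 1]), params, spec)
        assert ll == pytest.approx(np.log(0.6 * 0.4 * 0.6), abs=1e-12)

    def test_matches_enumeration_example(self):
        tpm = np.array([[0.7, 0.3], [0.2, 0.8]])
        pis = np.array([0.2, 0.8])
        spec = rh.ModelSpec(n_states=2)
        params = rh.HMMParameters(pis=pis, tpms=tpm)
        obs = [1, 0, 1]
        expected = brute_force_loglik(
            obs, stationary_distribution(tpm), tpm, pis
        )
        ll = rh.session_log_likelihood(make_session(obs), params, spec)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_session_likelihood_is_a_probability(self):
        rng = np.random.default_rng(11)
        spec = rh.ModelSpec(n_states=2)
        for _ in range(50):
            params = random_homogeneous_params(rng)
            obs = rng.integers(0, 2, rng.integers(1, 12))
            ll = rh.session_log_likelihood(make_session(obs), params, spec)
            assert ll <= 0.0
            assert np.isfinite(ll)


class TestJointLogLikelihood:
    def test_single_session_collection(self):
        spec = rh.ModelSpec(n_states=2)
        params = random_homogeneous_params(np.random.default_rng(0))
        s = make_session([0, 1, 1])
        assert rh.joint_log_likelihood([s], params, spec) == pytest.approx(
            rh.session_log_likelihood(s, params, spec), rel=1e-14
        )

    def test_additivity_for_duplicated_sessions(self):
        spec = rh.ModelSpec(n_states=2)
        params = random_homogeneous_params(np.random.default_rng(1))
        s = make_session([1, 0, 0, 1])
        single = rh.session_log_likelihood(s, params, spec)
        assert rh.joint_log_likelihood([s, s], params, spec) == pytest.approx(
            2 * single, rel=1e-14
        )

    def test_permutation_invariance(self):
        spec = rh.ModelSpec(n_states=2)
        rng = np.random.default_rng(2)
        params = random_homogeneous_params(rng)
        sessions = [
            make_session(rng.integers(0, 2, rng.integers(1, 9)), sid=i)
            for i in range(6)
        ]
        a = rh.joint_log_likelihood(sessions, params, spec)
        b = rh.joint_log_likelihood(sessions[::-1], params, spec)
        assert a == pytest.approx(b, rel=1e-14)

    def test_five_random_sessions_match_enumeration(self):
        spec = rh.ModelSpec(n_states=2)
        rng = np.random.default_rng(3)
        params = random_homogeneous_params(rng)
        delta = stationary_distribution(params.tpms[0])
        sessions = [
            make_session(rng.integers(0, 2, rng.integers(1, 9)), sid=i)
            for i in range(5)
        ]
        expected = sum(
            brute_force_loglik(s.observations, delta, params.tpms[0], params.pis)
            for s in sessions
        )
        assert rh.joint_log_likelihood(sessions, params, spec) == pytest.approx(
            expected, rel=1e-10
        )

    def test_empty_collection_rejected(self):
        params = random_homogeneous_params(np.random.default_rng(4))
        with pytest.raises(rh.ReassureHMMError, match="empty"):
            rh.joint_log_likelihood([], params, rh.ModelSpec(n_states=2))


class TestForwardAgainstEnumeration:
    def test_random_instances(self):
        """Forward product equals the sum over all state paths (n <= 10)."""
        rng = np.random.default_rng(5)
        spec = rh.ModelSpec(n_states=2)
        for _ in range(100):
            params = random_homogeneous_params(rng)
            delta = stationary_distribution(params.tpms[0])
            obs = rng.integers(0, 2, rng.integers(1, 11))
            expected = brute_force_loglik(obs, delta, params.tpms[0], params.pis)
            got = rh.session_log_likelihood(make_session(obs), params, spec)
            assert abs(got - expected) / abs(expected) < 1e-10


class TestCovariateLikelihood:
    def test_zero_slopes_equal_homogeneous(self):
        """With all slopes zero the non-homogeneous likelihood collapses to
        the homogeneous one with gamma = expit(intercepts)."""
        from scipy.special import expit

        rng = np.random.default_rng(6)
        cov_spec = rh.ModelSpec(
            n_states=2, covariates=("response_type", "log_dopr"),
            initial="estimated",
        )
        hom_spec = rh.ModelSpec(n_states=2, initial="estimated")
        for _ in range(20):
            b10, b20 = rng.normal(0, 2, 2)
            pis = rng.uniform(0.1, 0.9, 2)
            d1 = rng.uniform(0.1, 0.9)
            betas = np.array([[b10, 0.0, 0.0], [b20, 0.0, 0.0]])
            cov_params = rh.HMMParameters(
                pis=pis, betas=betas, deltas=np.array([d1, 1 - d1])
            )
            g12, g21 = expit(b10), expit(b20)
            hom_params = rh.HMMParameters(
                pis=pis,
                tpms=np.array([[1 - g12, g12], [g21, 1 - g21]]),
                deltas=np.array([d1, 1 - d1]),
            )
            n = rng.integers(2, 10)
            s = make_session(
                rng.integers(0, 2, n),
                durations=rng.lognormal(1.5, 0.5, n),
                responses=rng.integers(0, 2, n),
            )
            assert rh.session_log_likelihood(
                s, cov_params, cov_spec
            ) == pytest.approx(
                rh.session_log_likelihood(s, hom_params, hom_spec), rel=1e-12
            )

    def test_covariate_forward_matches_enumeration(self):
        """Non-homogeneous forward product equals path enumeration with the
        per-step transition matrices built from lagged covariates."""
        from reassurehmm.covariates import build_covariate_rows
        from scipy.special import expit

        rng = np.random.default_rng(7)
        spec = rh.ModelSpec(
            n_states=2, covariates=("log_dopr",), initial="estimated"
        )
        for _ in range(50):
            pis = rng.uniform(0.1, 0.9, 2)
            betas = rng.normal(0, 1.5, (1, 2, 2))
            d1 = rng.uniform(0.1, 0.9)
            params = rh.HMMParameters(
                pis=pis, betas=betas, deltas=np.array([d1, 1 - d1])
            )
            n = rng.integers(2, 9)
            s = make_session(
                rng.integers(0, 2, n), durations=rng.lognormal(1.0, 0.7, n)
            )
            rows = build_covariate_rows(s, spec)
            eta = rows @ betas[0].T
            g12, g21 = expit(eta[:, 0]), expit(eta[:, 1])
            tpms = np.stack(
                [np.array([[1 - a, a], [b, 1 - b]]) for a, b in zip(g12, g21)]
            )
            expected = brute_force_loglik(
                s.observations, np.array([d1, 1 - d1]), tpms, pis
            )
            got = rh.session_log_likelihood(s, params, spec)
            assert got == pytest.approx(expected, rel=1e-10)


class TestBatchedEngine:
    def test_agrees_with_reference_on_mixed_collection(self):
        """Padded batched forward equals the per-session reference for
        ragged lengths, both clinicians, and covariate-driven transitions."""
        rng = np.random.default_rng(8)
        spec = rh.ModelSpec(
            n_states=2, covariates=("log_dopr",), fixed_effects=True,
            initial="estimated",
        )
        sessions = []
        for i in range(12):
            n = int(rng.integers(1, 15))
            sessions.append(
                make_session(
                    rng.integers(0, 2, n),
                    durations=rng.lognormal(1.2, 0.8, n),
                    responses=rng.integers(0, 2, n),
                    clinician_id=int(rng.integers(1, 3)),
                    sid=i,
                )
            )
        params = rh.HMMParameters(
            pis=rng.uniform(0.1, 0.9, 2),
            betas=rng.normal(0, 1, (2, 2, 2)),
            deltas=np.column_stack(
                [rng.uniform(0.2, 0.8, 2), 1 - rng.uniform(0.2, 0.8, 2)]
            ),
        )
        # normalise deltas
        params.deltas = params.deltas / params.deltas.sum(axis=1, keepdims=True)
        engine = BatchedLikelihood(sessions, spec)
        np.testing.assert_allclose(
            engine.joint_log_likelihood(params),
            rh.joint_log_likelihood(sessions, params, spec),
            rtol=1e-12,
        )
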
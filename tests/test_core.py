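"""Core types: stationary laws, parameter bijection, emission matrices."""

import numpy as np
import pytest
from scipy import linalg

import reassurehmm as rh
from reassurehmm.core import STOCHASTIC_TOL, stationary_distribution

from conftest import make_session


class TestStationaryDistribution:
    def test_symmetric_chain_is_uniform(self):
        delta = stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        np.testing.assert_allclose(delta, [0.5, 0.5], atol=1e-12)

    def test_matches_eigenvector_oracle_at_published_estimates(self):
        # independent oracle: left eigenvector for eigenvalue 1 via scipy
        tpm = np.array([[0.735, 0.265], [0.169, 0.831]])
        vals, vecs = linalg.eig(tpm.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        oracle = v / v.sum()
        delta = stationary_distribution(tpm)
        np.testing.assert_allclose(delta, oracle, atol=1e-12)
        np.testing.assert_allclose(
            delta, np.array([0.169, 0.265]) / 0.434, atol=1e-12
        )

    def test_absorbing_state(self):
        delta = stationary_distribution(np.array([[1.0, 0.0], [0.3, 0.7]]))
        np.testing.assert_allclose(delta, [1.0, 0.0], atol=1e-12)

    def test_reducible_chain_raises(self):
        with pytest.raises(rh.ReassureHMMError, match="stationary"):
            stationary_distribution(np.eye(2))

    @pytest.mark.parametrize("n_states", [2, 3, 5])
    def test_random_matrices_satisfy_fixed_point(self, n_states):
        rng = np.random.default_rng(42)
        for _ in range(200):
            tpm = rng.uniform(0.01, 1.0, (n_states, n_states))
            tpm /= tpm.sum(axis=1, keepdims=True)
            delta = stationary_distribution(tpm)
            assert np.abs(delta @ tpm - delta).max() < STOCHASTIC_TOL
            assert abs(delta.sum() - 1.0) < STOCHASTIC_TOL

    def test_two_state_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            g12, g21 = rng.uniform(0.01, 0.99, 2)
            tpm = np.array([[1 - g12, g12], [g21, 1 - g21]])
            delta = stationary_distribution(tpm)
            closed = np.array([g21, g12]) / (g12 + g21)
            np.testing.assert_allclose(delta, closed, atol=1e-12)


class TestParameterBijection:
    def test_half_maps_to_zero(self):
        spec = rh.ModelSpec(n_states=1)
        vec = rh.pack_parameters(rh.HMMParameters(pis=[0.5]), spec)
        np.testing.assert_allclose(vec, [0.0], atol=1e-15)
        np.testing.assert_allclose(
            rh.unpack_parameters(vec, spec).pis, [0.5], atol=1e-15
        )

    def test_published_baseline_round_trips(self):
        spec = rh.ModelSpec(n_states=2)
        params = rh.HMMParameters(
            pis=[0.209, 0.782],
            tpms=np.array([[0.735, 0.265], [0.169, 0.831]]),
        )
        back = rh.unpack_parameters(rh.pack_parameters(params, spec), spec)
        np.testing.assert_allclose(back.pis, params.pis, atol=1e-10)
        np.testing.assert_allclose(back.tpms, params.tpms, atol=1e-10)

    @pytest.mark.parametrize("label,spec", rh.study_model_family())
    def test_vector_length_matches_parameter_count(self, label, spec):
        assert rh.parameter_layout(spec).n_parameters == rh.count_parameters(spec)

    @pytest.mark.parametrize(
        "spec",
        [
            rh.ModelSpec(n_states=2),
            rh.ModelSpec(n_states=3),
            rh.ModelSpec(n_states=2, initial="estimated"),
            rh.ModelSpec(n_states=2, covariates=("log_dopr",), initial="estimated"),
            rh.ModelSpec(
                n_states=2,
                covariates=("response_type", "log_dopr"),
                fixed_effects=True,
                initial="estimated",
            ),
            rh.ModelSpec(n_states=2, mixture=True),
            rh.ModelSpec(n_states=2, fixed_effects=True, initial="estimated"),
        ],
    )
    def test_random_round_trips(self, spec):
        rng = np.random.default_rng(
            1000 * spec.n_states + 100 * len(spec.covariates)
            + 10 * spec.fixed_effects + spec.mixture
        )
        n = spec.n_states
        for _ in range(150):
            pis = rng.uniform(0.01, 0.99, n)
            tpms = betas = deltas = None
            if spec.mixture:
                w = rng.dirichlet(np.ones(n))
                w = np.clip(w, 0.01, None)
                w /= w.sum()
                tpms = np.tile(w, (n, 1))
            elif spec.covariates:
                betas = rng.normal(0, 3, (spec.n_sets, 2, spec.n_covariates + 1))
            else:
                tpms = rng.uniform(0.01, 1, (spec.n_sets, n, n))
                tpms /= tpms.sum(axis=2, keepdims=True)
            if spec.initial == "estimated" and not spec.mixture:
                deltas = rng.dirichlet(np.ones(n), size=spec.n_sets)
                deltas = np.clip(deltas, 0.01, None)
                deltas /= deltas.sum(axis=1, keepdims=True)
            params = rh.HMMParameters(pis=pis, tpms=tpms, betas=betas, deltas=deltas)
            vec = rh.pack_parameters(params, spec)
            back = rh.unpack_parameters(vec, spec)
            np.testing.assert_allclose(back.pis, params.pis, atol=1e-10)
            if betas is not None:
                np.testing.assert_allclose(back.betas, betas, atol=1e-10)
            if tpms is not None and not spec.mixture:
                np.testing.assert_allclose(
                    back.tpms, np.asarray(tpms).reshape(spec.n_sets, n, n),
                    atol=1e-10,
                )
            if deltas is not None:
                np.testing.assert_allclose(back.deltas, deltas, atol=1e-10)

    def test_boundary_probability_rejected(self):
        spec = rh.ModelSpec(n_states=2)
        params = rh.HMMParameters(
            pis=[0.0, 0.8], tpms=np.array([[0.5, 0.5], [0.5, 0.5]])
        )
        with pytest.raises(rh.ReassureHMMError, match="strictly inside"):
            rh.pack_parameters(params, spec)


class TestEmissionMatrix:
    def test_cognitive_observation(self):
        np.testing.assert_allclose(
            rh.emission_matrix(np.array([0.2, 0.8]), 1), np.diag([0.2, 0.8])
        )

    def test_affective_complements_published_pis(self):
        np.testing.assert_allclose(
            rh.emission_matrix(np.array([0.209, 0.782]), 0),
            np.diag([0.791, 0.218]),
        )

    def test_uninformative_states(self):
        for x in (0, 1):
            np.testing.assert_allclose(
                rh.emission_matrix(np.array([0.5, 0.5]), x), np.diag([0.5, 0.5])
            )

    def test_invalid_observation_rejected(self):
        with pytest.raises(rh.ReassureHMMError, match="observation"):
            rh.emission_matrix(np.array([0.5, 0.5]), 2)


class TestSessionSeries:
    def test_nonbinary_observation_rejected(self):
        with pytest.raises(rh.ReassureHMMError, match="0/1"):
            make_session([0, 2, 1])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(rh.ReassureHMMError, match="positive"):
            make_session([0, 1], durations=[1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(rh.ReassureHMMError, match="length"):
            rh.SessionSeries(
                session_id="x",
                observations=[0, 1],
                durations=[1.0],
                response_types=[0, 1],
                response_durations=[0.0, 0.0],
            )

    def test_empty_session_rejected(self):
        with pytest.raises(rh.ReassureHMMError, match="at least one"):
            make_session([])


class TestRelabelling:
    def test_states_sorted_ascending_by_pi(self):
        spec = rh.ModelSpec(n_states=2, initial="estimated")
        params = rh.HMMParameters(
            pis=[0.8, 0.2],
            tpms=np.array([[0.7, 0.3], [0.4, 0.6]]),
            deltas=np.array([0.9, 0.1]),
        )
        out = rh.relabel_ascending(params, spec)
        np.testing.assert_allclose(out.pis, [0.2, 0.8])
        np.testing.assert_allclose(out.tpms[0], [[0.6, 0.4], [0.3, 0.7]])
        np.testing.assert_allclose(out.deltas[0], [0.1, 0.9])

    def test_relabelling_preserves_likelihood(self):
        spec = rh.ModelSpec(n_states=2, initial="estimated")
        rng = np.random.default_rng(3)
        sess = [make_session(rng.integers(0, 2, 6)) for _ in range(4)]
        params = rh.HMMParameters(
            pis=[0.9, 0.3],
            tpms=np.array([[0.6, 0.4], [0.2, 0.8]]),
            deltas=np.array([0.25, 0.75]),
        )
        flipped = rh.relabel_ascending(params, spec)
        assert flipped.pis[0] < flipped.pis[1]
        np.testing.assert_allclose(
            rh.joint_log_likelihood(sess, params, spec),
            rh.joint_log_likelihood(sess, flipped, spec),
            rtol=1e-12,
        )
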
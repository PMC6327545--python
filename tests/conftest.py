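"""Shared fixtures and independent brute-force oracles.

The oracles enumerate all N^n latent state paths directly from the model
definition (initial law x transition x emission products) and never touch
the forward/Viterbi implementations they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from reassurehmm import (
    GeneratorConfig,
    HMMParameters,
    ModelSpec,
    SessionSeries,
    simulate_collection,
)
from reassurehmm.core import stationary_distribution


def make_session(obs, durations=None, responses=None, clinician_id=1, sid="s"):
    obs = np.asarray(obs, dtype=int)
    n = obs.shape[0]
    return SessionSeries(
        session_id=sid,
        observations=obs,
        durations=np.ones(n) if durations is None else np.asarray(durations, float),
        response_types=np.zeros(n, int) if responses is None else np.asarray(responses, int),
        response_durations=np.zeros(n),
        clinician_id=clinician_id,
    )


def path_probability(path, obs, delta, tpms, pis):
    """Joint probability of one state path and the observations.

    ``tpms`` is either a single matrix or a sequence of per-step matrices
    (matrix t used for the transition into position t+1, 0-based).
    """
    tpms = np.asarray(tpms, dtype=float)
    per_step = tpms.ndim == 3

    def emis(state, x):
        return pis[state] if x == 1 else 1.0 - pis[state]

    p = delta[path[0]] * emis(path[0], obs[0])
    for t in range(1, len(obs)):
        tpm = tpms[t - 1] if per_step else tpms
        p *= tpm[path[t - 1], path[t]] * emis(path[t], obs[t])
    return p


def brute_force_loglik(obs, delta, tpms, pis, n_states=2):
    """Log of the total probability, summing over every state path."""
    total = 0.0
    for path in itertools.product(range(n_states), repeat=len(obs)):
        total += path_probability(path, obs, delta, tpms, pis)
    return np.log(total)


def brute_force_viterbi(obs, delta, tpms, pis, n_states=2):
    """Exhaustive argmax path (lowest lexicographic path on ties).

    ``itertools.product`` yields paths in lexicographic order and a strict
    ``>`` keeps the first maximiser, matching a lower-state tie-break.
    """
    best_path, best_p = None, -1.0
    for path in itertools.product(range(n_states), repeat=len(obs)):
        p = path_probability(path, obs, delta, tpms, pis)
        if p > best_p:
            best_p, best_path = p, path
    return np.asarray(best_path) + 1, np.log(best_p)


def assert_viterbi_optimal(path, obs, delta, tpms, pis, n_states=2):
    """Check a decoded path attains the exhaustive maximum.

    Exact ties between distinct maximising paths are structural for
    2-state stationary chains (detailed balance makes delta_1 gamma_12 =
    delta_2 gamma_21), so the check is on the attained score: the decoded
    path's own probability must equal the enumerated maximum, and its
    reported log-score must agree with both.
    """
    oracle_path, oracle_score = brute_force_viterbi(
        obs, delta, tpms, pis, n_states=n_states
    )
    own = np.log(path_probability(tuple(path.states - 1), obs, delta, tpms, pis))
    assert own == pytest.approx(oracle_score, rel=1e-10, abs=1e-10)
    assert path.log_score == pytest.approx(oracle_score, rel=1e-10, abs=1e-10)


def random_homogeneous_params(rng, n_states=2, lo=0.05, hi=0.95):
    pis = rng.uniform(lo, hi, n_states)
    tpm = rng.uniform(lo, hi, (n_states, n_states))
    tpm = tpm / tpm.sum(axis=1, keepdims=True)
    return HMMParameters(pis=pis, tpms=tpm)


@pytest.fixture(scope="session")
def study_collection():
    """A default study-emulating synthetic collection (44 sessions)."""
    return simulate_collection(GeneratorConfig(seed=20240101))


@pytest.fixture(scope="session")
def baseline_spec():
    return ModelSpec(n_states=2)
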
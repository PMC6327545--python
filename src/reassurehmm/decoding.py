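"""Global decoding: the single most probable state sequence per session.

The Viterbi recursion maximises the joint probability
Pr(S_1 = s_1, ..., S_n = s_n, X_1 = x_1, ..., X_n = x_n) over all N^n
state paths.  Computation is in log space throughout; exact ties are
broken toward the lower state index at every backtracking step, which
makes decoding deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import HMMParameters, ModelSpec, ReassureHMMError, SessionSeries
from .covariates import build_covariate_rows, transition_probabilities


@dataclass(frozen=True)
class StatePath:
    """Decoded state sequence for one session.

    ``states`` are 1-based labels (state 1 = dominantly affective under the
    package's pi-ascending convention); ``log_score`` is the joint
    log-probability of the path and the observations.
    """

    session_id: object
    states: np.ndarray
    log_score: float

    def __len__(self) -> int:
        return int(self.states.shape[0])


def _log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def viterbi(
    series: SessionSeries, params: HMMParameters, spec: ModelSpec
) -> StatePath:
    """Most probable state path for one session under ``params``."""
    obs = series.observations
    n = len(obs)
    nstate = params.n_states
    c = spec.set_index(series.clinician_id)
    delta = params.initial_distribution(c)
    pis = params.pis

    log_emis = np.where(
        obs[:, None] == 1, _log(pis[None, :]), _log(1.0 - pis[None, :])
    )  # (n, N)

    if spec.covariates:
        rows = build_covariate_rows(series, spec)
        g12, g21 = transition_probabilities(params.betas[c], rows)
        log_tpms = _log(
            np.stack(
                [
                    np.stack([1.0 - g12, g12], axis=1),
                    np.stack([g21, 1.0 - g21], axis=1),
                ],
                axis=1,
            )
        )  # (n-1, N, N)
    else:
        log_tpm = _log(params.tpms[c])
        log_tpms = None

    phi = _log(delta) + log_emis[0]
    back = np.zeros((n, nstate), dtype=np.int64)
    for t in range(1, n):
        lt = log_tpms[t - 1] if log_tpms is not None else log_tpm
        cand = phi[:, None] + lt  # (from, to)
        # argmax over axis 0 returns the lowest index on exact ties
        back[t] = np.argmax(cand, axis=0)
        phi = cand[back[t], np.arange(nstate)] + log_emis[t]

    states = np.empty(n, dtype=np.int64)
    states[-1] = int(np.argmax(phi))
    score = float(phi[states[-1]])
    for t in range(n - 2, -1, -1):
        states[t] = back[t + 1][states[t + 1]]
    return StatePath(
        session_id=series.session_id, states=states + 1, log_score=score
    )


def decode_collection(
    collection: Sequence[SessionSeries], params: HMMParameters, spec: ModelSpec
) -> list[StatePath]:
    """Viterbi decode every session in a collection."""
    if len(collection) == 0:
        raise ReassureHMMError("empty session collection")
    return [viterbi(s, params, spec) for s in collection]


def path_log_probability(
    series: SessionSeries,
    states: np.ndarray,
    params: HMMParameters,
    spec: ModelSpec,
) -> float:
    """Joint log-probability of one explicit state path (1-based labels).

    Direct recomputation used to validate decoded scores.
    """
    s = np.asarray(states, dtype=np.int64) - 1
    obs = series.observations
    c = spec.set_index(series.clinician_id)
    delta = params.initial_distribution(c)
    pis = params.pis
    if spec.covariates:
        rows = build_covariate_rows(series, spec)
        g12, g21 = transition_probabilities(params.betas[c], rows)

    def emis(t: int) -> float:
        p = pis[s[t]]
        return p if obs[t] == 1 else 1.0 - p

    with np.errstate(divide="ignore"):
        total = float(np.log(delta[s[0]])) + float(np.log(emis(0)))
        for t in range(1, len(obs)):
            if spec.covariates:
                tpm = np.array(
                    [[1 - g12[t - 1], g12[t - 1]], [g21[t - 1], 1 - g21[t - 1]]]
                )
            else:
                tpm = params.tpms[c]
            total += float(np.log(tpm[s[t - 1], s[t]])) + float(np.log(emis(t)))
    return total
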
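"""Forward-algorithm likelihood for pooled short binary time series.

The likelihood of one session is the matrix product

    L(theta | x_1..x_n) = delta P(x_1) Gamma_2 P(x_2) ... Gamma_n P(x_n) 1,

where ``P(x)`` is the diagonal matrix of state-conditional Bernoulli
masses and ``Gamma_t`` is the transition matrix into position t (constant
for a homogeneous chain, covariate-driven otherwise).  Sessions are
independent, so the joint log-likelihood of a collection is the sum of the
per-session log-likelihoods.

The forward pass rescales the state vector at every step and accumulates
the log of the scaling constants, so no intermediate product can
underflow regardless of session length.

Two evaluators are provided: a readable per-session reference
(:func:`session_log_likelihood`) and a batched one
(:class:`BatchedLikelihood`) that runs the forward recursion for the whole
collection simultaneously — the optimiser calls the latter thousands of
times, and batching turns the cost from "sum of lengths" Python steps into
"max length" vectorised steps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit

from .core import (
    HMMParameters,
    ModelSpec,
    ReassureHMMError,
    SessionSeries,
    unpack_parameters,
)
from .covariates import build_covariate_rows, transition_probabilities


def session_log_likelihood(
    series: SessionSeries, params: HMMParameters, spec: ModelSpec
) -> float:
    """Log-likelihood of a single session under ``params``.

    Reference implementation: explicit forward recursion with per-step
    rescaling.  Finite for all valid inputs; a length-1 session contributes
    ``log(delta P(x_1) 1)``.
    """
    obs = series.observations
    pis = params.pis
    if not np.isfinite(pis).all():
        raise ReassureHMMError("non-finite emission parameters")
    c = spec.set_index(series.clinician_id)
    delta = params.initial_distribution(c)

    if spec.covariates:
        rows = build_covariate_rows(series, spec)
        g12, g21 = transition_probabilities(params.betas[c], rows)
    else:
        tpm = params.tpms[c]

    def emis(x: int) -> np.ndarray:
        return pis if x == 1 else 1.0 - pis

    alpha = delta * emis(obs[0])
    total = 0.0
    s = alpha.sum()
    if s <= 0:
        return -np.inf
    total += np.log(s)
    alpha = alpha / s
    for t in range(1, len(obs)):
        if spec.covariates:
            gt = np.array([[1 - g12[t - 1], g12[t - 1]],
                           [g21[t - 1], 1 - g21[t - 1]]])
        else:
            gt = tpm
        alpha = (alpha @ gt) * emis(obs[t])
        s = alpha.sum()
        if s <= 0:
            return -np.inf
        total += np.log(s)
        alpha = alpha / s
    return float(total)


def joint_log_likelihood(
    collection: Sequence[SessionSeries], params: HMMParameters, spec: ModelSpec
) -> float:
    """Sum of session log-likelihoods over an independent collection."""
    if len(collection) == 0:
        raise ReassureHMMError("empty session collection")
    return float(
        sum(session_log_likelihood(s, params, spec) for s in collection)
    )


class BatchedLikelihood:
    """Precompiled joint negative log-likelihood for one collection.

    The collection is packed once into padded arrays; each call to
    :meth:`nll` or :meth:`joint_log_likelihood` then runs a single forward
    recursion over the time axis with all sessions in the batch dimension.
    Agrees with the per-session reference to machine precision.
    """

    def __init__(self, collection: Sequence[SessionSeries], spec: ModelSpec):
        if len(collection) == 0:
            raise ReassureHMMError("empty session collection")
        self.spec = spec
        self.n_sessions = len(collection)
        lengths = np.array([len(s) for s in collection])
        self.lengths = lengths
        tmax = lengths.max()
        self.tmax = int(tmax)
        self.obs = np.zeros((self.n_sessions, tmax), dtype=np.int64)
        self.active = np.zeros((self.n_sessions, tmax), dtype=bool)
        self.set_idx = np.array(
            [spec.set_index(s.clinician_id) for s in collection]
        )
        for i, s in enumerate(collection):
            self.obs[i, : lengths[i]] = s.observations
            self.active[i, : lengths[i]] = True
        if spec.covariates:
            k = spec.n_covariates
            # design row used for the transition *into* position t lives at
            # time index t (0-based), i.e. rows[:, t] built from data at t-1
            self.zrows = np.zeros((self.n_sessions, tmax, k + 1))
            for i, s in enumerate(collection):
                if lengths[i] > 1:
                    self.zrows[i, 1: lengths[i]] = build_covariate_rows(s, spec)
        else:
            self.zrows = None

    def joint_log_likelihood(self, params: HMMParameters) -> float:
        spec = self.spec
        n = spec.n_states
        pis = params.pis
        # per-session initial law
        deltas = np.stack(
            [params.initial_distribution(c) for c in range(spec.n_sets)]
        )[self.set_idx]  # (S, N)
        # emission probability of each observed symbol: (S, T, N)
        emis = np.where(self.obs[:, :, None] == 1, pis, 1.0 - pis)

        if spec.covariates:
            # (S, T, 2): eta for rows 1->2 and 2->1, per clinician set
            g12 = np.empty((self.n_sessions, self.tmax))
            g21 = np.empty((self.n_sessions, self.tmax))
            for c in range(spec.n_sets):
                mask = self.set_idx == c
                if not mask.any():
                    continue
                eta = self.zrows[mask] @ params.betas[c].T
                g12[mask] = expit(eta[:, :, 0])
                g21[mask] = expit(eta[:, :, 1])
        else:
            tpms = params.tpms[self.set_idx]  # (S, N, N)

        alpha = deltas * emis[:, 0, :]
        scale = alpha.sum(axis=1)
        ok = scale > 0
        loglik = np.where(ok, np.log(np.where(ok, scale, 1.0)), -np.inf)
        alpha = alpha / np.where(ok, scale, 1.0)[:, None]

        for t in range(1, self.tmax):
            act = self.active[:, t]
            if spec.covariates:
                a0, a1 = alpha[:, 0], alpha[:, 1]
                new = np.stack(
                    [
                        a0 * (1.0 - g12[:, t]) + a1 * g21[:, t],
                        a0 * g12[:, t] + a1 * (1.0 - g21[:, t]),
                    ],
                    axis=1,
                )
            else:
                new = np.einsum("sn,snm->sm", alpha, tpms)
            new = new * emis[:, t, :]
            scale = new.sum(axis=1)
            ok = act & (scale > 0)
            safe = np.where(scale > 0, scale, 1.0)
            loglik = loglik + np.where(act, np.where(
                scale > 0, np.log(safe), -np.inf), 0.0)
            alpha = np.where(act[:, None], new / safe[:, None], alpha)
        return float(loglik.sum())

    def nll_working(self, vec: np.ndarray) -> float:
        """Negative joint log-likelihood at a working-scale vector."""
        try:
            params = unpack_parameters(vec, self.spec)
            val = self.joint_log_likelihood(params)
        except ReassureHMMError:
            # degenerate interior points (e.g. a reducible chain with no
            # unique stationary law) are treated as infinitely bad
            return np.inf
        if not np.isfinite(val):
            return np.inf
        return -val
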
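"""Covariate-driven (non-homogeneous) transition matrices.

Transitions *into* position t (t = 2..n) depend on covariates measured at
position t-1: the lagged patient response type and/or the natural log of
the previous reassurance's duration ("log DOPR").  With this alignment
every transition has a covariate observation and nothing is needed before
the first position.  Off-diagonal transition probabilities come through the
inverse logit,

    gamma12(t) = logit^-1(beta_1' z_t),   gamma21(t) = logit^-1(beta_2' z_t),

with diagonals by complement, so every produced matrix is row-stochastic by
construction for arbitrary finite coefficients.  Under clinician fixed
effects each clinician has their own coefficient set.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .core import (
    HMMParameters,
    ModelSpec,
    ReassureHMMError,
    SessionSeries,
    stationary_distribution,
)


def build_covariate_rows(series: SessionSeries, spec: ModelSpec) -> np.ndarray:
    """Design rows z'_t = (1, z_1, ..., z_k) for transitions into t = 2..n.

    Returns an ``(n-1, k+1)`` array whose row ``t-2`` applies to the
    transition into position ``t`` (1-based) and carries the session's
    covariates observed at position ``t-1``.  Covariate columns follow the
    order of ``spec.covariates``.
    """
    n = len(series)
    k = spec.n_covariates
    rows = np.ones((max(n - 1, 0), k + 1))
    for j, name in enumerate(spec.covariates, start=1):
        if name == "response_type":
            rows[:, j] = series.response_types[:-1]
        elif name == "log_dopr":
            bad = np.flatnonzero(series.durations <= 0)
            if bad.size:
                raise ReassureHMMError(
                    f"session {series.session_id!r}: non-positive duration at "
                    f"position {bad[0] + 1}; log DOPR undefined"
                )
            rows[:, j] = np.log(series.durations[:-1])
        else:  # pragma: no cover - ModelSpec already validates names
            raise ReassureHMMError(f"unknown covariate {name!r}")
    return rows


def transition_matrix_at(
    params: HMMParameters,
    row: np.ndarray,
    clinician_id: int = 1,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """2x2 transition matrix at one covariate row.

    ``row`` is ``(1, z_1, ..., z_k)``.  The clinician picks the coefficient
    set when fixed effects are enabled (``spec`` with ``fixed_effects`` or a
    ``params.betas`` of two sets).
    """
    if params.betas is None:
        raise ReassureHMMError("transition_matrix_at needs covariate coefficients")
    row = np.asarray(row, dtype=float)
    n_sets = params.betas.shape[0]
    if n_sets == 1:
        c = 0
    else:
        if clinician_id not in (1, 2):
            raise ReassureHMMError(
                f"no coefficient set for clinician_id={clinician_id!r}"
            )
        c = clinician_id - 1
    beta = params.betas[c]
    if beta.shape[1] != row.shape[0]:
        raise ReassureHMMError(
            f"coefficient length {beta.shape[1]} does not match "
            f"covariate row length {row.shape[0]}"
        )
    g12 = float(expit(beta[0] @ row))
    g21 = float(expit(beta[1] @ row))
    return np.array([[1.0 - g12, g12], [g21, 1.0 - g21]])


def transition_probabilities(
    betas: np.ndarray, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (gamma12_t, gamma21_t) for a stack of design rows.

    ``betas`` has shape (2, k+1); ``rows`` has shape (m, k+1).
    """
    eta = rows @ betas.T  # (m, 2)
    return expit(eta[:, 0]), expit(eta[:, 1])


def covariate_profile(
    params: HMMParameters,
    grid: np.ndarray,
    clinician_id: int = 1,
    covariate_index: int = 1,
) -> "np.recarray":
    """Transition probabilities and hypothetical stationary law along a grid.

    Fixing the covariate at each grid value treats the chain as homogeneous
    (coefficients held as the true ones): at each point the profile reports
    ``gamma12``, ``gamma21`` and the stationary distribution of the
    resulting 2x2 matrix.  ``covariate_index`` is the design-row position of
    the varied covariate (1 for a single-covariate model).
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if not np.isfinite(grid).all():
        raise ReassureHMMError("profile grid must be finite")
    out = np.recarray(
        grid.shape[0],
        dtype=[("covariate", float), ("gamma12", float), ("gamma21", float),
               ("delta1", float), ("delta2", float)],
    )
    if params.betas is None:
        raise ReassureHMMError("covariate_profile needs covariate coefficients")
    k1 = params.betas.shape[2]
    for i, value in enumerate(grid):
        row = np.zeros(k1)
        row[0] = 1.0
        row[covariate_index] = value
        tpm = transition_matrix_at(params, row, clinician_id)
        g12, g21 = tpm[0, 1], tpm[1, 0]
        if g12 + g21 > 0:
            delta = stationary_distribution(tpm)
        else:  # both transitions impossible: no unique stationary law
            delta = np.array([np.nan, np.nan])
        out[i] = (value, g12, g21, delta[0], delta[1])
    return out
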
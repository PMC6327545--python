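"""Core domain types and parameter-space plumbing.

A *session* is one consultation between a patient and a clinician, recorded
as a short ordered sequence of binary reassurances (1 = cognitive,
0 = affective) together with per-reassurance covariates.  The latent-state
model is an N-state Markov chain with Bernoulli state-dependent
distributions: state i emits a cognitive reassurance with probability
``pi_i``.  Transition probabilities may be constant (homogeneous chain),
clinician-specific (fixed effects), or driven by lagged covariates through
an inverse-logit link.

This module holds the in-memory containers shared by every other module,
the bijection between natural parameters and the unconstrained working
scale used by the optimiser, and the stationary distribution of a
homogeneous chain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

#: Tolerance for row-stochasticity and stationarity checks.
STOCHASTIC_TOL = 1e-10

#: Covariates the model family knows how to build from a session.
KNOWN_COVARIATES = ("response_type", "log_dopr")


class ReassureHMMError(ValueError):
    """Base class for validation and modelling errors in this package."""


# ---------------------------------------------------------------------------
# Session container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionSeries:
    """One session's ordered reassurances with aligned covariates.

    Parameters
    ----------
    session_id
        Opaque session label.
    observations
        Binary reassurance types, 1 = cognitive, 0 = affective.
    durations
        Reassurance durations in seconds; strictly positive.
    response_types
        Binary patient responses, 1 = positive, 0 = neutral.
    response_durations
        Patient response durations in seconds; nonnegative.
    clinician_id
        1 or 2; selects the coefficient set under fixed effects.
    """

    session_id: object
    observations: np.ndarray
    durations: np.ndarray
    response_types: np.ndarray
    response_durations: np.ndarray
    clinician_id: int = 1

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=np.int64)
        dur = np.asarray(self.durations, dtype=float)
        resp = np.asarray(self.response_types, dtype=np.int64)
        rdur = np.asarray(self.response_durations, dtype=float)
        n = obs.shape[0]
        if n < 1:
            raise ReassureHMMError(
                f"session {self.session_id!r}: needs at least one observation"
            )
        for name, arr in (
            ("durations", dur),
            ("response_types", resp),
            ("response_durations", rdur),
        ):
            if arr.shape[0] != n:
                raise ReassureHMMError(
                    f"session {self.session_id!r}: {name} has length "
                    f"{arr.shape[0]}, expected {n}"
                )
        if not np.isin(obs, (0, 1)).all():
            raise ReassureHMMError(
                f"session {self.session_id!r}: observations must be 0/1"
            )
        if not np.isin(resp, (0, 1)).all():
            raise ReassureHMMError(
                f"session {self.session_id!r}: response_types must be 0/1"
            )
        if not (dur > 0).all():
            raise ReassureHMMError(
                f"session {self.session_id!r}: durations must be positive"
            )
        if (rdur < 0).any():
            raise ReassureHMMError(
                f"session {self.session_id!r}: response durations must be >= 0"
            )
        if self.clinician_id not in (1, 2):
            raise ReassureHMMError(
                f"session {self.session_id!r}: clinician_id must be 1 or 2"
            )
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "durations", dur)
        object.__setattr__(self, "response_types", resp)
        object.__setattr__(self, "response_durations", rdur)

    def __len__(self) -> int:
        return int(self.observations.shape[0])


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model family to fit.

    ``covariates`` is an ordered subset of :data:`KNOWN_COVARIATES`; a
    non-empty list makes the chain non-homogeneous, which forces
    ``initial="estimated"``.  ``mixture`` requests the independent-mixture
    special case (identical transition rows: the state at each position is
    drawn afresh from a fixed weight vector).
    """

    n_states: int = 2
    covariates: tuple[str, ...] = ()
    fixed_effects: bool = False
    mixture: bool = False
    initial: str = "stationary"

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.n_states < 1:
            raise ReassureHMMError("n_states must be >= 1")
        unknown = set(self.covariates) - set(KNOWN_COVARIATES)
        if unknown:
            raise ReassureHMMError(f"unknown covariates: {sorted(unknown)}")
        if self.initial not in ("stationary", "estimated"):
            raise ReassureHMMError("initial must be 'stationary' or 'estimated'")
        if self.covariates and self.initial == "stationary":
            raise ReassureHMMError(
                "a covariate-driven chain is non-homogeneous; "
                "use initial='estimated'"
            )
        if self.mixture and (self.covariates or self.fixed_effects):
            raise ReassureHMMError("mixture mode forbids covariates and fixed effects")
        if self.covariates and self.n_states != 2:
            raise ReassureHMMError("covariate-driven transitions require n_states=2")

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def n_sets(self) -> int:
        """Number of transition-parameter sets (2 under fixed effects)."""
        return 2 if self.fixed_effects else 1

    def set_index(self, clinician_id: int) -> int:
        if self.fixed_effects:
            if clinician_id not in (1, 2):
                raise ReassureHMMError(
                    f"no coefficient set for clinician_id={clinician_id!r}"
                )
            return clinician_id - 1
        return 0


# ---------------------------------------------------------------------------
# Natural parameters
# ---------------------------------------------------------------------------


@dataclass
class HMMParameters:
    """Natural-scale parameters for a :class:`ModelSpec`.

    Attributes
    ----------
    pis : ndarray, shape (N,)
        Per-state probability of a cognitive reassurance.
    tpms : ndarray, shape (n_sets, N, N), optional
        Homogeneous transition matrices (one per clinician set).  ``None``
        for covariate-driven models.
    betas : ndarray, shape (n_sets, 2, k+1), optional
        Logit-scale coefficients (intercept first) for the two off-diagonal
        transition rows of a 2-state covariate model.
    deltas : ndarray, shape (n_sets, N), optional
        Initial distributions.  ``None`` means "use the stationary
        distribution of the corresponding homogeneous t.p.m.".
    """

    pis: np.ndarray
    tpms: np.ndarray | None = None
    betas: np.ndarray | None = None
    deltas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pis = np.asarray(self.pis, dtype=float)
        if self.tpms is not None:
            self.tpms = np.asarray(self.tpms, dtype=float)
            if self.tpms.ndim == 2:
                self.tpms = self.tpms[None, :, :]
        if self.betas is not None:
            self.betas = np.asarray(self.betas, dtype=float)
            if self.betas.ndim == 2:
                self.betas = self.betas[None, :, :]
        if self.deltas is not None:
            self.deltas = np.asarray(self.deltas, dtype=float)
            if self.deltas.ndim == 1:
                self.deltas = self.deltas[None, :]

    @property
    def n_states(self) -> int:
        return int(self.pis.shape[0])

    def initial_distribution(self, set_index: int = 0) -> np.ndarray:
        """Initial state distribution for one clinician set."""
        if self.n_states == 1:
            return np.ones(1)
        if self.deltas is not None:
            return self.deltas[set_index]
        if self.tpms is None:
            raise ReassureHMMError(
                "no initial distribution: covariate models need explicit deltas"
            )
        return stationary_distribution(self.tpms[set_index])


def validate_tpm(tpm: np.ndarray, tol: float = STOCHASTIC_TOL) -> np.ndarray:
    """Check that ``tpm`` is a row-stochastic square matrix."""
    tpm = np.asarray(tpm, dtype=float)
    if tpm.ndim != 2 or tpm.shape[0] != tpm.shape[1]:
        raise ReassureHMMError(f"t.p.m. must be square, got shape {tpm.shape}")
    if (tpm < -tol).any() or (tpm > 1 + tol).any():
        raise ReassureHMMError("t.p.m. entries must lie in [0, 1]")
    rows = tpm.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise ReassureHMMError(f"t.p.m. rows must sum to 1, got {rows}")
    return tpm


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution of a homogeneous chain.

    Solves the linear system ``delta (I - Gamma + U) = 1'`` where ``U`` is
    the all-ones matrix; equivalent to the left eigenvector of ``Gamma``
    for eigenvalue 1, normalised to sum to one.

    Raises
    ------
    ReassureHMMError
        If the chain has no unique stationary distribution (e.g. two
        closed communicating classes).
    """
    tpm = validate_tpm(tpm)
    n = tpm.shape[0]
    a = np.eye(n) - tpm + np.ones((n, n))
    try:
        delta = np.linalg.solve(a.T, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ReassureHMMError(
            f"no unique stationary distribution for t.p.m. {tpm.tolist()}"
        ) from exc
    resid = np.abs(delta @ tpm - delta).max()
    if resid > 1e-8 or (delta < -1e-10).any():
        raise ReassureHMMError(
            f"no unique stationary distribution for t.p.m. {tpm.tolist()} "
            f"(residual {resid:.2e})"
        )
    delta = np.clip(delta, 0.0, 1.0)
    return delta / delta.sum()


def emission_matrix(pis: np.ndarray, x: int) -> np.ndarray:
    """Diagonal matrix P(x) of state-conditional Bernoulli masses.

    Entry (i, i) is ``pi_i`` when ``x == 1`` (cognitive) and ``1 - pi_i``
    when ``x == 0`` (affective).
    """
    if x not in (0, 1):
        raise ReassureHMMError(f"observation must be 0 or 1, got {x!r}")
    pis = np.asarray(pis, dtype=float)
    return np.diag(pis if x == 1 else 1.0 - pis)


# ---------------------------------------------------------------------------
# Working-scale parameterisation
# ---------------------------------------------------------------------------
#
# Probabilities map through the logit; rows of an N>=3 t.p.m. map through a
# multinomial logit with the diagonal entry as reference (which reduces to
# the plain logit when N=2); betas pass through unchanged.  The map is a
# bijection on the interior of the parameter space, so the optimiser works
# unconstrained.


def _check_open_unit(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p <= 0).any() or (p >= 1).any():
        raise ReassureHMMError(
            f"{what} must lie strictly inside (0, 1) to be representable "
            f"on the working scale; got {p.tolist()}"
        )
    return p


def _tpm_row_to_working(row: np.ndarray, i: int) -> np.ndarray:
    """Off-diagonal entries of row i -> log-odds against the diagonal."""
    row = _check_open_unit(row, "t.p.m. row entries")
    off = np.delete(row, i)
    return np.log(off / row[i])


def _tpm_row_from_working(eta: np.ndarray, i: int) -> np.ndarray:
    n = eta.shape[0] + 1
    # softmax with the diagonal as the zero-logit reference, guarded
    # against overflow for very large working values
    logits = np.insert(eta, i, 0.0)
    logits = logits - logits.max()
    ex = np.exp(logits)
    return ex / ex.sum()


def _simplex_to_working(w: np.ndarray) -> np.ndarray:
    w = _check_open_unit(w, "probability weights")
    return np.log(w[1:] / w[0])


def _simplex_from_working(eta: np.ndarray) -> np.ndarray:
    logits = np.concatenate(([0.0], eta))
    logits = logits - logits.max()
    ex = np.exp(logits)
    return ex / ex.sum()


@dataclass(frozen=True)
class ParameterLayout:
    """Slice map of the flat working vector for one :class:`ModelSpec`."""

    spec: ModelSpec
    names: tuple[str, ...]
    #: parallel to names: "logit" (back-transform through expit),
    #: "identity" (betas), or "mlogit" (part of a multinomial block)
    transforms: tuple[str, ...]

    @property
    def n_parameters(self) -> int:
        return len(self.names)


def parameter_layout(spec: ModelSpec, n_covariates: int | None = None) -> ParameterLayout:
    """Names and back-transform kinds for the working vector of ``spec``."""
    n = spec.n_states
    k = spec.n_covariates if n_covariates is None else n_covariates
    names: list[str] = []
    trans: list[str] = []

    for i in range(n):
        names.append(f"pi[{i + 1}]")
        trans.append("logit")

    def set_tag(c: int) -> str:
        return f"^{c + 1}" if spec.fixed_effects else ""

    if spec.mixture:
        for j in range(1, n):
            names.append(f"w[{j + 1}]")
            trans.append("logit" if n == 2 else "mlogit")
    elif spec.covariates or k:
        for c in range(spec.n_sets):
            for row, tgt in ((1, "1,"), (2, "2,")):
                for j in range(k + 1):
                    names.append(f"beta{set_tag(c)}[{tgt}{j}]")
                    trans.append("identity")
    elif n > 1:
        for c in range(spec.n_sets):
            for i in range(n):
                for j in range(n):
                    if j != i:
                        names.append(f"gamma{set_tag(c)}[{i + 1},{j + 1}]")
                        trans.append("logit" if n == 2 else "mlogit")

    if spec.initial == "estimated" and n > 1 and not spec.mixture:
        for c in range(spec.n_sets):
            if n == 2:
                names.append(f"delta{set_tag(c)}[1]")
                trans.append("logit")
            else:
                for j in range(1, n):
                    names.append(f"delta{set_tag(c)}[{j + 1}]")
                    trans.append("mlogit")

    return ParameterLayout(spec=spec, names=tuple(names), transforms=tuple(trans))


def pack_parameters(params: HMMParameters, spec: ModelSpec) -> np.ndarray:
    """Natural parameters -> flat unconstrained working vector."""
    n = spec.n_states
    if params.n_states != n:
        raise ReassureHMMError(
            f"parameters have {params.n_states} states, spec has {n}"
        )
    chunks: list[np.ndarray] = [logit(_check_open_unit(params.pis, "pi"))]

    if spec.mixture:
        if params.tpms is None:
            raise ReassureHMMError("mixture parameters need tpms (identical rows)")
        w = params.tpms[0][0]
        chunks.append(_simplex_to_working(w))
    elif spec.covariates:
        if params.betas is None:
            raise ReassureHMMError("covariate model needs betas")
        if params.betas.shape[0] != spec.n_sets:
            raise ReassureHMMError(
                f"expected {spec.n_sets} beta sets, got {params.betas.shape[0]}"
            )
        chunks.append(params.betas.ravel())
    elif n > 1 and not spec.mixture:
        if params.tpms is None:
            raise ReassureHMMError("homogeneous model needs tpms")
        for c in range(spec.n_sets):
            tpm = validate_tpm(params.tpms[c])
            for i in range(n):
                chunks.append(_tpm_row_to_working(tpm[i], i))

    if spec.initial == "estimated" and n > 1 and not spec.mixture:
        if params.deltas is None:
            raise ReassureHMMError("initial='estimated' needs explicit deltas")
        for c in range(spec.n_sets):
            d = _check_open_unit(params.deltas[c], "delta")
            if n == 2:
                chunks.append(np.atleast_1d(logit(d[0])))
            else:
                chunks.append(_simplex_to_working(d))

    vec = np.concatenate([np.atleast_1d(c) for c in chunks])
    if not np.isfinite(vec).all():
        raise ReassureHMMError("non-finite working parameter")
    return vec


def unpack_parameters(vec: np.ndarray, spec: ModelSpec) -> HMMParameters:
    """Flat working vector -> natural parameters (inverse of pack)."""
    vec = np.asarray(vec, dtype=float)
    layout = parameter_layout(spec)
    if vec.shape[0] != layout.n_parameters:
        raise ReassureHMMError(
            f"working vector has length {vec.shape[0]}, "
            f"spec needs {layout.n_parameters}"
        )
    n = spec.n_states
    k = spec.n_covariates
    pos = 0

    pis = expit(vec[pos:pos + n])
    pos += n

    tpms = betas = deltas = None
    if n == 1 and not spec.covariates:
        tpms = np.ones((spec.n_sets, 1, 1))
    if spec.mixture:
        w = _simplex_from_working(vec[pos:pos + n - 1])
        pos += n - 1
        tpms = np.tile(w, (1, n, 1)).reshape(1, n, n)
        deltas = w[None, :]
    elif spec.covariates:
        size = spec.n_sets * 2 * (k + 1)
        betas = vec[pos:pos + size].reshape(spec.n_sets, 2, k + 1)
        pos += size
    elif n > 1:
        tpms = np.empty((spec.n_sets, n, n))
        for c in range(spec.n_sets):
            for i in range(n):
                eta = vec[pos:pos + n - 1]
                pos += n - 1
                tpms[c, i] = _tpm_row_from_working(eta, i)

    if spec.initial == "estimated" and n > 1 and not spec.mixture:
        deltas = np.empty((spec.n_sets, n))
        for c in range(spec.n_sets):
            if n == 2:
                d1 = expit(vec[pos])
                pos += 1
                deltas[c] = (d1, 1.0 - d1)
            else:
                deltas[c] = _simplex_from_working(vec[pos:pos + n - 1])
                pos += n - 1

    return HMMParameters(pis=pis, tpms=tpms, betas=betas, deltas=deltas)


def clip_to_interior(
    params: HMMParameters, eps: float = 1e-12
) -> HMMParameters:
    """Pull saturated probabilities just inside (0, 1).

    An optimiser can drive a probability to exact 0 or 1 in floating
    point; such a point is not representable on the working scale, so
    before repacking it is nudged to the interior by ``eps`` (rows and
    distributions renormalised).  The likelihood change is O(eps).
    """

    def clip_simplex(rows: np.ndarray) -> np.ndarray:
        rows = np.clip(rows, eps, 1.0 - eps)
        return rows / rows.sum(axis=-1, keepdims=True)

    pis = np.clip(params.pis, eps, 1.0 - eps)
    tpms = None if params.tpms is None else clip_simplex(params.tpms)
    deltas = None if params.deltas is None else clip_simplex(params.deltas)
    return HMMParameters(
        pis=pis, tpms=tpms, betas=params.betas, deltas=deltas
    )


def relabel_ascending(params: HMMParameters, spec: ModelSpec) -> HMMParameters:
    """Reorder states so the emission probabilities are ascending.

    State labels in an HMM are arbitrary (label switching); the package
    convention is pi_1 < pi_2 < ..., so state 1 is the dominantly affective
    state and state N the dominantly cognitive one.  Swapping states 1 and 2
    in a covariate model also swaps the two off-diagonal coefficient rows.
    """
    order = np.argsort(params.pis, kind="stable")
    if (order == np.arange(params.n_states)).all():
        return params
    pis = params.pis[order]
    tpms = betas = deltas = None
    if params.tpms is not None:
        tpms = params.tpms[:, order][:, :, order]
    if params.betas is not None:
        # only defined for N=2: reversing the states swaps rows 1->2 and 2->1
        betas = params.betas[:, ::-1, :]
    if params.deltas is not None:
        deltas = params.deltas[:, order]
    return HMMParameters(pis=pis, tpms=tpms, betas=betas, deltas=deltas)
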
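"""Maximum-likelihood fitting and inverse-Hessian confidence intervals.

The joint negative log-likelihood is minimised on the unconstrained
working scale with a quasi-Newton (BFGS) optimiser, restarted from
several random initial points because short pooled series produce
multimodal likelihood surfaces.  Standard errors come from the inverse of
a finite-difference Hessian at the optimum; 95% Wald intervals are formed
on the working scale and back-transformed, so intervals for probabilities
are asymmetric and always inside (0, 1) while intervals for logit-scale
coefficients stay symmetric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess

from . import __version__ as _pkg_version
from .core import (
    clip_to_interior,
    HMMParameters,
    ModelSpec,
    ReassureHMMError,
    SessionSeries,
    pack_parameters,
    parameter_layout,
    relabel_ascending,
    stationary_distribution,
    unpack_parameters,
)
from .covariates import covariate_profile
from .decoding import StatePath, decode_collection
from .likelihood import BatchedLikelihood

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: |beta| above this is flagged: it signals a saturated (near 0/1)
#: transition probability whose scale is no longer interpretable.
LARGE_BETA = 50.0

#: |logit(pi)| above this flags a boundary-adjacent emission probability
#: (pi outside roughly (0.001, 0.999)), typical of degenerate data.
BOUNDARY_LOGIT = 6.9


class FitError(ReassureHMMError):
    """No optimiser restart produced a usable optimum."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitOptions:
    """Knobs for the numerical fit.

    ``n_restarts`` random initialisations are tried and the best local
    optimum kept; ``seed`` makes the whole fit reproducible.  ``gtol`` is
    the working-scale gradient-norm target passed to the optimiser;
    ``extra_starts`` prepends explicit natural-parameter starting points
    (used e.g. to give a covariate model its nested baseline optimum as a
    warm start).
    """

    n_restarts: int = 10
    seed: int | None = None
    gtol: float = 1e-6
    max_iter: int = 500
    extra_starts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ReassureHMMError("n_restarts must be >= 1")


def _random_natural_start(
    rng: np.random.Generator, spec: ModelSpec
) -> HMMParameters:
    """One random interior starting point, drawn on the natural scale."""
    n = spec.n_states
    pis = rng.uniform(0.1, 0.9, size=n)
    tpms = betas = deltas = None
    if spec.mixture:
        w = rng.uniform(0.1, 0.9, size=n)
        w = w / w.sum()
        w = np.clip(w, 0.05, 0.95)
        w = w / w.sum()
        tpms = np.tile(w, (n, 1))[None, :, :]
    elif spec.covariates:
        k = spec.n_covariates
        betas = np.zeros((spec.n_sets, 2, k + 1))
        betas[:, :, 0] = logit(rng.uniform(0.1, 0.9, size=(spec.n_sets, 2)))
        betas[:, :, 1:] = rng.uniform(-1.0, 1.0, size=(spec.n_sets, 2, k))
    elif n > 1:
        tpms = np.empty((spec.n_sets, n, n))
        for c in range(spec.n_sets):
            for i in range(n):
                if n == 2:
                    off = rng.uniform(0.1, 0.9)
                    row = np.full(2, off)
                    row[i] = 1.0 - off
                    tpms[c, i] = row
                else:
                    row = rng.dirichlet(np.ones(n))
                    row = np.clip(row, 0.02, None)
                    tpms[c, i] = row / row.sum()
    if spec.initial == "estimated" and n > 1 and not spec.mixture:
        if n == 2:
            d1 = rng.uniform(0.1, 0.9, size=spec.n_sets)
            deltas = np.stack([d1, 1.0 - d1], axis=1)
        else:
            deltas = np.stack(
                [rng.dirichlet(np.ones(n)) for _ in range(spec.n_sets)]
            )
            deltas = np.clip(deltas, 0.02, None)
            deltas = deltas / deltas.sum(axis=1, keepdims=True)
    return HMMParameters(pis=pis, tpms=tpms, betas=betas, deltas=deltas)


def baseline_warm_start(
    baseline: HMMParameters, spec: ModelSpec
) -> HMMParameters:
    """Embed a fitted homogeneous baseline into a covariate model.

    Intercepts are the logits of the baseline off-diagonal transition
    probabilities, all slopes zero, and the free initial distribution is
    the baseline's stationary law — the covariate model then starts at
    exactly the baseline's likelihood (nested-model warm start).
    """
    if not spec.covariates:
        raise ReassureHMMError("warm start targets a covariate spec")
    k = spec.n_covariates
    base_tpms = baseline.tpms
    if base_tpms is None:
        raise ReassureHMMError("baseline parameters must be homogeneous")
    betas = np.zeros((spec.n_sets, 2, k + 1))
    deltas = np.zeros((spec.n_sets, 2))
    for c in range(spec.n_sets):
        b = base_tpms[min(c, base_tpms.shape[0] - 1)]
        betas[c, 0, 0] = logit(np.clip(b[0, 1], 1e-12, 1 - 1e-12))
        betas[c, 1, 0] = logit(np.clip(b[1, 0], 1e-12, 1 - 1e-12))
        if baseline.deltas is not None:
            deltas[c] = baseline.deltas[min(c, baseline.deltas.shape[0] - 1)]
        else:
            deltas[c] = stationary_distribution(b)
    deltas = np.clip(deltas, 1e-10, 1 - 1e-10)
    deltas = deltas / deltas.sum(axis=1, keepdims=True)
    return HMMParameters(pis=baseline.pis, betas=betas, deltas=deltas)


def fit(
    collection: Sequence[SessionSeries],
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> "HMMFitResult":
    """Fit ``spec`` to a session collection by maximum likelihood."""
    options = options or FitOptions()
    engine = BatchedLikelihood(collection, spec)
    layout = parameter_layout(spec)
    rng = np.random.default_rng(options.seed)

    starts: list[np.ndarray] = []
    for extra in options.extra_starts:
        if isinstance(extra, HMMParameters):
            starts.append(pack_parameters(extra, spec))
        else:
            starts.append(np.asarray(extra, dtype=float))
    for _ in range(options.n_restarts):
        starts.append(pack_parameters(_random_natural_start(rng, spec), spec))

    best = None
    diagnostics = []
    for x0 in starts:
        if x0.shape[0] != layout.n_parameters:
            raise ReassureHMMError(
                f"start vector length {x0.shape[0]} != {layout.n_parameters}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                engine.nll_working,
                x0,
                method="BFGS",
                options={"gtol": options.gtol, "maxiter": options.max_iter},
            )
        gnorm = float(np.abs(res.jac).max()) if res.jac is not None else np.inf
        diagnostics.append(
            {"fun": float(res.fun), "grad_norm": gnorm, "success": bool(res.success)}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(
            "no restart converged to a finite optimum", diagnostics
        )

    # resolve label switching (reorder states so pi is ascending) and pull
    # numerically saturated probabilities inside (0,1) so they repack
    params = relabel_ascending(
        clip_to_interior(unpack_parameters(best.x, spec)), spec
    )
    xbest = pack_parameters(params, spec)
    nllk = float(engine.nll_working(xbest))
    grad_norm = float(np.abs(best.jac).max())
    converged = bool(best.success or grad_norm < 1e-3)

    fit_warnings: list[str] = []
    if np.abs(logit(np.clip(params.pis, 1e-15, 1 - 1e-15))).max() > BOUNDARY_LOGIT:
        fit_warnings.append(
            "boundary_pi: an emission probability is within ~0.001 of 0 or 1"
        )
    if params.betas is not None and np.abs(params.betas).max() > LARGE_BETA:
        fit_warnings.append(
            "large_beta: |beta| > 50 signals a saturated transition probability"
        )

    se, singular = _working_standard_errors(engine, xbest)
    if singular:
        fit_warnings.append(
            "singular_hessian: covariance from pseudo-inverse; intervals unreliable"
        )

    p = layout.n_parameters
    return HMMFitResult(
        spec=spec,
        params=params,
        working=xbest,
        working_se=se,
        nllk=nllk,
        p=p,
        aic=2.0 * nllk + 2.0 * p,
        converged=converged,
        grad_norm=grad_norm,
        n_restarts_used=len(starts),
        seed=options.seed,
        warnings=fit_warnings,
        restart_diagnostics=diagnostics,
    )


def _working_standard_errors(
    engine: BatchedLikelihood, xbest: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Finite-difference Hessian of the nll -> working-scale SEs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess(xbest, engine.nll_working)
    singular = False
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        singular = True
    var = np.diag(cov).copy()
    if (var <= 0).any() or not np.isfinite(var).all():
        if not singular:
            cov = np.linalg.pinv(hess)
            var = np.diag(cov).copy()
            singular = True
        var[var <= 0] = np.nan
    return np.sqrt(var), singular


class HMMFitResult:
    """Fitted-model results: estimates, uncertainty, diagnostics.

    Mirrors the usual results-object idiom: ``params`` holds natural-scale
    estimates, :meth:`conf_int` the 95% Wald table, :meth:`summary` a
    printable report, and :meth:`decode` / :meth:`profile` the downstream
    analyses that treat the estimates as fixed.
    """

    def __init__(
        self,
        spec: ModelSpec,
        params: HMMParameters,
        working: np.ndarray,
        working_se: np.ndarray,
        nllk: float,
        p: int,
        aic: float,
        converged: bool,
        grad_norm: float,
        n_restarts_used: int,
        seed: int | None,
        warnings: list[str],
        restart_diagnostics: list,
    ):
        self.spec = spec
        self.params = params
        self.working = working
        self.working_se = working_se
        self.nllk = nllk
        self.llf = -nllk
        self.p = p
        self.aic = aic
        self.converged = converged
        self.grad_norm = grad_norm
        self.n_restarts_used = n_restarts_used
        self.seed = seed
        self.warnings = list(warnings)
        self.restart_diagnostics = restart_diagnostics
        self._layout = parameter_layout(spec)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-parameter (estimate, lower, upper) Wald table.

        Intervals are symmetric on the working scale; probability-type
        parameters are back-transformed through the inverse logit, so
        their bounds are asymmetric around the estimate and strictly
        inside (0, 1).  Multinomial-logit block entries (N >= 3) are
        reported on the working scale.
        """
        if alpha != 0.05:
            from scipy.stats import norm

            z = float(norm.ppf(1 - alpha / 2))
        else:
            z = Z_95
        rows = []
        for i, (name, tr) in enumerate(
            zip(self._layout.names, self._layout.transforms)
        ):
            w = self.working[i]
            se = self.working_se[i]
            lo_w, hi_w = w - z * se, w + z * se
            if tr == "logit":
                est, lo, hi = expit(w), expit(lo_w), expit(hi_w)
            else:  # identity betas and mlogit blocks stay on their own scale
                est, lo, hi = w, lo_w, hi_w
            rows.append((name, est, lo, hi, se, tr))
        return pd.DataFrame(
            rows,
            columns=["parameter", "estimate", "lower", "upper", "se_working",
                     "scale"],
        ).set_index("parameter")

    def decode(self, collection: Sequence[SessionSeries]) -> list[StatePath]:
        """Viterbi-decode a collection under the fitted parameters."""
        return decode_collection(collection, self.params, self.spec)

    def profile(
        self,
        grid: np.ndarray,
        clinician_id: int = 1,
        covariate_index: int = 1,
    ):
        """Transition-probability profile along a covariate grid."""
        return covariate_profile(
            self.params, grid, clinician_id, covariate_index
        )

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Bernoulli-emission hidden Markov model",
            "=" * 54,
            f"states:            {spec.n_states}"
            + ("  (independent mixture)" if spec.mixture else ""),
            f"covariates:        {list(spec.covariates) or 'none'}",
            f"fixed effects:     {spec.fixed_effects}",
            f"initial law:       {spec.initial}",
            f"-log likelihood:   {self.nllk:.4f}",
            f"parameters (p):    {self.p}",
            f"AIC:               {self.aic:.4f}",
            f"converged:         {self.converged} "
            f"(max |grad| = {self.grad_norm:.2e})",
            "-" * 54,
            self.conf_int().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if self.warnings:
            lines.append("-" * 54)
            lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable record (spec, estimates, CIs, provenance)."""
        ci = self.conf_int()
        return {
            "package_version": _pkg_version,
            "seed": self.seed,
            "spec": {
                "n_states": self.spec.n_states,
                "covariates": list(self.spec.covariates),
                "fixed_effects": self.spec.fixed_effects,
                "mixture": self.spec.mixture,
                "initial": self.spec.initial,
            },
            "nllk": self.nllk,
            "p": self.p,
            "aic": self.aic,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "warnings": self.warnings,
            "estimates": {
                "pis": self.params.pis.tolist(),
                "tpms": None if self.params.tpms is None else self.params.tpms.tolist(),
                "betas": None if self.params.betas is None else self.params.betas.tolist(),
                "deltas": None if self.params.deltas is None else self.params.deltas.tolist(),
            },
            "ci_table": {
                name: {
                    "estimate": float(row["estimate"]),
                    "lower": float(row["lower"]),
                    "upper": float(row["upper"]),
                }
                for name, row in ci.iterrows()
            },
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None
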
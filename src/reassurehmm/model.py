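"""Model-level interface: build a model from data, fit it, inspect results.

Typical use::

    from reassurehmm import BernoulliSessionHMM

    model = BernoulliSessionHMM(sessions, n_states=2, covariates=["log_dopr"])
    result = model.fit(seed=1)
    print(result.summary())
    paths = result.decode(sessions)
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .core import HMMParameters, ModelSpec, ReassureHMMError, SessionSeries
from .estimation import FitOptions, HMMFitResult, fit
from .likelihood import joint_log_likelihood


class BernoulliSessionHMM:
    """Bernoulli-emission HMM pooled over independent sessions.

    Parameters
    ----------
    sessions
        Collection of :class:`~reassurehmm.core.SessionSeries`; the joint
        likelihood is the product over sessions (sessions are independent
        consultations, each a short binary series).
    n_states
        Number of latent behavioural states.
    covariates
        Ordered subset of ``("response_type", "log_dopr")``; lagged values
        drive the transition probabilities through an inverse-logit link.
    fixed_effects
        Give each clinician their own transition-parameter set.
    mixture
        Fit the independent-mixture special case (no serial dependence).
    initial
        ``"stationary"`` (homogeneous chains only) or ``"estimated"``.
        Defaults to ``"estimated"`` when covariates are present.
    """

    def __init__(
        self,
        sessions: Sequence[SessionSeries],
        n_states: int = 2,
        covariates: Sequence[str] = (),
        fixed_effects: bool = False,
        mixture: bool = False,
        initial: str | None = None,
    ):
        if len(sessions) == 0:
            raise ReassureHMMError("empty session collection")
        if initial is None:
            initial = "estimated" if covariates else "stationary"
        self.sessions = list(sessions)
        self.spec = ModelSpec(
            n_states=n_states,
            covariates=tuple(covariates),
            fixed_effects=fixed_effects,
            mixture=mixture,
            initial=initial,
        )

    @classmethod
    def from_spec(
        cls, sessions: Sequence[SessionSeries], spec: ModelSpec
    ) -> "BernoulliSessionHMM":
        model = cls.__new__(cls)
        if len(sessions) == 0:
            raise ReassureHMMError("empty session collection")
        model.sessions = list(sessions)
        model.spec = spec
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BernoulliSessionHMM":
        """Build from a flat session table (see :mod:`reassurehmm.io`)."""
        from .io import sessions_from_dataframe

        return cls(sessions_from_dataframe(df), **kwargs)

    def loglike(self, params: HMMParameters) -> float:
        """Joint log-likelihood of the collection at ``params``."""
        return joint_log_likelihood(self.sessions, params, self.spec)

    def fit(
        self,
        n_restarts: int = 10,
        seed: int | None = None,
        options: FitOptions | None = None,
    ) -> HMMFitResult:
        """Maximum-likelihood fit; see :class:`FitOptions` for the knobs."""
        if options is None:
            options = FitOptions(n_restarts=n_restarts, seed=seed)
        return fit(self.sessions, self.spec, options)
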
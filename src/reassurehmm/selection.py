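"""Parameter counting, AIC, and multi-model comparison tables.

Candidate models are compared by the Akaike Information Criterion,
``AIC = -2 log l + 2 p`` where ``p`` is the length of the estimated
parameter vector; the lowest AIC wins.  Parameter counts are derived
structurally from the :class:`~reassurehmm.core.ModelSpec`:

========================================  =======================================
model                                     p
========================================  =======================================
homogeneous N-state baseline, stationary  N(N-1) transitions + N emissions
independent mixture (N components)        (N-1) weights + N emissions
covariate model (2 states, k covariates)  2 emissions + 2(k+1) betas + 1 initial
fixed-effects variants                    transition/initial blocks doubled
========================================  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelSpec, ReassureHMMError, SessionSeries, parameter_layout
from .estimation import FitOptions, HMMFitResult, fit


def count_parameters(spec: ModelSpec) -> int:
    """Length of the estimated parameter vector for ``spec``."""
    return parameter_layout(spec).n_parameters


def aic(nllk: float, p: int) -> float:
    """Akaike Information Criterion from a *negative* log-likelihood."""
    if p < 0:
        raise ReassureHMMError("parameter count must be nonnegative")
    return 2.0 * float(nllk) + 2.0 * int(p)


@dataclass
class ComparisonTable:
    """Fitted comparison of several candidate specs on one collection."""

    table: pd.DataFrame  # columns: label, nllk, p, aic, best
    results: dict  # label -> HMMFitResult

    @property
    def best_label(self) -> str:
        return str(self.table.loc[self.table["best"], "label"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = self.table.to_dict(orient="records")
        import json

        text = json.dumps(payload, indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")

    def __str__(self) -> str:
        df = self.table.copy()
        df["best"] = np.where(df["best"], "  <-- lowest AIC", "")
        return df.to_string(index=False)


def compare_models(
    collection: Sequence[SessionSeries],
    specs: Sequence[tuple[str, ModelSpec]],
    options: FitOptions | None = None,
) -> ComparisonTable:
    """Fit every (label, spec) candidate and rank by AIC.

    Each candidate gets its own deterministic seed derived from
    ``options.seed``, so the whole table is reproducible and two identical
    specs in the list produce identical rows.
    """
    if len(specs) == 0:
        raise ReassureHMMError("no candidate specs given")
    options = options or FitOptions()
    rows = []
    results: dict[str, HMMFitResult] = {}
    base_seed = options.seed
    for label, spec in specs:
        sub_seed = (
            None
            if base_seed is None
            else int(
                np.random.SeedSequence(
                    [base_seed, spec.n_states, len(spec.covariates),
                     int(spec.fixed_effects), int(spec.mixture)]
                ).generate_state(1)[0] % (2**31)
            )
        )
        opts = FitOptions(
            n_restarts=options.n_restarts,
            seed=sub_seed,
            gtol=options.gtol,
            max_iter=options.max_iter,
        )
        try:
            res = fit(collection, spec, opts)
        except ReassureHMMError as exc:
            raise ReassureHMMError(f"fit failed for model {label!r}: {exc}") from exc
        results[label] = res
        rows.append((label, res.nllk, res.p, res.aic))
    df = pd.DataFrame(rows, columns=["label", "nllk", "p", "aic"])
    best_pos = int(df["aic"].idxmin())
    df["best"] = False
    df.loc[best_pos, "best"] = True
    return ComparisonTable(table=df, results=results)


def study_model_family() -> list[tuple[str, ModelSpec]]:
    """The ten candidate models of the reassurance study.

    Four baselines (1-, 2-, 3-state homogeneous HMMs and the independent
    mixture), three covariate models, and the three fixed-effects
    counterparts of baseline/response/log-DOPR.
    """
    return [
        ("Baseline N=1", ModelSpec(n_states=1)),
        ("Baseline N=2", ModelSpec(n_states=2)),
        ("Baseline N=3", ModelSpec(n_states=3)),
        ("Indep. mixt.", ModelSpec(n_states=2, mixture=True)),
        ("Response Type",
         ModelSpec(covariates=("response_type",), initial="estimated")),
        ("Log DOPR", ModelSpec(covariates=("log_dopr",), initial="estimated")),
        ("Response Type & log DOPR",
         ModelSpec(covariates=("response_type", "log_dopr"),
                   initial="estimated")),
        ("FE baseline",
         ModelSpec(fixed_effects=True, initial="estimated")),
        ("FE Response",
         ModelSpec(covariates=("response_type",), fixed_effects=True,
                   initial="estimated")),
        ("FE Log DOPR",
         ModelSpec(covariates=("log_dopr",), fixed_effects=True,
                   initial="estimated")),
    ]
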
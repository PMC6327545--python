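"""Synthetic consultation-session generator.

The study's consultation recordings are not publicly deposited, so this
module generates collections with the same statistical structure: 44
sessions between breast-cancer patients and one of two therapeutic
radiographers, 3-37 reassurances per session with lengths drawn from the
study's empirical frequency table, binary reassurance types emitted from a
2-state latent chain, right-skewed reassurance durations that are longer
for cognitive than for affective reassurances, and binary patient
responses.

Defaults reproduce the study conditions: the generating chain uses the
published baseline estimates (pi = (0.209, 0.782), gamma12 = 0.265,
gamma21 = 0.169), whose stationary mixture gives a long-run cognitive
share of 55.9% — the share observed in the pooled study sample.  Durations
are log-normal per reassurance type (a package choice: the study reports
only that durations are heavily right-skewed and that cognitive
reassurances last longer).

When the generating model has covariate-driven transitions the simulation
closes the feedback loop: the transition matrix for step t is computed
from the covariates simulated at step t-1 before the new state is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    HMMParameters,
    ModelSpec,
    ReassureHMMError,
    SessionSeries,
    stationary_distribution,
)
from .covariates import transition_probabilities

# Empirical session-length frequency table from the study: 44 first-visit
# sessions; note the listed sizes and frequencies total 480 reassurances
# while the pooled count is reported as 483 — the table is used as the
# sampling distribution as printed.
TABLE1_SIZES = np.array(
    [3, 4, 5, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16, 18, 19, 26, 37]
)
TABLE1_FREQS = np.array([3, 4, 2, 1, 3, 3, 5, 4, 4, 6, 1, 1, 1, 1, 3, 1, 1])

#: Published baseline 2-state estimates, used as the default generator truth.
BASELINE_TPM = np.array([[0.735, 0.265], [0.169, 0.831]])
BASELINE_PIS = np.array([0.209, 0.782])


def default_parameters() -> HMMParameters:
    """Generating truth for the default (study-emulating) configuration."""
    return HMMParameters(pis=BASELINE_PIS.copy(), tpms=BASELINE_TPM.copy())


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-session generator.

    Parameters
    ----------
    n_sessions
        Number of sessions to draw (study: 44).
    lengths
        ``"table1"`` draws from the study's empirical length table;
        otherwise an explicit sequence of lengths (one per session) or an
        inclusive ``(lo, hi)`` range sampled uniformly.
    spec, params
        Generating model and its true parameters; defaults to the
        homogeneous 2-state baseline at the published estimates.
    duration_logmean, duration_logsd
        Log-normal duration parameters per reassurance type
        ``{0: affective, 1: cognitive}``, on the log-seconds scale.
        Defaults put the cognitive median above the affective one.
    response_prob
        Probability of a positive patient response; a scalar, or a
        length-N array for a state-dependent response law.
    response_duration_logmean, response_duration_logsd
        Log-normal parameters of the patient-response duration.
    clinician_probs
        Assignment probabilities of clinicians 1 and 2 per session.
    seed
        Generator seed; identical configs with identical seeds produce
        bit-identical collections.
    """

    n_sessions: int = 44
    lengths: object = "table1"
    spec: ModelSpec = field(default_factory=ModelSpec)
    params: HMMParameters = field(default_factory=default_parameters)
    duration_logmean: dict = field(default_factory=lambda: {0: 1.2, 1: 2.0})
    duration_logsd: dict = field(default_factory=lambda: {0: 0.8, 1: 0.8})
    response_prob: object = 0.5
    response_duration_logmean: float = 1.0
    response_duration_logsd: float = 0.8
    clinician_probs: tuple[float, float] = (0.5, 0.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ReassureHMMError("n_sessions must be >= 1")
        if any(sd <= 0 for sd in self.duration_logsd.values()):
            raise ReassureHMMError("duration log-sd must be positive")
        cp = np.asarray(self.clinician_probs, dtype=float)
        if cp.shape != (2,) or (cp < 0).any() or abs(cp.sum() - 1) > 1e-9:
            raise ReassureHMMError("clinician_probs must be two probabilities summing to 1")


def table1_length_sampler(seed=None) -> "callable":
    """Sampler of session lengths from the study's frequency table.

    Returns a zero-argument callable producing one length per call, drawn
    from the discrete distribution given by the (size, frequency) pairs
    normalised to probabilities.
    """
    rng = np.random.default_rng(seed)
    probs = TABLE1_FREQS / TABLE1_FREQS.sum()

    def draw() -> int:
        return int(rng.choice(TABLE1_SIZES, p=probs))

    return draw


def _draw_lengths(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lengths = config.lengths
    if isinstance(lengths, str):
        if lengths != "table1":
            raise ReassureHMMError(f"unknown length source {lengths!r}")
        probs = TABLE1_FREQS / TABLE1_FREQS.sum()
        return rng.choice(TABLE1_SIZES, size=config.n_sessions, p=probs)
    if (
        isinstance(lengths, tuple)
        and len(lengths) == 2
        and all(isinstance(v, (int, np.integer)) for v in lengths)
    ):
        lo, hi = lengths
        if lo < 1 or hi < lo:
            raise ReassureHMMError(f"invalid length range {lengths!r}")
        return rng.integers(lo, hi + 1, size=config.n_sessions)
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.shape != (config.n_sessions,) or (arr < 1).any():
        raise ReassureHMMError(
            "explicit lengths must list one positive length per session"
        )
    return arr


def simulate_collection(
    config: GeneratorConfig, return_states: bool = False
):
    """Draw a synthetic session collection.

    Returns the list of :class:`SessionSeries`; with ``return_states=True``
    also returns the list of true latent state arrays (1-based), which are
    deliberately kept out of the session objects — real data never carries
    them — but are needed by recovery and decoding oracles.
    """
    rng = np.random.default_rng(config.seed)
    spec, params = config.spec, config.params
    n_states = params.n_states
    lengths = _draw_lengths(config, rng)
    clinicians = rng.choice((1, 2), size=config.n_sessions, p=config.clinician_probs)

    resp_p = np.asarray(config.response_prob, dtype=float)
    state_dependent_resp = resp_p.ndim == 1 and resp_p.shape[0] == n_states

    sessions: list[SessionSeries] = []
    latent: list[np.ndarray] = []
    for s in range(config.n_sessions):
        n = int(lengths[s])
        clin = int(clinicians[s])
        cset = spec.set_index(clin)
        delta = params.initial_distribution(cset)

        states = np.empty(n, dtype=np.int64)
        obs = np.empty(n, dtype=np.int64)
        dur = np.empty(n)
        resp = np.empty(n, dtype=np.int64)
        rdur = np.empty(n)

        states[0] = rng.choice(n_states, p=delta)
        for t in range(n):
            if t > 0:
                if spec.covariates:
                    z = [1.0]
                    for name in spec.covariates:
                        if name == "response_type":
                            z.append(float(resp[t - 1]))
                        else:  # log_dopr
                            z.append(float(np.log(dur[t - 1])))
                    g12, g21 = transition_probabilities(
                        params.betas[cset], np.asarray(z)[None, :]
                    )
                    tpm = np.array(
                        [[1 - g12[0], g12[0]], [g21[0], 1 - g21[0]]]
                    )
                else:
                    tpm = params.tpms[cset]
                states[t] = rng.choice(n_states, p=tpm[states[t - 1]])
            obs[t] = rng.random() < params.pis[states[t]]
            dur[t] = float(
                rng.lognormal(
                    config.duration_logmean[int(obs[t])],
                    config.duration_logsd[int(obs[t])],
                )
            )
            p_pos = float(resp_p[states[t]]) if state_dependent_resp else float(resp_p)
            resp[t] = rng.random() < p_pos
            rdur[t] = float(
                rng.lognormal(
                    config.response_duration_logmean,
                    config.response_duration_logsd,
                )
            )
        sessions.append(
            SessionSeries(
                session_id=s + 1,
                observations=obs,
                durations=dur,
                response_types=resp,
                response_durations=rdur,
                clinician_id=clin,
            )
        )
        latent.append(states + 1)
    if return_states:
        return sessions, latent
    return sessions
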
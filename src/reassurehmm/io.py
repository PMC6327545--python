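"""Session CSV readers/writers and result serialisation.

The on-disk session format is a flat UTF-8 CSV with exactly these columns:

    session_id, position, reassurance_type, duration_s,
    response_type, response_duration_s, clinician_id

``position`` is 1-based and consecutive within a session;
``reassurance_type`` and ``response_type`` are 0/1; durations are in
seconds.  Reading then writing a well-formed file reproduces its content.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import HMMParameters, ModelSpec, ReassureHMMError, SessionSeries

SESSION_COLUMNS = [
    "session_id",
    "position",
    "reassurance_type",
    "duration_s",
    "response_type",
    "response_duration_s",
    "clinician_id",
]


def sessions_from_dataframe(df: pd.DataFrame) -> list[SessionSeries]:
    """Validate a flat session table and group it into sessions."""
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if missing or extra:
        raise ReassureHMMError(
            f"bad session table columns: missing {missing}, unexpected {extra}"
        )
    df = df.copy()
    df["_row"] = np.arange(len(df)) + 2  # 1-based file row incl. header

    for col, ok in (
        ("reassurance_type", df["reassurance_type"].isin((0, 1))),
        ("response_type", df["response_type"].isin((0, 1))),
        ("duration_s", df["duration_s"] > 0),
        ("response_duration_s", df["response_duration_s"] >= 0),
        ("clinician_id", df["clinician_id"].isin((1, 2))),
    ):
        bad = df.loc[~ok, "_row"]
        if len(bad):
            raise ReassureHMMError(
                f"invalid {col} value at row(s) {bad.tolist()[:5]}"
            )

    sessions = []
    for sid, grp in df.groupby("session_id", sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos.shape[0] != np.unique(pos).shape[0]:
            raise ReassureHMMError(
                f"duplicate positions in session {sid!r} "
                f"(rows {grp['_row'].tolist()[:5]})"
            )
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ReassureHMMError(
                f"positions in session {sid!r} must be consecutive from 1, "
                f"got {pos.tolist()[:8]}"
            )
        clin = grp["clinician_id"].unique()
        if len(clin) != 1:
            raise ReassureHMMError(
                f"session {sid!r} has multiple clinician_ids {clin.tolist()}"
            )
        sessions.append(
            SessionSeries(
                session_id=sid,
                observations=grp["reassurance_type"].to_numpy(),
                durations=grp["duration_s"].to_numpy(dtype=float),
                response_types=grp["response_type"].to_numpy(),
                response_durations=grp["response_duration_s"].to_numpy(dtype=float),
                clinician_id=int(clin[0]),
            )
        )
    return sessions


def sessions_to_dataframe(collection: Sequence[SessionSeries]) -> pd.DataFrame:
    """Flatten sessions to the standard table, sorted by (session, position)."""
    frames = []
    try:
        ordered = sorted(collection, key=lambda s: s.session_id)
    except TypeError:
        ordered = sorted(collection, key=lambda s: str(s.session_id))
    for s in ordered:
        n = len(s)
        frames.append(
            pd.DataFrame(
                {
                    "session_id": [s.session_id] * n,
                    "position": np.arange(1, n + 1),
                    "reassurance_type": s.observations,
                    "duration_s": s.durations,
                    "response_type": s.response_types,
                    "response_duration_s": s.response_durations,
                    "clinician_id": [s.clinician_id] * n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_sessions(path) -> list[SessionSeries]:
    """Read a session CSV into validated session objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    return sessions_from_dataframe(df)


def write_sessions(collection: Sequence[SessionSeries], path) -> None:
    """Write sessions to the standard CSV."""
    sessions_to_dataframe(collection).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fitted-parameter JSON
# ---------------------------------------------------------------------------


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        n_states=int(d.get("n_states", 2)),
        covariates=tuple(d.get("covariates", ())),
        fixed_effects=bool(d.get("fixed_effects", False)),
        mixture=bool(d.get("mixture", False)),
        initial=str(d.get("initial", "stationary")),
    )


def load_fit_json(path) -> tuple[ModelSpec, HMMParameters, dict]:
    """Load a serialised fit result: (spec, parameters, full record)."""
    with open(path) as fh:
        record = json.load(fh)
    spec = spec_from_dict(record["spec"])
    est = record["estimates"]
    params = HMMParameters(
        pis=np.asarray(est["pis"], dtype=float),
        tpms=None if est.get("tpms") is None else np.asarray(est["tpms"]),
        betas=None if est.get("betas") is None else np.asarray(est["betas"]),
        deltas=None if est.get("deltas") is None else np.asarray(est["deltas"]),
    )
    return spec, params, record


def load_generator_config(path):
    """Build a :class:`~reassurehmm.synthetic.GeneratorConfig` from YAML.

    Recognised keys mirror the dataclass fields; ``params`` may give
    ``pis`` plus ``tpm``/``betas``/``deltas``, and ``spec`` the usual model
    flags.  Omitted keys keep the study-emulating defaults.
    """
    from .synthetic import GeneratorConfig, default_parameters

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in (
        "n_sessions",
        "response_prob",
        "response_duration_logmean",
        "response_duration_logsd",
        "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "lengths" in raw:
        v = raw["lengths"]
        kwargs["lengths"] = tuple(v) if isinstance(v, list) and len(v) == 2 and raw.get(
            "lengths_is_range", False) else v
    if "clinician_probs" in raw:
        kwargs["clinician_probs"] = tuple(raw["clinician_probs"])
    if "duration_logmean" in raw:
        kwargs["duration_logmean"] = {int(k): float(v) for k, v in raw["duration_logmean"].items()}
    if "duration_logsd" in raw:
        kwargs["duration_logsd"] = {int(k): float(v) for k, v in raw["duration_logsd"].items()}
    if "spec" in raw:
        kwargs["spec"] = spec_from_dict(raw["spec"])
    if "params" in raw:
        p = raw["params"]
        kwargs["params"] = HMMParameters(
            pis=np.asarray(p["pis"], dtype=float),
            tpms=None if p.get("tpm") is None else np.asarray(p["tpm"], dtype=float),
            betas=None if p.get("betas") is None else np.asarray(p["betas"], dtype=float),
            deltas=None if p.get("deltas") is None else np.asarray(p["deltas"], dtype=float),
        )
    else:
        kwargs["params"] = default_parameters()
    return GeneratorConfig(**kwargs)


def paths_to_dataframe(collection, paths) -> pd.DataFrame:
    """Decoded paths as flat CSV rows (session, position, obs, state)."""
    by_id = {s.session_id: s for s in collection}
    frames = []
    for p in paths:
        s = by_id[p.session_id]
        frames.append(
            pd.DataFrame(
                {
                    "session_id": [p.session_id] * len(p),
                    "position": np.arange(1, len(p) + 1),
                    "observation": s.observations,
                    "decoded_state": p.states,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
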
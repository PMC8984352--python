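"""CSV readers and writers for colony data and resampling results.

All files are comma-separated UTF-8 with a mandatory header row and
ISO-8601 dates.  A colony directory holds four files::

    bats.csv      bat_id,site,excluded_low_sampling,excluded_infection
    sessions.csv  date,phase,hours_sampled
    triads.csv    triad_id,bat_id
    bouts.csv     date,actor,receiver,duration_s

Phase calendar bounds are inferred from the sessions table (first and last
sampled date of each phase), so a written colony round-trips exactly when
its sessions span each phase — which is always true for generated data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .colony import (
    BATS_COLUMNS,
    BOUTS_COLUMNS,
    DEFAULT_HOURS_BOUNDS,
    DEFAULT_MIN_BOUT_S,
    PHASE_NAMES,
    SESSIONS_COLUMNS,
    TRIADS_COLUMNS,
    Colony,
    ColonyValidationError,
    Phase,
    forced_cross_cage_rows,
    validate_colony,
)
from .inference import ResamplingResult

logger = logging.getLogger(__name__)

COLONY_FILES = {
    "bats": "bats.csv",
    "sessions": "sessions.csv",
    "triads": "triads.csv",
    "bouts": "bouts.csv",
}

RESULTS_COLUMNS = ("statistic", "estimate", "ci_low", "ci_high", "p_value", "n_resamples", "seed")

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(column: pd.Series, label: str) -> pd.Series:
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        try:
            return _BOOL_TOKENS[str(v).strip().lower()]
        except KeyError:
            raise ColonyValidationError(f"{label}: unparseable boolean {v!r}")

    return column.map(one)


def _parse_dates(column: pd.Series) -> pd.Series:
    return pd.to_datetime(column, format="ISO8601").dt.date


def read_colony(
    directory,
    *,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
    hours_bounds=DEFAULT_HOURS_BOUNDS,
    strict: bool = True,
) -> Colony:
    """Read and validate a colony from a directory of CSV files.

    Bouts shorter than ``min_bout_s`` are dropped (with a logged count): the
    scoring protocol only recognises bouts at or above the minimum duration.
    Under ``strict=True`` a bout between bats housed in different cages
    during the FORCED phase is a validation error; under ``strict=False``
    such rows are dropped with a warning instead.
    """
    directory = Path(directory)
    paths = {key: directory / name for key, name in COLONY_FILES.items()}
    for key, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing colony file: {path}")

    bats = pd.read_csv(paths["bats"], dtype={"bat_id": str, "site": str})
    for col in ("excluded_low_sampling", "excluded_infection"):
        if col in bats.columns:
            bats[col] = _parse_bool(bats[col], f"bats.{col}")
    # round_trip float parsing keeps write -> read exact to the last bit
    sessions = pd.read_csv(paths["sessions"], dtype={"phase": str}, float_precision="round_trip")
    triads = pd.read_csv(paths["triads"], dtype=str)
    bouts = pd.read_csv(
        paths["bouts"], dtype={"actor": str, "receiver": str}, float_precision="round_trip"
    )

    for frame, cols, label in (
        (bats, BATS_COLUMNS, "bats"),
        (sessions, SESSIONS_COLUMNS, "sessions"),
        (triads, TRIADS_COLUMNS, "triads"),
        (bouts, BOUTS_COLUMNS, "bouts"),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ColonyValidationError(f"{label}.csv is missing columns {missing}")

    sessions["date"] = _parse_dates(sessions["date"])
    sessions["hours_sampled"] = sessions["hours_sampled"].astype(float)
    bouts["date"] = _parse_dates(bouts["date"]) if len(bouts) else bouts["date"]
    bouts["duration_s"] = bouts["duration_s"].astype(float)

    n_total = len(bouts)
    keep = bouts["duration_s"] >= min_bout_s
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d of %d bouts below the %.3g s minimum", n_dropped, n_total, min_bout_s)
    bouts = bouts[keep].reset_index(drop=True)

    phases = infer_phases(sessions)
    colony = Colony(
        bats=bats[list(BATS_COLUMNS)],
        phases=phases,
        triads=triads[list(TRIADS_COLUMNS)],
        sessions=sessions[list(SESSIONS_COLUMNS)],
        bouts=bouts[list(BOUTS_COLUMNS)],
    )

    if not strict:
        cross = forced_cross_cage_rows(colony)
        if cross:
            logger.warning(
                "dropping %d FORCED-phase bouts between different cages (lenient mode)",
                len(cross),
            )
            colony = colony.replace(bouts=colony.bouts.drop(index=cross).reset_index(drop=True))

    validate_colony(colony, min_bout_s=min_bout_s, hours_bounds=hours_bounds)
    return colony


def infer_phases(sessions: pd.DataFrame) -> tuple:
    """Phase calendar bounds from the sessions table (min/max date per phase)."""
    present = set(sessions["phase"])
    missing = [p for p in PHASE_NAMES if p not in present]
    if missing:
        raise ColonyValidationError(f"sessions table has no rows for phases {missing}")
    phases = []
    for name in PHASE_NAMES:
        dates = sessions.loc[sessions["phase"] == name, "date"]
        phases.append(Phase(name, min(dates), max(dates)))
    return tuple(phases)


def write_colony(colony: Colony, directory) -> None:
    """Write the four colony CSV files into ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    colony.bats[list(BATS_COLUMNS)].to_csv(directory / COLONY_FILES["bats"], index=False)
    colony.sessions[list(SESSIONS_COLUMNS)].to_csv(directory / COLONY_FILES["sessions"], index=False)
    colony.triads[list(TRIADS_COLUMNS)].to_csv(directory / COLONY_FILES["triads"], index=False)
    colony.bouts[list(BOUTS_COLUMNS)].to_csv(directory / COLONY_FILES["bouts"], index=False)


def results_frame(results) -> pd.DataFrame:
    """Flatten resampling results into the interchange table (one row each)."""
    rows = []
    for r in results:
        rows.append(
            {
                "statistic": r.statistic_name,
                "estimate": r.estimate,
                "ci_low": np.nan if r.ci_low is None else r.ci_low,
                "ci_high": np.nan if r.ci_high is None else r.ci_high,
                "p_value": np.nan if r.p_value is None else r.p_value,
                "n_resamples": r.n_resamples,
                "seed": np.nan if r.seed is None else r.seed,
            }
        )
    return pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))


def write_results(results, path) -> None:
    """Write a non-empty collection of :class:`ResamplingResult` to a flat CSV.

    Output is bit-stable for a fixed seed and input: pandas serialises floats
    with ``repr``, which round-trips IEEE doubles exactly.
    """
    results = list(results)
    if not results:
        raise ValueError("results collection is empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RESULTS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"results file is missing columns {missing}")
    return frame


__all__ = [
    "read_colony",
    "write_colony",
    "write_results",
    "read_results",
    "results_frame",
    "infer_phases",
    "COLONY_FILES",
    "RESULTS_COLUMNS",
    "ResamplingResult",
]
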
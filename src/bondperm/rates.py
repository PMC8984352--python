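"""Dyadic allogrooming rates, dyad classification and change scores.

The central quantity is the *allogrooming log rate* of an unordered pair
within a phase:

    rate_log = ln(1 + x),   x = (rate_a_to_b + rate_b_to_a) / 2

where each directed rate is total grooming seconds divided by the pair's
exposure — the total sampled hours during which the two bats could
physically interact (all session hours in PRE and POST; during FORCED only
cage-mates have exposure).  Averaging the two directions reflects that
allogrooming is largely bidirectional; the log(x + 1) transform stabilises
the variance, which grows with the mean.

Dyads are classified by familiarity and treatment:

* ``FAMILIAR`` — both bats from the same capture site;
* ``TEST``     — different sites, forced into the same triad cage;
* ``CONTROL``  — different sites, never caged together.

These three classes partition all pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .colony import PHASE_NAMES, Colony, ColonyValidationError, canonical_dyad

DYAD_CLASSES = ("TEST", "CONTROL", "FAMILIAR")
ROBUSTNESS_FILTERS = ("high_pre_controls", "low_sampling_bats", "infected_bats")


@dataclass(frozen=True)
class DyadPhaseRate:
    """The symmetric log grooming rate of one pair in one phase.

    ``rate_log`` is NaN when the pair had zero exposure in the phase
    (e.g. a cross-cage pair during FORCED): an undefined rate is a missing
    value, never a numeric zero.
    """

    bat_a: str
    bat_b: str
    phase: str
    exposure_h: float
    rate_log: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rate_log)


def classify_dyads(colony: Colony) -> pd.DataFrame:
    """Label every unordered pair TEST / CONTROL / FAMILIAR.

    Returns a frame with columns ``bat_a, bat_b, dyad_class`` covering all
    C(n, 2) pairs (canonical ordering, ``bat_a < bat_b``).
    """
    site_of = colony.site_of()
    triad_of = colony.triad_of()
    missing = [b for b in colony.bat_ids if b not in triad_of]
    if missing:
        raise ColonyValidationError(f"bats missing a triad assignment: {missing}")
    rows = []
    for a, b in combinations(colony.bat_ids, 2):
        if site_of[a] == site_of[b]:
            label = "FAMILIAR"
        elif triad_of[a] == triad_of[b]:
            label = "TEST"
        else:
            label = "CONTROL"
        rows.append((a, b, label))
    return pd.DataFrame(rows, columns=["bat_a", "bat_b", "dyad_class"])


def _phase_of_date(colony: Colony) -> dict:
    return dict(zip(colony.sessions["date"], colony.sessions["phase"]))


def _phase_hours(colony: Colony) -> dict:
    return colony.sessions.groupby("phase")["hours_sampled"].sum().to_dict()


def exposure_hours(colony: Colony, dyad, phase: str) -> float:
    """Total sampled hours during which both members of ``dyad`` could interact."""
    if phase not in PHASE_NAMES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASE_NAMES}")
    a, b = canonical_dyad(*dyad)
    known = set(colony.bats["bat_id"])
    for bat in (a, b):
        if bat not in known:
            raise ValueError(f"unknown bat_id {bat!r}")
    hours = _phase_hours(colony).get(phase, 0.0)
    if phase == "FORCED":
        triad_of = colony.triad_of()
        if triad_of.get(a) != triad_of.get(b) or a not in triad_of:
            return 0.0
    return float(hours)


def dyad_log_rate(colony: Colony, dyad, phase: str) -> DyadPhaseRate:
    """Allogrooming log rate of one pair in one phase (NaN if zero exposure)."""
    a, b = canonical_dyad(*dyad)
    h = exposure_hours(colony, (a, b), phase)
    if h == 0.0:
        return DyadPhaseRate(a, b, phase, 0.0, math.nan)
    phase_of = _phase_of_date(colony)
    bouts = colony.bouts
    mask = [
        phase_of.get(d) == phase and {act, rec} == {a, b}
        for d, act, rec in zip(bouts["date"], bouts["actor"], bouts["receiver"])
    ]
    seconds = float(bouts.loc[mask, "duration_s"].sum())
    # mean of the two directed s/h rates == total pair seconds / (2 * exposure)
    x = seconds / (2.0 * h)
    return DyadPhaseRate(a, b, phase, h, math.log1p(x))


def phase_rate_table(colony: Colony) -> pd.DataFrame:
    """Vectorised rate table: one row per (dyad, phase) for all pairs.

    Columns: ``bat_a, bat_b, dyad_class, phase, exposure_h, rate_log``.
    ``rate_log`` is NaN wherever exposure is zero.
    """
    classes = classify_dyads(colony)
    hours = _phase_hours(colony)
    triad_of = colony.triad_of()

    bouts = colony.bouts.copy()
    if len(bouts):
        phase_of = _phase_of_date(colony)
        bouts["phase"] = bouts["date"].map(phase_of)
        ab = np.minimum(bouts["actor"], bouts["receiver"])
        ba = np.maximum(bouts["actor"], bouts["receiver"])
        bouts["bat_a"], bouts["bat_b"] = ab, ba
        seconds = (
            bouts.groupby(["phase", "bat_a", "bat_b"])["duration_s"].sum().reset_index()
        )
    else:
        seconds = pd.DataFrame(columns=["phase", "bat_a", "bat_b", "duration_s"])

    frames = []
    for phase in PHASE_NAMES:
        frame = classes.copy()
        frame["phase"] = phase
        h = float(hours.get(phase, 0.0))
        if phase == "FORCED":
            same_cage = np.array(
                [
                    triad_of.get(a) is not None and triad_of.get(a) == triad_of.get(b)
                    for a, b in zip(frame["bat_a"], frame["bat_b"])
                ]
            )
            frame["exposure_h"] = np.where(same_cage, h, 0.0)
        else:
            frame["exposure_h"] = h
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(seconds, on=["phase", "bat_a", "bat_b"], how="left")
    table["duration_s"] = table["duration_s"].astype(float).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = table["duration_s"] / (2.0 * table["exposure_h"])
    table["rate_log"] = np.where(table["exposure_h"] > 0, np.log1p(x), np.nan)
    return table[["bat_a", "bat_b", "dyad_class", "phase", "exposure_h", "rate_log"]]


def dyad_changes(colony: Colony, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-dyad change in allogrooming log rate, POST minus PRE.

    Only dyads with positive exposure in both phases appear; dyads on the
    colony's exclusion list (robustness filters) are dropped.  Columns:
    ``bat_a, bat_b, dyad_class, pre_log, post_log, delta_log``.
    """
    if table is None:
        table = phase_rate_table(colony)
    pre = table[table["phase"] == "PRE"].rename(columns={"rate_log": "pre_log"})
    post = table[table["phase"] == "POST"].rename(columns={"rate_log": "post_log"})
    merged = pre[["bat_a", "bat_b", "dyad_class", "pre_log"]].merge(
        post[["bat_a", "bat_b", "post_log"]], on=["bat_a", "bat_b"]
    )
    merged = merged.dropna(subset=["pre_log", "post_log"]).reset_index(drop=True)
    if colony.excluded_dyads:
        keep = [
            (a, b) not in colony.excluded_dyads
            for a, b in zip(merged["bat_a"], merged["bat_b"])
        ]
        merged = merged[keep].reset_index(drop=True)
    merged["delta_log"] = merged["post_log"] - merged["pre_log"]
    return merged


def windowed_rates(colony: Colony, window_days: int) -> pd.DataFrame:
    """Allogrooming log rates in consecutive windows within each phase.

    Windows are anchored at each phase's start date; the last window of a
    phase may be short.  Rows with zero exposure carry NaN.  Columns:
    ``bat_a, bat_b, dyad_class, phase, window_index, window_start,
    exposure_h, rate_log``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    classes = classify_dyads(colony)
    triad_of = colony.triad_of()
    phase_lut = {ph.name: ph for ph in colony.phases}

    sess = colony.sessions.copy()
    sess["window_index"] = [
        (d - phase_lut[p].start).days // window_days
        for d, p in zip(sess["date"], sess["phase"])
    ]
    win_hours = sess.groupby(["phase", "window_index"])["hours_sampled"].sum()
    win_start = {
        (p, w): phase_lut[p].start + pd.Timedelta(days=w * window_days).to_pytimedelta()
        for p, w in win_hours.index
    }

    bouts = colony.bouts.copy()
    if len(bouts):
        phase_of = _phase_of_date(colony)
        bouts["phase"] = bouts["date"].map(phase_of)
        bouts["window_index"] = [
            (d - phase_lut[p].start).days // window_days
            for d, p in zip(bouts["date"], bouts["phase"])
        ]
        bouts["bat_a"] = np.minimum(bouts["actor"], bouts["receiver"])
        bouts["bat_b"] = np.maximum(bouts["actor"], bouts["receiver"])
        seconds = (
            bouts.groupby(["phase", "window_index", "bat_a", "bat_b"])["duration_s"]
            .sum()
            .reset_index()
        )
    else:
        seconds = pd.DataFrame(columns=["phase", "window_index", "bat_a", "bat_b", "duration_s"])

    frames = []
    for (phase, w), h in win_hours.items():
        frame = classes.copy()
        frame["phase"] = phase
        frame["window_index"] = w
        frame["window_start"] = win_start[(phase, w)]
        if phase == "FORCED":
            same_cage = np.array(
                [
                    triad_of.get(a) is not None and triad_of.get(a) == triad_of.get(b)
                    for a, b in zip(frame["bat_a"], frame["bat_b"])
                ]
            )
            frame["exposure_h"] = np.where(same_cage, float(h), 0.0)
        else:
            frame["exposure_h"] = float(h)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(seconds, on=["phase", "window_index", "bat_a", "bat_b"], how="left")
    table["duration_s"] = table["duration_s"].astype(float).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = table["duration_s"] / (2.0 * table["exposure_h"])
    table["rate_log"] = np.where(table["exposure_h"] > 0, np.log1p(x), np.nan)
    cols = ["bat_a", "bat_b", "dyad_class", "phase", "window_index", "window_start", "exposure_h", "rate_log"]
    return table[cols].sort_values(["phase", "window_index", "bat_a", "bat_b"]).reset_index(drop=True)


def apply_robustness_filter(colony: Colony, which: str) -> Colony:
    """Return a copy of the colony with one robustness exclusion applied.

    * ``high_pre_controls`` — exclude CONTROL dyads whose PRE log rate
      exceeds the maximum PRE log rate among TEST dyads (guards against
      regression-to-the-mean in the group comparison).
    * ``low_sampling_bats`` / ``infected_bats`` — drop flagged bats and all
      their bouts and dyads.
    """
    if which not in ROBUSTNESS_FILTERS:
        raise ValueError(f"unknown filter {which!r}; expected one of {ROBUSTNESS_FILTERS}")

    if which == "high_pre_controls":
        table = phase_rate_table(colony)
        pre = table[table["phase"] == "PRE"]
        test_rates = pre.loc[pre["dyad_class"] == "TEST", "rate_log"].dropna()
        if test_rates.empty:
            raise ColonyValidationError("no TEST dyads with a defined PRE rate")
        cutoff = float(test_rates.max())
        controls = pre[(pre["dyad_class"] == "CONTROL") & (pre["rate_log"] > cutoff)]
        excluded = frozenset(
            colony.excluded_dyads | {(a, b) for a, b in zip(controls["bat_a"], controls["bat_b"])}
        )
        return colony.replace(excluded_dyads=excluded)

    flag = "excluded_low_sampling" if which == "low_sampling_bats" else "excluded_infection"
    drop = set(colony.bats.loc[colony.bats[flag].astype(bool), "bat_id"])
    if not drop:
        return colony
    bats = colony.bats[~colony.bats["bat_id"].isin(drop)].reset_index(drop=True)
    triads = colony.triads[~colony.triads["bat_id"].isin(drop)].reset_index(drop=True)
    bouts = colony.bouts[
        ~(colony.bouts["actor"].isin(drop) | colony.bouts["receiver"].isin(drop))
    ].reset_index(drop=True)
    return colony.replace(bats=bats, triads=triads, bouts=bouts)
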
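"""Data model and validation for a forced-proximity colony experiment.

The experimental design this package analyses has three consecutive phases:

* ``PRE`` — several weeks of free association in a common flight cage;
* ``FORCED`` — a short period during which the colony is partitioned into
  small observation cages ("triads"), each holding exactly one bat from
  every capture site, so that cage-mates are previously unfamiliar;
* ``POST`` — free association again, during which any enduring effect of
  the forced proximity can express itself.

A :class:`Colony` bundles the five tables the analysis needs — individuals,
phase calendar, triad membership, daily observation sessions and directed
allogrooming bouts — together with an optional set of dyads excluded by a
robustness filter.  All tables are plain :class:`pandas.DataFrame` objects
with the column layout given by the ``*_COLUMNS`` constants, which is also
the CSV interchange layout used by :mod:`bondperm.io`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass

import pandas as pd

PHASE_NAMES: tuple[str, str, str] = ("PRE", "FORCED", "POST")

BATS_COLUMNS = ("bat_id", "site", "excluded_low_sampling", "excluded_infection")
SESSIONS_COLUMNS = ("date", "phase", "hours_sampled")
TRIADS_COLUMNS = ("triad_id", "bat_id")
BOUTS_COLUMNS = ("date", "actor", "receiver", "duration_s")

#: Minimum scoreable bout duration, seconds.
DEFAULT_MIN_BOUT_S = 5.0
#: Plausibility bounds for hours sampled in one session.
DEFAULT_HOURS_BOUNDS = (3.0, 6.0)


class ColonyValidationError(ValueError):
    """A colony table violates an experimental-design invariant."""


@dataclass(frozen=True)
class Phase:
    """One experimental phase with inclusive calendar bounds."""

    name: str
    start: dt.date
    end: dt.date

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class Colony:
    """A complete experimental dataset.

    Attributes
    ----------
    bats
        One row per individual: ``bat_id, site, excluded_low_sampling,
        excluded_infection``.
    phases
        The three :class:`Phase` records, ordered PRE < FORCED < POST.
    triads
        Long-format forced-proximity membership: ``triad_id, bat_id``.
    sessions
        One row per sampled day: ``date, phase, hours_sampled``.
    bouts
        Directed grooming events: ``date, actor, receiver, duration_s``.
    excluded_dyads
        Canonically ordered pairs removed from dyad-level analyses by a
        robustness filter (empty for raw data).
    """

    bats: pd.DataFrame
    phases: tuple[Phase, ...]
    triads: pd.DataFrame
    sessions: pd.DataFrame
    bouts: pd.DataFrame
    excluded_dyads: frozenset = frozenset()

    # -- convenience lookups -------------------------------------------------

    @property
    def bat_ids(self) -> list:
        return sorted(self.bats["bat_id"])

    @property
    def sites(self) -> list:
        return sorted(self.bats["site"].unique())

    def site_of(self) -> dict:
        return dict(zip(self.bats["bat_id"], self.bats["site"]))

    def triad_of(self) -> dict:
        return dict(zip(self.triads["bat_id"], self.triads["triad_id"]))

    def phase_by_name(self, name: str) -> Phase:
        for ph in self.phases:
            if ph.name == name:
                return ph
        raise ValueError(f"unknown phase {name!r}; expected one of {PHASE_NAMES}")

    def replace(self, **changes) -> "Colony":
        return dataclasses.replace(self, **changes)


def canonical_dyad(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) under the canonical lexicographic key."""
    if a == b:
        raise ValueError(f"a dyad needs two distinct bats, got {a!r} twice")
    return (a, b) if a < b else (b, a)


def _frames_equal(x: pd.DataFrame, y: pd.DataFrame) -> bool:
    x = x.reset_index(drop=True)
    y = y.reset_index(drop=True)
    if list(x.columns) != list(y.columns) or len(x) != len(y):
        return False
    for col in x.columns:
        a, b = x[col], y[col]
        if pd.api.types.is_float_dtype(a) and pd.api.types.is_float_dtype(b):
            if not ((a == b) | (a.isna() & b.isna())).all():
                return False
        elif not (a.astype(object) == b.astype(object)).all():
            return False
    return True


def colonies_equal(a: Colony, b: Colony) -> bool:
    """Exact equality of two colonies (tables, phases and exclusions)."""
    return (
        a.phases == b.phases
        and a.excluded_dyads == b.excluded_dyads
        and _frames_equal(a.bats, b.bats)
        and _frames_equal(a.triads, b.triads)
        and _frames_equal(a.sessions, b.sessions)
        and _frames_equal(a.bouts, b.bouts)
    )


def _require_columns(frame: pd.DataFrame, columns, label: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ColonyValidationError(f"{label} table is missing columns {missing}")


def validate_colony(
    colony: Colony,
    *,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
    hours_bounds: tuple | None = DEFAULT_HOURS_BOUNDS,
    check_triads: bool = True,
) -> None:
    """Check every design invariant; raise :class:`ColonyValidationError` on failure.

    ``check_triads=False`` relaxes the site-completeness and partition checks,
    which a bat-level robustness filter necessarily breaks.
    """
    _require_columns(colony.bats, BATS_COLUMNS, "bats")
    _require_columns(colony.sessions, SESSIONS_COLUMNS, "sessions")
    _require_columns(colony.triads, TRIADS_COLUMNS, "triads")
    _require_columns(colony.bouts, BOUTS_COLUMNS, "bouts")

    ids = colony.bats["bat_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ColonyValidationError(f"duplicate bat_id values: {dupes}")
    known = set(ids)
    site_of = colony.site_of()

    # phases: all three present, ordered, non-overlapping
    names = tuple(ph.name for ph in colony.phases)
    if names != PHASE_NAMES:
        raise ColonyValidationError(f"phases must be {PHASE_NAMES} in order, got {names}")
    for ph in colony.phases:
        if ph.end < ph.start:
            raise ColonyValidationError(f"phase {ph.name} ends before it starts")
    for prev, nxt in zip(colony.phases, colony.phases[1:]):
        if nxt.start <= prev.end:
            raise ColonyValidationError(f"phases {prev.name} and {nxt.name} overlap or are out of order")

    # triads
    tri_members = colony.triads["bat_id"]
    unknown = sorted(set(tri_members) - known)
    if unknown:
        raise ColonyValidationError(f"triads reference unknown bats: {unknown}")
    if tri_members.duplicated().any():
        dupes = sorted(tri_members[tri_members.duplicated()].unique())
        raise ColonyValidationError(f"bats assigned to more than one triad: {dupes}")
    if check_triads:
        if set(tri_members) != known:
            missing = sorted(known - set(tri_members))
            raise ColonyValidationError(f"bats missing a triad assignment: {missing}")
        all_sites = set(colony.bats["site"])
        for triad_id, grp in colony.triads.groupby("triad_id"):
            sites = [site_of[b] for b in grp["bat_id"]]
            if len(set(sites)) != len(sites):
                raise ColonyValidationError(
                    f"triad {triad_id!r} has two members from the same site"
                )
            if set(sites) != all_sites:
                raise ColonyValidationError(
                    f"triad {triad_id!r} is not site-complete (sites {sorted(set(sites))})"
                )

    # sessions
    sess = colony.sessions
    bad_phase = sess.index[~sess["phase"].isin(PHASE_NAMES)].tolist()
    if bad_phase:
        raise ColonyValidationError(f"sessions rows {bad_phase} have unknown phase labels")
    if (sess["hours_sampled"] <= 0).any():
        rows = sess.index[sess["hours_sampled"] <= 0].tolist()
        raise ColonyValidationError(f"sessions rows {rows} have non-positive hours_sampled")
    if hours_bounds is not None:
        lo, hi = hours_bounds
        out = sess.index[(sess["hours_sampled"] < lo) | (sess["hours_sampled"] > hi)].tolist()
        if out:
            raise ColonyValidationError(
                f"sessions rows {out} have hours_sampled outside [{lo}, {hi}]"
            )
    phase_lut = {ph.name: ph for ph in colony.phases}
    bad_date = [
        i
        for i, (d, p) in enumerate(zip(sess["date"], sess["phase"]))
        if not phase_lut[p].contains(d)
    ]
    if bad_date:
        raise ColonyValidationError(f"sessions rows {bad_date} have dates outside their phase")

    # bouts
    bouts = colony.bouts
    if len(bouts):
        self_rows = bouts.index[bouts["actor"] == bouts["receiver"]].tolist()
        if self_rows:
            raise ColonyValidationError(f"bouts rows {self_rows} have actor == receiver")
        bad_ids = sorted((set(bouts["actor"]) | set(bouts["receiver"])) - known)
        if bad_ids:
            rows = bouts.index[
                bouts["actor"].isin(bad_ids) | bouts["receiver"].isin(bad_ids)
            ].tolist()
            raise ColonyValidationError(
                f"bouts rows {rows} reference unknown bat_id values {bad_ids}"
            )
        short = bouts.index[bouts["duration_s"] < min_bout_s].tolist()
        if short:
            raise ColonyValidationError(
                f"bouts rows {short} are shorter than the {min_bout_s} s minimum"
            )
        session_dates = set(sess["date"])
        off = bouts.index[[d not in session_dates for d in bouts["date"]]].tolist()
        if off:
            raise ColonyValidationError(f"bouts rows {off} fall on dates with no session")
        cross = forced_cross_cage_rows(colony)
        if cross:
            raise ColonyValidationError(
                f"bouts rows {cross} occur between different cages during FORCED"
            )


def forced_cross_cage_rows(colony: Colony) -> list:
    """Row indices of bouts between non-cage-mates during the FORCED phase."""
    forced = colony.phase_by_name("FORCED")
    triad_of = colony.triad_of()
    rows = []
    for i, (d, a, r) in enumerate(
        zip(colony.bouts["date"], colony.bouts["actor"], colony.bouts["receiver"])
    ):
        if forced.contains(d) and triad_of.get(a) != triad_of.get(r):
            rows.append(colony.bouts.index[i])
    return rows
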
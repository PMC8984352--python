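"""Shared fixtures: hand-built toy colonies and generated default colonies."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

from bondperm import Colony, Phase, SimConfig, generate_colony

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def build_colony(bats, triads, sessions, bouts, phases):
    """Assemble a Colony from plain tuples.

    bats: (bat_id, site[, low_sampling, infection]); triads: (triad_id, bat_id);
    sessions: (iso_date, phase, hours); bouts: (iso_date, actor, receiver, s).
    """
    bat_rows = [(b[0], b[1], b[2] if len(b) > 2 else False, b[3] if len(b) > 3 else False) for b in bats]
    return Colony(
        bats=pd.DataFrame(bat_rows, columns=["bat_id", "site", "excluded_low_sampling", "excluded_infection"]),
        phases=tuple(Phase(n, dt.date.fromisoformat(s), dt.date.fromisoformat(e)) for n, s, e in phases),
        triads=pd.DataFrame(triads, columns=["triad_id", "bat_id"]),
        sessions=pd.DataFrame(
            [(dt.date.fromisoformat(d), p, h) for d, p, h in sessions],
            columns=["date", "phase", "hours_sampled"],
        ),
        bouts=pd.DataFrame(
            [(dt.date.fromisoformat(d), a, r, s) for d, a, r, s in bouts],
            columns=["date", "actor", "receiver", "duration_s"],
        ),
    )


TOY_PHASES = [("PRE", "2020-01-01", "2020-01-02"), ("FORCED", "2020-01-03", "2020-01-03"),
              ("POST", "2020-01-04", "2020-01-05")]
TOY_SESSIONS = [("2020-01-01", "PRE", 3.0), ("2020-01-02", "PRE", 5.0),
                ("2020-01-03", "FORCED", 4.0),
                ("2020-01-04", "POST", 6.0), ("2020-01-05", "POST", 4.0)]


@pytest.fixture
def toy_colony():
    """Four bats, two sites, two duad 'cages'; bouts chosen for hand checking.

    PRE exposure 8 h, FORCED 4 h (cage-mates only), POST 10 h.
    """
    return build_colony(
        bats=[("ax1", "X"), ("ax2", "X"), ("by1", "Y"), ("by2", "Y")],
        triads=[("t1", "ax1"), ("t1", "by1"), ("t2", "ax2"), ("t2", "by2")],
        sessions=TOY_SESSIONS,
        bouts=[
            ("2020-01-01", "ax1", "by1", 30.0),
            ("2020-01-02", "ax1", "by1", 10.0),
            ("2020-01-01", "by1", "ax1", 20.0),
            ("2020-01-02", "ax1", "ax2", 16.0),
            ("2020-01-03", "ax1", "by1", 40.0),
            ("2020-01-04", "by1", "ax1", 50.0),
            ("2020-01-05", "ax2", "by2", 100.0),
        ],
        phases=TOY_PHASES,
    )


@pytest.fixture(scope="session")
def default_colony():
    """One colony at the full experimental design (21 bats, default rates)."""
    return generate_colony(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_colony():
    """Full design but shortened phases: cheap end-to-end exercises."""
    return generate_colony(SimConfig(seed=23, phase_lengths_days=(14, 7, 21)))
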
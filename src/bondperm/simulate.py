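"""Synthetic colony generator.

Emulates the statistical structure of a forced-proximity allogrooming
experiment so the whole inference pipeline can be exercised without any
external data: a colony of ``n_sites x bats_per_site`` bats; a PRE / FORCED
/ POST phase calendar; daily observation sessions with uniform 3-6 h of
sampling; random site-complete triads; and directed grooming bouts.

Generative model
----------------
For an unordered pair *p* the directed bout stream in each direction is
Poisson with per-hour intensity

    lambda_p = base_rate_lambda * familiarity_multiplier^[same site]
               * exp(eps_p),   eps_p ~ Normal(0, dyad_sd)

The dyad effect ``eps_p`` is shared by both directions of a pair (most
allogrooming is bidirectional).  Bout durations are ``5 + Exponential(
bout_mean_s)`` seconds — a hard 5 s floor matching the scoring minimum,
so every generated bout survives ingest filtering.  Expected grooming
seconds per hour are therefore ``x_p = lambda_p * D`` with
``D = 5 + bout_mean_s``.

The treatment effect is defined on the scale the analysis measures: for a
test dyad (cage-mates) in a treated phase the intensity is inflated to

    lambda'_p = ((1 + x_p) * exp(delta) - 1) / D

so that the pair's expected allogrooming log rate ``ln(1 + x)`` shifts by
exactly ``treatment_effect_delta``.  With ``delta = 0`` the generator is an
exact null.  During FORCED, only cage-mates are co-observable and only
their bouts are generated.

Reproducibility: one master seed; each pair owns a substream keyed by the
(site, within-site) indices of its two members, so enlarging the colony
leaves existing pairs' draws unchanged.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .colony import (
    BATS_COLUMNS,
    BOUTS_COLUMNS,
    SESSIONS_COLUMNS,
    TRIADS_COLUMNS,
    Colony,
    Phase,
    validate_colony,
)

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SimConfig:
    """Study-design and rate parameters of the generator.

    Defaults reproduce the design of the experiment this package targets:
    21 female bats, 7 from each of 3 capture sites; 42 days of free
    association, 7 days of forced proximity in 7 site-complete triads and
    63 days of free association afterwards; 3-6 h of video sampling per day.
    """

    n_sites: int = 3
    bats_per_site: int = 7
    phase_lengths_days: tuple = (42, 7, 63)
    hours_per_day: tuple = (3.0, 6.0)
    base_rate_lambda: float = 0.04
    familiarity_multiplier: float = 3.0
    treatment_effect_delta: float = 0.5
    treatment_in_forced: bool = True
    dyad_sd: float = 0.8
    bout_mean_s: float = 25.0
    start_date: dt.date = dt.date(2019, 6, 23)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 so unfamiliar dyads exist")
        if self.bats_per_site < 2:
            raise ValueError("bats_per_site must be >= 2 so familiar dyads exist")
        if len(self.phase_lengths_days) != 3 or any(d < 1 for d in self.phase_lengths_days):
            raise ValueError("phase_lengths_days must be three positive day counts")
        lo, hi = self.hours_per_day
        if not (0 < lo <= hi):
            raise ValueError("hours_per_day must be an increasing positive range")
        if self.base_rate_lambda < 0:
            raise ValueError("base_rate_lambda must be >= 0")
        if self.familiarity_multiplier <= 0:
            raise ValueError("familiarity_multiplier must be > 0")
        if self.treatment_effect_delta < 0:
            raise ValueError("treatment_effect_delta must be >= 0 (0 is the null model)")
        if self.dyad_sd < 0:
            raise ValueError("dyad_sd must be >= 0")
        if self.bout_mean_s <= 0:
            raise ValueError("bout_mean_s must be > 0")


def _phase_calendar(config: SimConfig):
    d_pre, d_forced, d_post = config.phase_lengths_days
    start = config.start_date
    pre = Phase("PRE", start, start + dt.timedelta(days=d_pre - 1))
    forced = Phase("FORCED", pre.end + dt.timedelta(days=1), pre.end + dt.timedelta(days=d_forced))
    post = Phase("POST", forced.end + dt.timedelta(days=1), forced.end + dt.timedelta(days=d_post))
    return pre, forced, post


def _treated_lambda(lam: float, delta: float, mean_dur: float) -> float:
    # shift ln(1 + lambda*D) by exactly delta; a silent pair (lam == 0)
    # has no behaviour to boost and stays silent
    if lam == 0.0:
        return 0.0
    x = lam * mean_dur
    return ((1.0 + x) * np.exp(delta) - 1.0) / mean_dur


def generate_colony(config: SimConfig) -> Colony:
    """Draw one synthetic colony; same config (incl. seed) gives an identical colony."""
    config.validate()
    pre, forced, post = _phase_calendar(config)
    phases = (pre, forced, post)

    sites = [f"s{i + 1:02d}" for i in range(config.n_sites)]
    bat_index = {}  # bat_id -> (site_idx, within_site_idx)
    bat_rows = []
    for i, site in enumerate(sites):
        for j in range(config.bats_per_site):
            bat_id = f"{site}b{j + 1:02d}"
            bat_index[bat_id] = (i, j)
            bat_rows.append((bat_id, site, False, False))
    bats = pd.DataFrame(bat_rows, columns=list(BATS_COLUMNS))

    # sessions: one per day, uniform hours on [lo, hi]
    hours_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    sess_rows = []
    for ph in phases:
        days = [ph.start + dt.timedelta(days=k) for k in range(ph.n_days)]
        hours = hours_rng.uniform(config.hours_per_day[0], config.hours_per_day[1], len(days))
        sess_rows.extend(zip(days, [ph.name] * len(days), hours))
    sessions = pd.DataFrame(sess_rows, columns=list(SESSIONS_COLUMNS))

    # triads: anchor site 1 in id order, independent uniform permutations of the rest
    triad_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    by_site = [sorted(b for b, (i, _) in bat_index.items() if i == s) for s in range(config.n_sites)]
    cols = [by_site[0]] + [list(triad_rng.permutation(by_site[s])) for s in range(1, config.n_sites)]
    triad_rows = []
    for k in range(config.bats_per_site):
        tid = f"t{k + 1:02d}"
        for col in cols:
            triad_rows.append((tid, col[k]))
    triads = pd.DataFrame(triad_rows, columns=list(TRIADS_COLUMNS))
    triad_of = dict(zip(triads["bat_id"], triads["triad_id"]))

    mean_dur = 5.0 + config.bout_mean_s
    phase_days = {
        ph.name: np.array([ph.start + dt.timedelta(days=k) for k in range(ph.n_days)], dtype=object)
        for ph in phases
    }
    phase_hours = {
        ph.name: sessions.loc[sessions["phase"] == ph.name, "hours_sampled"].to_numpy()
        for ph in phases
    }

    dates, actors, receivers, durations = [], [], [], []
    site_of = dict(zip(bats["bat_id"], bats["site"]))
    for a, b in combinations(sorted(bat_index), 2):
        ia, ja = bat_index[a]
        ib, jb = bat_index[b]
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2, ia, ja, ib, jb)))
        eps = rng.normal(0.0, config.dyad_sd)
        lam = config.base_rate_lambda * np.exp(eps)
        if site_of[a] == site_of[b]:
            lam *= config.familiarity_multiplier
        cage_mates = triad_of[a] == triad_of[b]
        for phase_name in ("PRE", "FORCED", "POST"):
            if phase_name == "FORCED" and not cage_mates:
                continue
            lam_phase = lam
            if cage_mates and (
                phase_name == "POST" or (phase_name == "FORCED" and config.treatment_in_forced)
            ):
                lam_phase = _treated_lambda(lam, config.treatment_effect_delta, mean_dur)
            days = phase_days[phase_name]
            hours = phase_hours[phase_name]
            for actor, receiver in ((a, b), (b, a)):
                counts = rng.poisson(lam_phase * hours)
                total = int(counts.sum())
                if total == 0:
                    continue
                dates.append(np.repeat(days, counts))
                actors.append(np.full(total, actor, dtype=object))
                receivers.append(np.full(total, receiver, dtype=object))
                durations.append(5.0 + rng.exponential(config.bout_mean_s, total))

    if dates:
        bouts = pd.DataFrame(
            {
                "date": np.concatenate(dates),
                "actor": np.concatenate(actors),
                "receiver": np.concatenate(receivers),
                "duration_s": np.concatenate(durations),
            }
        )
        bouts = bouts.sort_values(["date", "actor", "receiver"], kind="stable").reset_index(drop=True)
    else:
        bouts = pd.DataFrame(columns=list(BOUTS_COLUMNS))

    colony = Colony(bats=bats, phases=phases, triads=triads, sessions=sessions, bouts=bouts)
    validate_colony(colony, hours_bounds=config.hours_per_day)
    return colony


def generate_null_ensemble(config: SimConfig, n_datasets: int) -> list:
    """Independent null colonies (treatment effect forced to zero).

    Per-dataset seeds are derived deterministically from ``config.seed``, so
    the ensemble is reproducible and its members are pairwise independent.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    config.validate()
    child_seeds = np.random.SeedSequence(config.seed, spawn_key=(3,)).generate_state(n_datasets)
    colonies = []
    for s in child_seeds:
        cfg = dataclasses.replace(config, treatment_effect_delta=0.0, seed=int(s) % _MAX_SEED)
        colonies.append(generate_colony(cfg))
    return colonies


def config_from_dict(data: dict) -> SimConfig:
    """Build a :class:`SimConfig` from parsed YAML/JSON, with field checking."""
    data = dict(data)
    if "start_date" in data and isinstance(data["start_date"], str):
        data["start_date"] = dt.date.fromisoformat(data["start_date"])
    for key in ("phase_lengths_days", "hours_per_day"):
        if key in data:
            data[key] = tuple(data[key])
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {unknown}")
    return SimConfig(**data)
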
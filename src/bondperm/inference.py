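"""Resampling inference for dyadic rate changes.

Implements the statistics of the analysis:

* percentile-bootstrap confidence intervals on per-class mean changes in
  allogrooming log rates and on their TEST - CONTROL difference;
* a constrained permutation test whose null re-randomises the treatment
  itself — bats are re-assigned into possible new site-complete triads,
  dyad classes are relabelled accordingly, and the TEST - CONTROL mean
  change is recomputed with the observed per-dyad rates held fixed;
* the mean per-bat shift in the proportion of grooming directed to
  previously unfamiliar (different-site) partners;
* the trade-off correlation between each bat's change in grooming to
  familiar versus unfamiliar partners;
* rank-based linear models of test-dyad grooming (change on forced-phase
  rank; post rank on pre + forced ranks) with one-sided permutation
  p-values from shuffling forced-phase rates within each cage;
* Spearman correlations of forced-phase rates with pre- and post-phase
  rates.

Monte-Carlo p-values carry the add-one correction
``p = (1 + #{null >= observed}) / (1 + n)``, so ``p >= 1/(n + 1)`` always;
when a null space is small enough it is enumerated exhaustively and the
p-value is the exact tail proportion (the observed arrangement is a member
of the space, so ``p >= 1/N``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .colony import Colony
from .rates import dyad_changes, phase_rate_table

DEFAULT_N_RESAMPLES = 5000
DEFAULT_EXHAUSTIVE_CAP = 100_000


class DegenerateStatisticError(ValueError):
    """A statistic is undefined on the given data (e.g. a constant vector)."""


@dataclass
class ResamplingResult:
    """A point estimate with optional percentile CI, p-value and null draws."""

    statistic_name: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_resamples: int = 0
    null_distribution: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None
    #: two-sided OLS t-test companion for the rank models (None elsewhere)
    parametric_p: float | None = None


def _child_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# percentile bootstrap
# ---------------------------------------------------------------------------

def bootstrap_mean_ci(
    values,
    n_boot: int = DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: int = 0,
    statistic_name: str = "mean",
) -> ResamplingResult:
    """Percentile-bootstrap CI for a mean: resample with replacement, take
    empirical quantiles of the resampled means."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return ResamplingResult(
        statistic_name=statistic_name,
        estimate=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_boot,
        null_distribution=means,
        seed=seed,
    )


def group_change_summary(
    changes: pd.DataFrame,
    n_boot: int = DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Bootstrap mean change per dyad class plus the TEST - CONTROL difference.

    The resampling unit is the dyad within its class; the difference CI
    resamples the two classes independently.  Classes with no dyads are
    skipped with a warning.
    """
    out = {}
    deltas = {}
    for i, cls in enumerate(("TEST", "CONTROL", "FAMILIAR")):
        vals = changes.loc[changes["dyad_class"] == cls, "delta_log"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"no dyads in class {cls}; skipping its mean change")
            continue
        deltas[cls] = vals
        name = f"{cls.lower()}_mean_change"
        out[name] = bootstrap_mean_ci(
            vals, n_boot=n_boot, level=level, seed=_child_seed(seed, i), statistic_name=name
        )
    if "TEST" in deltas and "CONTROL" in deltas:
        t, c = deltas["TEST"], deltas["CONTROL"]
        rng = np.random.default_rng(_child_seed(seed, 3))
        bt = t[rng.integers(0, t.size, size=(n_boot, t.size))].mean(axis=1)
        bc = c[rng.integers(0, c.size, size=(n_boot, c.size))].mean(axis=1)
        diff = bt - bc
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(diff, [alpha, 1.0 - alpha])
        out["test_minus_control"] = ResamplingResult(
            statistic_name="test_minus_control",
            estimate=float(t.mean() - c.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
            n_resamples=n_boot,
            null_distribution=diff,
            seed=seed,
        )
    return out


# ---------------------------------------------------------------------------
# constrained triad re-assignment null
# ---------------------------------------------------------------------------

@dataclass
class TriadAssignmentSpace:
    """All site-complete partitions of a colony into triads.

    Bats from the first (anchor) site are fixed in sorted order, one per
    triad; an assignment is a choice of permutation for every other site's
    bats.  Distinct choices give distinct unlabeled partitions, so the
    space size is ``(n!)**(s-1)`` for ``s`` sites of ``n`` bats.
    """

    bats_by_site: list  # list of sorted bat-id lists, one per site

    def __post_init__(self):
        sizes = {len(b) for b in self.bats_by_site}
        if len(self.bats_by_site) < 2:
            raise ValueError("need at least two sites")
        if len(sizes) != 1:
            raise ValueError(f"sites must have equal numbers of bats, got sizes {sorted(sizes)}")

    @property
    def n_per_site(self) -> int:
        return len(self.bats_by_site[0])

    @property
    def count(self) -> int:
        return math.factorial(self.n_per_site) ** (len(self.bats_by_site) - 1)

    def all(self, max_count: int = 10_000_000):
        """Exhaustive list of assignments (tuples of triads); refuses above cap."""
        if self.count > max_count:
            raise ValueError(f"{self.count} assignments exceed max_count={max_count}")
        anchor = tuple(self.bats_by_site[0])
        out = []
        for perms in product(*(permutations(b) for b in self.bats_by_site[1:])):
            out.append(tuple(tuple(col[k] for col in (anchor, *perms)) for k in range(len(anchor))))
        return out

    def sample(self, rng: np.random.Generator):
        """One uniform draw: independent uniform permutations of each non-anchor site."""
        anchor = tuple(self.bats_by_site[0])
        perms = [tuple(rng.permutation(b)) for b in self.bats_by_site[1:]]
        return tuple(tuple(col[k] for col in (anchor, *perms)) for k in range(len(anchor)))


def triad_assignment_space(colony_or_bats) -> TriadAssignmentSpace:
    """Assignment space for a colony (or a bats table)."""
    bats = colony_or_bats.bats if isinstance(colony_or_bats, Colony) else colony_or_bats
    by_site = [
        sorted(grp["bat_id"]) for _, grp in bats.groupby("site", sort=True)
    ]
    return TriadAssignmentSpace(by_site)


def _delta_matrix(colony: Colony, changes: pd.DataFrame):
    """Symmetric matrix of cross-site dyad deltas (NaN elsewhere) + bat index."""
    index = {b: i for i, b in enumerate(colony.bat_ids)}
    n = len(index)
    mat = np.full((n, n), np.nan)
    cross = changes[changes["dyad_class"] != "FAMILIAR"]
    for a, b, d in zip(cross["bat_a"], cross["bat_b"], cross["delta_log"]):
        ia, ib = index[a], index[b]
        mat[ia, ib] = mat[ib, ia] = d
    return mat, index


def _assignment_stats(mat: np.ndarray, assignments_idx: np.ndarray, s_cross: float, c_cross: int):
    """TEST-minus-CONTROL mean deltas for a batch of assignments.

    ``assignments_idx`` has shape (m, n_triads, n_sites): bat indices per
    triad column.  Cross-site dyads missing a delta (NaN) are excluded from
    both the test and control means.
    """
    m = assignments_idx.shape[0]
    test_sum = np.zeros(m)
    test_cnt = np.zeros(m)
    n_sites = assignments_idx.shape[2]
    for u, v in combinations(range(n_sites), 2):
        vals = mat[assignments_idx[:, :, u], assignments_idx[:, :, v]]
        test_sum += np.nansum(vals, axis=1)
        test_cnt += np.isfinite(vals).sum(axis=1)
    ctrl_cnt = c_cross - test_cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        return test_sum / test_cnt - (s_cross - test_sum) / ctrl_cnt


def triad_permutation_test(
    colony: Colony,
    n_perm: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
    changes: pd.DataFrame | None = None,
) -> ResamplingResult:
    """Constrained permutation test of the TEST - CONTROL mean rate change.

    The null re-randomises the experimental assignment: bats are re-drawn
    into possible new site-complete triads, TEST/CONTROL labels follow the
    new triads, and the statistic is recomputed on the fixed per-dyad
    changes.  Familiar (same-site) dyads never enter the statistic.  The
    null is enumerated exhaustively when the assignment space has at most
    ``exhaustive_cap`` members, else sampled uniformly ``n_perm`` times
    with the add-one Monte-Carlo p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    if changes is None:
        changes = dyad_changes(colony)
    mat, index = _delta_matrix(colony, changes)
    upper = mat[np.triu_indices(mat.shape[0], k=1)]
    s_cross = float(np.nansum(upper))
    c_cross = int(np.isfinite(upper).sum())
    if c_cross < 2:
        raise ValueError("need at least two cross-site dyads with defined changes")

    triad_groups = [sorted(grp["bat_id"]) for _, grp in colony.triads.groupby("triad_id")]
    site_of = colony.site_of()
    observed_idx = np.array(
        [[[index[b] for b in sorted(tri, key=lambda x: site_of[x])] for tri in triad_groups]]
    )
    observed = float(_assignment_stats(mat, observed_idx, s_cross, c_cross)[0])

    space = triad_assignment_space(colony)
    if space.count < 2:
        raise ValueError("the design admits fewer than two distinct triad assignments")

    def to_idx(assignments):
        return np.array([[[index[b] for b in tri] for tri in asg] for asg in assignments])

    if space.count <= exhaustive_cap:
        null = _assignment_stats(mat, to_idx(space.all()), s_cross, c_cross)
        n_used = null.size
        tail = _tail_count(null, observed, alternative)
        p = tail / n_used
    else:
        rng = np.random.default_rng(seed)
        draws = [space.sample(rng) for _ in range(n_perm)]
        null = _assignment_stats(mat, to_idx(draws), s_cross, c_cross)
        n_used = n_perm
        p = (1.0 + _tail_count(null, observed, alternative)) / (1.0 + n_perm)

    return ResamplingResult(
        statistic_name="test_minus_control_permutation",
        estimate=observed,
        p_value=float(p),
        n_resamples=int(n_used),
        null_distribution=null,
        seed=seed,
    )


def _tail_count(null: np.ndarray, observed: float, alternative: str) -> float:
    if alternative == "greater":
        return float(np.sum(null >= observed))
    if alternative == "less":
        return float(np.sum(null <= observed))
    return float(np.sum(np.abs(null) >= abs(observed)))


# ---------------------------------------------------------------------------
# per-bat proportion shift and trade-off correlation
# ---------------------------------------------------------------------------

def _per_bat_proportions(colony: Colony, table: pd.DataFrame, phase: str, use_raw: bool) -> dict:
    site_of = colony.site_of()
    sub = table[(table["phase"] == phase)].dropna(subset=["rate_log"])
    vals = np.expm1(sub["rate_log"]) if use_raw else sub["rate_log"]
    props = {}
    for bat in colony.bat_ids:
        mask = (sub["bat_a"] == bat) | (sub["bat_b"] == bat)
        v = np.asarray(vals[mask], dtype=float)
        partners = np.where(sub.loc[mask, "bat_a"] == bat, sub.loc[mask, "bat_b"], sub.loc[mask, "bat_a"])
        unfam = np.array([site_of[p] != site_of[bat] for p in partners])
        total = v.sum()
        if total <= 0 or v.size == 0:
            continue  # proportion undefined for this bat in this phase
        props[bat] = float(v[unfam].sum() / total)
    return props


def proportion_unfamiliar_shift(
    colony: Colony,
    n_boot: int = DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: int = 0,
    use_raw: bool = False,
) -> ResamplingResult:
    """Mean per-bat change (POST - PRE) in the proportion of allogrooming log
    rate directed to previously unfamiliar (different-site) partners.

    Bats with zero total grooming rate in either phase have an undefined
    proportion and are dropped with a warning.  The bootstrap resamples
    bats.  ``use_raw=True`` sums back-transformed (s/h) rates instead of
    log rates.
    """
    table = phase_rate_table(colony)
    pre = _per_bat_proportions(colony, table, "PRE", use_raw)
    post = _per_bat_proportions(colony, table, "POST", use_raw)
    bats = sorted(set(pre) & set(post))
    dropped = sorted(set(colony.bat_ids) - set(bats))
    if dropped:
        warnings.warn(f"bats with undefined grooming proportion dropped: {dropped}")
    if not bats:
        raise ValueError("no bats with defined proportions in both phases")
    changes = np.array([post[b] - pre[b] for b in bats])
    res = bootstrap_mean_ci(
        changes, n_boot=n_boot, level=level, seed=seed,
        statistic_name="proportion_unfamiliar_shift",
    )
    return res


def tradeoff_correlation(
    colony: Colony,
    n_boot: int = DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: int = 0,
    changes: pd.DataFrame | None = None,
) -> ResamplingResult:
    """Pearson correlation, across bats, of mean grooming change to familiar
    partners versus mean change to previously unfamiliar partners.

    A clearly negative correlation would indicate a trade-off: bats that
    redirect grooming to new partners withdraw it from familiar ones.
    Percentile-bootstrap CI resamples bats; the two-sided p-value is the
    standard Pearson test on the observed pairs.
    """
    if changes is None:
        changes = dyad_changes(colony)
    fam_means, unfam_means = [], []
    for bat in colony.bat_ids:
        mask = (changes["bat_a"] == bat) | (changes["bat_b"] == bat)
        sub = changes[mask]
        fam = sub.loc[sub["dyad_class"] == "FAMILIAR", "delta_log"]
        unfam = sub.loc[sub["dyad_class"] != "FAMILIAR", "delta_log"]
        if fam.empty or unfam.empty:
            continue
        fam_means.append(fam.mean())
        unfam_means.append(unfam.mean())
    x = np.asarray(fam_means)
    y = np.asarray(unfam_means)
    if x.size < 3:
        raise ValueError("need at least 3 bats with changes to both partner types")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("correlation undefined: a change vector is constant")
    r, p = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xb, yb = x[idx], y[idx]
        xc = xb - xb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        boot = np.where(denom > 0, (xc * yc).sum(axis=1) / np.where(denom > 0, denom, 1.0), np.nan)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(boot, [alpha, 1.0 - alpha])
    return ResamplingResult(
        statistic_name="tradeoff_correlation",
        estimate=float(r),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        n_resamples=n_boot,
        null_distribution=boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank linear models with within-cage permutation nulls
# ---------------------------------------------------------------------------

def _test_dyad_table(colony: Colony) -> pd.DataFrame:
    """Per-test-dyad phase rates, change and cage id."""
    table = phase_rate_table(colony)
    test = table[table["dyad_class"] == "TEST"]
    wide = test.pivot_table(index=["bat_a", "bat_b"], columns="phase", values="rate_log").reset_index()
    triad_of = colony.triad_of()
    wide["triad_id"] = [triad_of[a] for a in wide["bat_a"]]
    if wide[["PRE", "FORCED", "POST"]].isna().any().any():
        raise ValueError("every TEST dyad needs defined PRE, FORCED and POST rates")
    wide["delta_log"] = wide["POST"] - wide["PRE"]
    if colony.excluded_dyads:
        keep = [(a, b) not in colony.excluded_dyads for a, b in zip(wide["bat_a"], wide["bat_b"])]
        wide = wide[keep].reset_index(drop=True)
    return wide


def _slope(x_cols: np.ndarray, y: np.ndarray) -> float:
    """First-column coefficient of OLS y ~ 1 + x_cols (closed form)."""
    X = np.column_stack([np.ones(len(y)), *x_cols.T]) if x_cols.ndim > 1 else np.column_stack(
        [np.ones(len(y)), x_cols]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def _within_cage_permutations(groups: list, values: np.ndarray, rng, n_perm: int, cap: int):
    """Yield permuted copies of ``values`` shuffled within each cage.

    ``groups`` is a list of index arrays, one per cage.  When the product
    of per-cage factorials is at most ``cap`` the full arrangement space is
    enumerated (exhaustive null); otherwise ``n_perm`` independent uniform
    draws are made.  Returns (array of permuted vectors, exhaustive flag).
    """
    n_states = 1
    for g in groups:
        n_states *= math.factorial(len(g))
    if n_states <= cap:
        out = []
        for perms in product(*(permutations(range(len(g))) for g in groups)):
            v = values.copy()
            for g, p in zip(groups, perms):
                v[g] = values[g][list(p)]
            out.append(v)
        return np.array(out), True
    out = np.empty((n_perm, values.size))
    for i in range(n_perm):
        v = values.copy()
        for g in groups:
            v[g] = values[rng.permutation(g)]
        out[i] = v
    return out, False


def _rank_lm(
    y_raw: np.ndarray,
    forced_raw: np.ndarray,
    groups: list,
    extra_raw: np.ndarray | None,
    n_perm: int,
    seed: int,
    exhaustive_cap: int,
    statistic_name: str,
) -> ResamplingResult:
    if np.unique(forced_raw).size < 2:
        raise DegenerateStatisticError("forced-phase predictor has fewer than 2 distinct values")
    y = stats.rankdata(y_raw)
    forced_rank = stats.rankdata(forced_raw)
    if extra_raw is not None:
        extra_rank = stats.rankdata(extra_raw)
        X_obs = np.column_stack([forced_rank, extra_rank])
    else:
        X_obs = forced_rank
    beta_obs = _slope(X_obs, y)

    # parametric companion p (two-sided OLS t-test on the forced coefficient)
    design = sm.add_constant(X_obs if X_obs.ndim > 1 else X_obs[:, None])
    fit = sm.OLS(y, design).fit()
    parametric_p = float(fit.pvalues[1])

    rng = np.random.default_rng(seed)
    permuted, exhaustive = _within_cage_permutations(groups, forced_raw.copy(), rng, n_perm, exhaustive_cap)
    null = np.empty(len(permuted))
    for i, f in enumerate(permuted):
        fr = stats.rankdata(f)
        Xp = np.column_stack([fr, extra_rank]) if extra_raw is not None else fr
        null[i] = _slope(Xp, y)
    if exhaustive:
        perm_p = float(np.mean(null >= beta_obs))
        n_used = len(null)
    else:
        perm_p = float((1.0 + np.sum(null >= beta_obs)) / (1.0 + n_perm))
        n_used = n_perm

    res = ResamplingResult(
        statistic_name=statistic_name,
        estimate=beta_obs,
        p_value=perm_p,
        n_resamples=int(n_used),
        null_distribution=null,
        seed=seed,
        parametric_p=parametric_p,
    )
    return res


def _cage_groups(wide: pd.DataFrame) -> list:
    return [np.asarray(g.index) for _, g in wide.groupby("triad_id")]


def rank_lm_change(
    colony: Colony,
    n_perm: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> ResamplingResult:
    """Rank regression of test-dyad change on forced-phase grooming rank.

    Response: rank of (POST - PRE) log-rate change; predictor: rank of the
    forced-proximity log rate; midranks for ties.  The one-sided permutation
    p-value shuffles forced-phase rates within each forced-proximity cage
    (the three dyads of a triad), preserving cage structure.
    """
    wide = _test_dyad_table(colony).reset_index(drop=True)
    return _rank_lm(
        wide["delta_log"].to_numpy(),
        wide["FORCED"].to_numpy(),
        _cage_groups(wide),
        None,
        n_perm,
        seed,
        exhaustive_cap,
        "rank_lm_change_forced_beta",
    )


def rank_lm_post(
    colony: Colony,
    n_perm: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> ResamplingResult:
    """Rank regression of post-phase grooming on pre- and forced-phase ranks.

    Reports the forced-proximity coefficient; the within-cage permutation
    moves only the forced-phase rates while pre-treatment ranks stay fixed.
    """
    wide = _test_dyad_table(colony).reset_index(drop=True)
    return _rank_lm(
        wide["POST"].to_numpy(),
        wide["FORCED"].to_numpy(),
        _cage_groups(wide),
        wide["PRE"].to_numpy(),
        n_perm,
        seed,
        exhaustive_cap,
        "rank_lm_post_forced_beta",
    )


def phase_correlations(colony: Colony) -> dict:
    """Spearman correlations of test-dyad forced-phase rates with post- and
    pre-phase rates (two-sided p-values)."""
    wide = _test_dyad_table(colony)
    out = {}
    for other, name in (("POST", "spearman_forced_post"), ("PRE", "spearman_forced_pre")):
        x = wide["FORCED"].to_numpy()
        y = wide[other].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateStatisticError(f"correlation undefined: constant rates ({name})")
        rho, p = stats.spearmanr(x, y)
        out[name] = ResamplingResult(
            statistic_name=name, estimate=float(rho), p_value=float(p), n_resamples=0
        )
    return out
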
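"""End-to-end orchestration: simulate or load a colony, compute rates,
run the full inference suite and write a reproducible report bundle.

Outputs written to the run directory:

* ``rates.csv``      — per-dyad, per-phase exposure and log rates;
* ``changes.csv``    — per-dyad POST - PRE changes with class labels;
* ``timecourse.csv`` — windowed log rates (time-course reporting);
* ``results.csv``    — one row per statistic (estimate, CI, p, seed);
* ``summary.md``     — human-readable summary of the group comparison,
  permutation test, proportion shift, trade-off and rank models;
* ``manifest.json``  — configuration, seeds, package version and a config
  hash, sufficient to reproduce every number in the report.

Everything is deterministic under a fixed seed: re-running an identical
configuration reproduces ``results.csv`` byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .colony import Colony
from .inference import (
    group_change_summary,
    phase_correlations,
    proportion_unfamiliar_shift,
    rank_lm_change,
    rank_lm_post,
    tradeoff_correlation,
    triad_permutation_test,
    _child_seed,
)
from .io import read_colony, write_colony, write_results
from .rates import ROBUSTNESS_FILTERS, apply_robustness_filter, dyad_changes, phase_rate_table, windowed_rates
from .simulate import SimConfig, generate_colony

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one of ``sim`` (generate a synthetic colony) or ``input_dir``
    (read CSV data) must be supplied.
    """

    out_dir: str
    sim: SimConfig | None = None
    input_dir: str | None = None
    filters: tuple = ()
    n_boot: int = 5000
    n_perm: int = 5000
    level: float = 0.95
    seed: int = 0
    window_days: int = 7
    min_bout_s: float = 5.0
    strict: bool = True

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("supply exactly one of sim or input_dir")
        for f in self.filters:
            if f not in ROBUSTNESS_FILTERS:
                raise ValueError(f"unknown filter {f!r}; expected one of {ROBUSTNESS_FILTERS}")


def _config_dict(config: RunConfig) -> dict:
    data = dataclasses.asdict(config)
    if config.sim is not None:
        data["sim"]["start_date"] = config.sim.start_date.isoformat()
    data["filters"] = list(config.filters)
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> rates -> inference -> report.

    Returns a dict with the colony, the rate/change tables, the
    :class:`ResamplingResult` objects and the output paths.  On failure,
    partial outputs in the run directory are removed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        return _run(config, out, written)
    except Exception:
        for path in written:
            Path(path).unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out: Path, written: list) -> dict:
    if config.sim is not None:
        colony = generate_colony(config.sim)
        write_colony(colony, out / "colony")
        logger.info("generated synthetic colony: %d bats, %d bouts", len(colony.bats), len(colony.bouts))
    else:
        colony = read_colony(config.input_dir, min_bout_s=config.min_bout_s, strict=config.strict)
        logger.info("read colony from %s: %d bats, %d bouts", config.input_dir, len(colony.bats), len(colony.bouts))

    for name in config.filters:
        colony = apply_robustness_filter(colony, name)
        logger.info("applied robustness filter %s", name)

    rates = phase_rate_table(colony)
    changes = dyad_changes(colony, table=rates)
    timecourse = windowed_rates(colony, config.window_days)

    rates_path = out / "rates.csv"
    rates.to_csv(rates_path, index=False)
    written.append(rates_path)
    changes_path = out / "changes.csv"
    changes.to_csv(changes_path, index=False)
    written.append(changes_path)
    tc_path = out / "timecourse.csv"
    timecourse.to_csv(tc_path, index=False)
    written.append(tc_path)

    seed = config.seed
    results = {}
    results.update(
        group_change_summary(changes, n_boot=config.n_boot, level=config.level, seed=_child_seed(seed, 10))
    )
    results["test_minus_control_permutation"] = triad_permutation_test(
        colony, n_perm=config.n_perm, seed=_child_seed(seed, 11), changes=changes
    )
    results["proportion_unfamiliar_shift"] = proportion_unfamiliar_shift(
        colony, n_boot=config.n_boot, level=config.level, seed=_child_seed(seed, 12)
    )
    results["tradeoff_correlation"] = tradeoff_correlation(
        colony, n_boot=config.n_boot, level=config.level, seed=_child_seed(seed, 13), changes=changes
    )
    results["rank_lm_change_forced_beta"] = rank_lm_change(colony, n_perm=config.n_perm, seed=_child_seed(seed, 14))
    results["rank_lm_post_forced_beta"] = rank_lm_post(colony, n_perm=config.n_perm, seed=_child_seed(seed, 15))
    results.update(phase_correlations(colony))

    results_path = out / "results.csv"
    write_results(results.values(), results_path)
    written.append(results_path)

    summary_path = out / "summary.md"
    summary_path.write_text(render_summary(colony, changes, results, config))
    written.append(summary_path)

    manifest = {
        "package": "bondperm",
        "version": __version__,
        "config": _config_dict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_bats": int(len(colony.bats)),
        "n_bouts": int(len(colony.bouts)),
        "n_excluded_dyads": int(len(colony.excluded_dyads)),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)

    return {
        "colony": colony,
        "rates": rates,
        "changes": changes,
        "timecourse": timecourse,
        "results": results,
        "paths": {
            "rates": rates_path,
            "changes": changes_path,
            "timecourse": tc_path,
            "results": results_path,
            "summary": summary_path,
            "manifest": manifest_path,
        },
    }


def _fmt(r, ci=True, p=False) -> str:
    parts = [f"{r.estimate:.3f}"]
    if ci and r.ci_low is not None:
        parts.append(f"[{r.ci_low:.3f}, {r.ci_high:.3f}]")
    if p and r.p_value is not None:
        parts.append(f"p = {r.p_value:.4g}")
    if getattr(r, "parametric_p", None) is not None:
        parts.append(f"(parametric p = {r.parametric_p:.4g})")
    return " ".join(parts)


def render_summary(colony: Colony, changes, results: dict, config: RunConfig) -> str:
    counts = changes["dyad_class"].value_counts()
    lines = [
        "# Forced-proximity analysis summary",
        "",
        f"Colony: {len(colony.bats)} bats, {len(colony.bouts)} grooming bouts, "
        f"{counts.get('TEST', 0)} test / {counts.get('CONTROL', 0)} control / "
        f"{counts.get('FAMILIAR', 0)} familiar dyads with defined changes.",
    ]
    if config.filters:
        lines.append(f"Robustness filters applied: {', '.join(config.filters)}.")
    lines += [
        "",
        "## Mean change in allogrooming log rate (POST - PRE), log s/h",
        "",
    ]
    for key, label in (
        ("test_mean_change", "Test dyads"),
        ("control_mean_change", "Control dyads"),
        ("familiar_mean_change", "Familiar dyads"),
    ):
        if key in results:
            lines.append(f"- {label}: {_fmt(results[key])}")
    if "test_minus_control_permutation" in results:
        perm = results["test_minus_control_permutation"]
        diff_ci = ""
        if "test_minus_control" in results:
            d = results["test_minus_control"]
            diff_ci = f" {_fmt(d)}"
        lines += [
            "",
            "## Constrained permutation test (triad re-assignment null)",
            "",
            f"- Test - control difference:{diff_ci}, one-sided permutation "
            f"p = {perm.p_value:.4g} ({perm.n_resamples} null assignments)",
        ]
    if "proportion_unfamiliar_shift" in results:
        lines += [
            "",
            "## Partner-type proportions and trade-off",
            "",
            f"- Mean shift in proportion of grooming to unfamiliar partners: "
            f"{_fmt(results['proportion_unfamiliar_shift'])}",
        ]
    if "tradeoff_correlation" in results:
        lines.append(
            f"- Familiar-vs-unfamiliar change correlation: {_fmt(results['tradeoff_correlation'], p=True)}"
        )
    lines += ["", "## Test-dyad rank models and phase correlations", ""]
    for key, label in (
        ("rank_lm_change_forced_beta", "Change ~ forced rank, forced beta"),
        ("rank_lm_post_forced_beta", "Post ~ pre + forced ranks, forced beta"),
    ):
        if key in results:
            lines.append(f"- {label}: {_fmt(results[key], ci=False, p=True)}")
    for key, label in (
        ("spearman_forced_post", "Spearman rho, forced vs post"),
        ("spearman_forced_pre", "Spearman rho, forced vs pre"),
    ):
        if key in results:
            lines.append(f"- {label}: {_fmt(results[key], ci=False, p=True)}")
    lines.append("")
    return "\n".join(lines)
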
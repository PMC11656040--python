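"""Monte-Carlo simulation study engine: bias, power and coverage.

Replicated cohorts are drawn across a grid of sample sizes, each requested
estimator is applied, and the replicate-level estimates are summarised into
bias, empirical SD, power (two-sided 5% Wald test) and 95% CI coverage, each
with its Monte-Carlo standard error:

* ``mcse_bias = empirical_sd / sqrt(n_reps)``
* ``mcse_power = sqrt(power * (1 - power) / n_reps)`` (same form for coverage)

Child seeds are derived deterministically from ``(master_seed, n, replicate)``
with a splittable counter-based scheme, so any subset of the grid is
reproducible independently of the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .config import SimConfig
from .errors import ConfigurationError, HetmrError
from .estimators import GroupEffects, method1, method2, rgmee, standard_mr
from .simulate import simulate_cohort

__all__ = [
    "StudyScenario",
    "child_seed",
    "run_replicates",
    "summarize",
    "power_curve",
    "plot_summary",
    "plot_power_curve",
]

logger = logging.getLogger("hetmr.study")

_METHODS: dict[str, Callable[[Cohort], Any]] = {
    "method1": method1,
    "method2": method2,
    "rgmee": rgmee,
    "standard_mr": standard_mr,
}

#: Fraction of failed fits in a (method, n) cell above which the cell is
#: flagged invalid rather than silently summarised.
_MAX_FAILURE_RATE = 0.01


def child_seed(master_seed: int, n: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence((int(master_seed), int(n), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class StudyScenario:
    """A replicated-simulation design over a sample-size grid."""

    base: SimConfig
    sample_sizes: tuple[int, ...]
    n_reps: int
    methods: tuple[str, ...] = ("method1", "method2")
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.n_reps < 2:
            raise ConfigurationError(f"n_reps must be >= 2, got {self.n_reps}")
        sizes = self.sample_sizes
        if not sizes or any(b <= a for a, b in zip(sizes, sizes[1:])) or sizes[0] < 1:
            raise ConfigurationError(
                f"sample_sizes must be strictly increasing positive integers, got {sizes}"
            )
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ConfigurationError(
                f"methods contains unknown entries {sorted(unknown)}; "
                f"choose from {sorted(_METHODS)}"
            )

    @property
    def truth(self) -> dict[str, float]:
        """Generating values of the three target parameters."""
        return {
            "beta1": self.base.beta1,
            "beta0": self.base.beta0,
            "diff": self.base.diff,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyScenario":
        """Read a scenario file: flat generator keys plus a nested ``study`` block."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "study" not in raw:
            raise ConfigurationError(
                f"scenario file {path} must contain a 'study' block"
            )
        study = dict(raw.pop("study"))
        base = SimConfig.from_dict(raw)
        try:
            return cls(
                base=base,
                sample_sizes=tuple(study.pop("sample_sizes")),
                n_reps=int(study.pop("n_reps")),
                methods=tuple(study.pop("methods", ("method1", "method2"))),
                master_seed=int(study.pop("master_seed", 0)),
            )
        except KeyError as err:
            raise ConfigurationError(f"study block is missing key {err}") from err


def _rows_from_fit(result: Any, method: str) -> list[dict[str, Any]]:
    if isinstance(result, GroupEffects):
        rows = []
        for p in ("beta1", "beta0", "diff"):
            est = result.estimate(p)
            rows.append(
                dict(
                    parameter=p,
                    estimate=est.value,
                    se=est.se,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    p_value=est.p_value,
                )
            )
        return rows
    parameter = "diff" if method == "rgmee" else "ace"
    return [
        dict(
            parameter=parameter,
            estimate=result.value,
            se=result.se,
            ci_low=result.ci_low,
            ci_high=result.ci_high,
            p_value=result.p_value,
        )
    ]


def run_replicates(scn: StudyScenario, progress: bool = False) -> pd.DataFrame:
    """Simulate and fit every (sample size, replicate) in the scenario.

    Returns a long table keyed by ``(method, parameter, n, replicate)``.
    Failed fits yield a single row with missing estimates and the error
    message in the ``error`` column; they are excluded and counted by
    :func:`summarize`.
    """
    records: list[dict[str, Any]] = []
    import warnings as _warnings

    for n in scn.sample_sizes:
        for r in range(scn.n_reps):
            cfg = scn.base.replace(n=n, seed=child_seed(scn.master_seed, n, r))
            cohort = simulate_cohort(cfg)
            for method in scn.methods:
                try:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        result = _METHODS[method](cohort)
                    rows = _rows_from_fit(result, method)
                    for row in rows:
                        row.update(method=method, n=n, replicate=r, error=None)
                        records.append(row)
                except HetmrError as err:
                    records.append(
                        dict(
                            method=method,
                            parameter=None,
                            n=n,
                            replicate=r,
                            estimate=np.nan,
                            se=np.nan,
                            ci_low=np.nan,
                            ci_high=np.nan,
                            p_value=np.nan,
                            error=str(err),
                        )
                    )
        if progress:
            logger.info("completed %d replicates at n=%d", scn.n_reps, n)
    cols = [
        "method",
        "parameter",
        "n",
        "replicate",
        "estimate",
        "se",
        "ci_low",
        "ci_high",
        "p_value",
        "error",
    ]
    return pd.DataFrame.from_records(records, columns=cols)


def summarize(
    replicates: pd.DataFrame,
    truth: dict[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(method, parameter, n) bias, SD, power and coverage with MCSEs.

    ``truth`` maps each parameter appearing in the table to its generating
    value.  Cells with more than 1% failed fits are flagged via the
    ``flag_invalid`` column rather than silently summarised.
    """
    failures = (
        replicates[replicates["error"].notna()]
        .groupby(["method", "n"])
        .size()
        .rename("n_failed")
    )
    ok = replicates[replicates["error"].isna()]
    for parameter in ok["parameter"].unique():
        if parameter not in truth:
            raise ConfigurationError(
                f"truth value missing for parameter {parameter!r}"
            )
    rows = []
    for (method, parameter, n), cell in ok.groupby(
        ["method", "parameter", "n"], sort=False
    ):
        true_val = truth[parameter]
        est = cell["estimate"].to_numpy()
        n_used = len(est)
        if n_used < 2:
            raise ConfigurationError(
                f"cell (method={method}, parameter={parameter}, n={n}) has fewer "
                "than 2 successful replicates"
            )
        sd = float(est.std(ddof=1))
        power = float((cell["p_value"] < alpha).mean())
        coverage = float(
            ((cell["ci_low"] <= true_val) & (true_val <= cell["ci_high"])).mean()
        )
        n_failed = int(failures.get((method, n), 0))
        rows.append(
            dict(
                method=method,
                parameter=parameter,
                n=n,
                n_reps_used=n_used,
                mean_estimate=float(est.mean()),
                bias=float(est.mean() - true_val),
                empirical_sd=sd,
                mcse_bias=sd / np.sqrt(n_used),
                power=power,
                mcse_power=float(np.sqrt(power * (1 - power) / n_used)),
                coverage=coverage,
                mcse_coverage=float(np.sqrt(coverage * (1 - coverage) / n_used)),
                n_failed=n_failed,
                flag_invalid=n_failed > _MAX_FAILURE_RATE * (n_used + n_failed),
            )
        )
    return pd.DataFrame(rows)


def power_curve(
    base: SimConfig,
    diffs: Sequence[float],
    sample_sizes: Sequence[int],
    n_reps: int,
    methods: Iterable[str] = ("method1", "method2"),
    master_seed: int = 0,
) -> pd.DataFrame:
    """Power to detect the moderated effect over a (diff, n) grid.

    Each ``diff`` is imposed by setting ``beta1 = beta0 + diff`` with
    ``beta0`` held fixed.  Power is the proportion of replicates whose
    two-sided 5% Wald test of the group difference rejects; the grid row
    carries its Monte-Carlo SE.
    """
    methods = tuple(methods)
    bad = [m for m in methods if m not in ("method1", "method2", "rgmee")]
    if bad:
        raise ConfigurationError(
            f"power_curve requires methods estimating the group difference; got {bad}"
        )
    frames = []
    for diff in diffs:
        cfg = base.replace(beta1=base.beta0 + diff)
        scn = StudyScenario(
            base=cfg,
            sample_sizes=tuple(sample_sizes),
            n_reps=n_reps,
            methods=methods,
            master_seed=master_seed,
        )
        reps = run_replicates(scn)
        summary = summarize(reps, scn.truth)
        part = summary[summary["parameter"] == "diff"][
            ["method", "n", "power", "mcse_power", "n_reps_used", "flag_invalid"]
        ].copy()
        part.insert(1, "diff", diff)
        frames.append(part)
        logger.info("power grid: finished diff=%g", diff)
    return pd.concat(frames, ignore_index=True)


# -- optional figures ------------------------------------------------------


def plot_summary(summary: pd.DataFrame, metric: str = "mean_estimate", truth: dict[str, float] | None = None):
    """Panel per parameter: a metric versus sample size, one line per method."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    parameters = list(summary["parameter"].unique())
    fig, axes = plt.subplots(1, len(parameters), figsize=(4 * len(parameters), 3.2), squeeze=False)
    for ax, parameter in zip(axes[0], parameters):
        sub = summary[summary["parameter"] == parameter]
        for method, line in sub.groupby("method"):
            line = line.sort_values("n")
            ax.plot(line["n"], line[metric], marker="o", label=method)
            if metric in ("power", "coverage"):
                mc = line[f"mcse_{metric}"]
                ax.fill_between(
                    line["n"],
                    line[metric] - 1.96 * mc,
                    line[metric] + 1.96 * mc,
                    alpha=0.2,
                )
        if truth and metric == "mean_estimate" and parameter in truth:
            ax.axhline(truth[parameter], ls="--", color="grey")
        if metric == "coverage":
            ax.axhline(0.95, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_title(parameter)
        ax.set_xlabel("sample size")
        ax.set_ylabel(metric)
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_power_curve(power: pd.DataFrame):
    """Power versus sample size, one panel per true difference."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    diffs = sorted(power["diff"].unique())
    fig, axes = plt.subplots(1, len(diffs), figsize=(4 * len(diffs), 3.2), squeeze=False)
    for ax, diff in zip(axes[0], diffs):
        sub = power[power["diff"] == diff]
        for method, line in sub.groupby("method"):
            line = line.sort_values("n")
            ax.plot(line["n"], line["power"], marker="o", label=method)
            ax.fill_between(
                line["n"],
                line["power"] - 1.96 * line["mcse_power"],
                line["power"] + 1.96 * line["mcse_power"],
                alpha=0.2,
            )
        ax.axhline(0.8, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"true difference {diff:g} g")
        ax.set_xlabel("sample size")
        ax.set_ylabel("power")
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
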
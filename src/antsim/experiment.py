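"""Run orchestration, lifetime metrics and multi-run aggregation.

A single run steps the world for ``duration / dt`` ticks and samples a
lifetime record every ``sample_interval`` ticks: the longest lifetime ever
observed (running maximum over ages at death and ages of the living), the
age of the oldest living organism, and the mean and root-mean-square
deviation of age-at-death over deaths since the previous sample.  These
are the three population curves of the lifetime-growth experiment;
repeating the run under identical parameters with different seeds and
averaging per tick across runs gives the aggregate curves.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, save_config
from .world import WorldState, init_world, step

__all__ = [
    "METRIC_COLUMNS",
    "LifetimeRecord",
    "RunResult",
    "AggregateCurves",
    "run_simulation",
    "run_many",
    "aggregate_runs",
    "write_curves",
    "read_curves",
    "plot_curves",
    "initial_cohort_mean_lifetime",
    "final_quarter_mean_lifetime",
    "lifetime_growth_summary",
]

METRIC_COLUMNS = [
    "tick", "time", "population", "births_total", "deaths_total",
    "max_lifetime_ever", "max_lifetime_current",
    "mean_lifetime", "sd_lifetime",
]


@dataclass(frozen=True)
class LifetimeRecord:
    """One sampled metrics row (lifetimes in simulated seconds)."""

    tick: int
    time: float
    population: int
    births_total: int
    deaths_total: int
    max_lifetime_ever: float
    max_lifetime_current: float
    mean_lifetime: float        # NaN when no deaths fell in the window
    sd_lifetime: float


@dataclass
class RunResult:
    config: SimConfig
    records: pd.DataFrame       # METRIC_COLUMNS schema
    events: list[dict]          # birth/death events in tick order
    final_state: WorldState


def _sample(state: WorldState, max_ever: float,
            window_lifetimes: list[float]) -> tuple[LifetimeRecord, float]:
    ages = [state.time - o.born_at for o in state.organisms.values()]
    max_current = max(ages) if ages else 0.0
    max_ever = max([max_ever, max_current] + window_lifetimes)
    if window_lifetimes:
        arr = np.asarray(window_lifetimes)
        mean_lt, sd_lt = float(arr.mean()), float(arr.std(ddof=0))
    else:
        mean_lt = sd_lt = math.nan
    rec = LifetimeRecord(
        tick=state.tick, time=state.time, population=state.population,
        births_total=state.births_total, deaths_total=state.deaths_total,
        max_lifetime_ever=max_ever, max_lifetime_current=max_current,
        mean_lifetime=mean_lt, sd_lifetime=sd_lt)
    return rec, max_ever


def run_simulation(config: SimConfig, out_dir=None,
                   tick_callback: Callable[[WorldState], None] | None = None,
                   progress_every: int = 0,
                   log: Callable[[str], None] | None = None) -> RunResult:
    """Run one simulation to completion; fully reproducible from the seed.

    When ``out_dir`` is given, writes ``config.txt``, ``metrics.csv`` (one
    row per sample) and ``events.jsonl`` there.  Extinction is not an
    error: sampling continues with zero population so aggregation grids
    stay aligned across runs.
    """
    state = init_world(config)
    records: list[LifetimeRecord] = []
    events: list[dict] = []
    window: list[float] = []
    max_ever = 0.0

    rec, max_ever = _sample(state, max_ever, window)
    records.append(rec)
    n_ticks = config.n_ticks
    for _ in range(n_ticks):
        step(state, config)
        new_events = state.drain_events()
        events.extend(new_events)
        window.extend(e["lifetime"] for e in new_events if e["type"] == "death")
        if state.tick % config.sample_interval == 0 or state.tick == n_ticks:
            rec, max_ever = _sample(state, max_ever, window)
            records.append(rec)
            window = []
        if tick_callback is not None:
            tick_callback(state)
        if log is not None and progress_every and state.tick % progress_every == 0:
            log(f"tick {state.tick}/{n_ticks} population={state.population} "
                f"births={state.births_total} deaths={state.deaths_total}")

    df = pd.DataFrame([r.__dict__ for r in records], columns=METRIC_COLUMNS)
    result = RunResult(config=config, records=df, events=events,
                       final_state=state)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.txt")
        write_metrics(df, out / "metrics.csv")
        with open(out / "events.jsonl", "w") as fh:
            for e in events:
                fh.write(json.dumps(e) + "\n")
    return result


def write_metrics(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, lineterminator="\n")


def run_many(config: SimConfig, n_runs: int, base_seed: int | None = None,
             log: Callable[[str], None] | None = None) -> list[RunResult]:
    """Repeat the run with identical parameters and per-run derived seeds."""
    base = config.seed if base_seed is None else base_seed
    seeds = _derive_seeds(base, n_runs)
    results = []
    for i, s in enumerate(seeds):
        if log is not None:
            log(f"run {i + 1}/{n_runs} (seed {s})")
        results.append(run_simulation(config.with_seed(s)))
    return results


def _derive_seeds(base_seed: int, n: int) -> list[int]:
    words = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(w) & 0x7FFFFFFF for w in words]


# ---------------------------------------------------------------------------
# aggregation across runs

@dataclass
class AggregateCurves:
    """Per-tick mean and RMS deviation of each metric across runs."""

    curves: pd.DataFrame        # tick, time, <metric>_mean, <metric>_sd
    n_runs: int


def aggregate_runs(runs: Sequence[pd.DataFrame]) -> AggregateCurves:
    """Average metric curves over runs sharing one sampling grid.

    NaN window metrics (samples with no deaths) are ignored pointwise; the
    deviation is the root-mean-square deviation about the mean (ddof 0).
    """
    if not runs:
        raise ValueError("aggregate_runs needs at least one run")
    grid = runs[0]["tick"].to_numpy()
    for i, df in enumerate(runs[1:], 1):
        if not np.array_equal(df["tick"].to_numpy(), grid):
            raise ValueError(f"run {i} has a different sampling grid")
    out = {"tick": grid, "time": runs[0]["time"].to_numpy()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN windows
        for col in METRIC_COLUMNS[2:]:
            stack = np.vstack([df[col].to_numpy(dtype=float) for df in runs])
            out[f"{col}_mean"] = np.nanmean(stack, axis=0)
            out[f"{col}_sd"] = np.nanstd(stack, axis=0, ddof=0)
    return AggregateCurves(curves=pd.DataFrame(out), n_runs=len(runs))


def write_curves(agg: AggregateCurves, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# runs={agg.n_runs}\n")
        agg.curves.to_csv(fh, index=False, lineterminator="\n")


def read_curves(path) -> AggregateCurves:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# runs="):
            raise ValueError("missing run-count header")
        n_runs = int(header.split("=", 1)[1])
        curves = pd.read_csv(fh)
    return AggregateCurves(curves=curves, n_runs=n_runs)


def plot_curves(agg: AggregateCurves, path) -> None:
    """Three lifetime curves with an RMS-deviation band (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = agg.curves
    fig, ax = plt.subplots(figsize=(8, 5))
    t = df["time"]
    for col, label, color in [
            ("max_lifetime_ever", "max lifetime (ever)", "tab:blue"),
            ("max_lifetime_current", "max lifetime (current)", "tab:green"),
            ("mean_lifetime", "mean lifetime", "tab:red")]:
        mean, sd = df[f"{col}_mean"], df[f"{col}_sd"]
        ax.plot(t, mean, label=label, color=color)
        ax.fill_between(t, mean - sd, mean + sd, color=color, alpha=0.2)
    ax.set_xlabel("simulated time (s)")
    ax.set_ylabel("lifetime (s)")
    ax.legend()
    ax.set_title(f"Lifetime growth under selection ({agg.n_runs} runs)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# lifetime-growth (evolutionary efficacy) summaries

def initial_cohort_mean_lifetime(result: RunResult) -> float:
    """Mean lifetime of the founding cohort (organisms born at t = 0).

    Founders still alive at the end of the run contribute their final age
    (a lower bound on their lifetime).
    """
    lifetimes = [e["lifetime"] for e in result.events
                 if e["type"] == "death" and e["born_at"] == 0.0]
    end = result.final_state.time
    lifetimes += [end - o.born_at for o in result.final_state.organisms.values()
                  if o.born_at == 0.0]
    return float(np.mean(lifetimes)) if lifetimes else math.nan


def final_quarter_mean_lifetime(result: RunResult) -> float:
    """The population's mean lifetime over the last quarter of the run.

    Mean age-at-death over deaths in the window; if the final quarter had
    no deaths (a saturated, long-lived population) the mean age of the
    living at run end is used instead.
    """
    end = result.final_state.time
    t0 = 0.75 * end
    deaths = [e["lifetime"] for e in result.events
              if e["type"] == "death" and e["time"] > t0]
    if deaths:
        return float(np.mean(deaths))
    ages = [end - o.born_at for o in result.final_state.organisms.values()]
    return float(np.mean(ages)) if ages else math.nan


def lifetime_growth_summary(results: Sequence[RunResult]) -> dict:
    """Per-run initial-cohort vs final-quarter lifetimes and improvement count."""
    initial = [initial_cohort_mean_lifetime(r) for r in results]
    final = [final_quarter_mean_lifetime(r) for r in results]
    improved = sum(1 for i, f in zip(initial, final)
                   if not math.isnan(f) and f > i)
    monotone = all(r.records["max_lifetime_ever"].is_monotonic_increasing
                   for r in results)
    return {
        "n_runs": len(results),
        "initial_cohort_mean": initial,
        "final_quarter_mean": final,
        "runs_improved": improved,
        "max_ever_monotone_all_runs": monotone,
    }
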
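"""End-to-end orchestration: detect -> tension -> Bell fit, per condition.

The pipeline consumes either a written dataset directory (cells.csv plus
traces.csv or events.csv) or generates a synthetic study in memory, and
produces per-condition reports: per-rate rupture-voltage statistics with
pairwise Welch tests, tension points, and the Bell fit with pore radius and
barrier.  All conventions and seeds are echoed into the report so any number
is reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bell_fit import (
    BellFitResult,
    TensionPoint,
    aggregate_by_rate,
    fit_bell,
)
from .config import Settings, default_settings
from .electro_model import CellElectricalModel, tension_and_rate_at
from .exceptions import DataValidationError
from .rupture_detect import RuptureEvent, batch_detect
from .synthetic_data import (
    Dataset,
    PopulationSpec,
    SimulationTruth,
    TraceNoiseSpec,
    calibrate_k0,
    events_from_frame,
    make_population,
    read_dataset,
    simulate_rupture_events,
    synthesize_traces,
    traces_from_frame,
)

__all__ = [
    "RunConfig",
    "ConditionReport",
    "make_tension_converter",
    "star_code",
    "rate_statistics",
    "run_synthetic_condition",
    "run_pipeline",
    "compare_conditions",
]

#: the six experimental voltage loading rates, V_pp per second
STANDARD_RATES = (0.003, 0.006, 0.012, 0.025, 0.05, 0.1)


def make_tension_converter(cell: CellElectricalModel, settings: Settings):
    """Tension converter (V, R_V) -> (sigma_e, R_sigma_e) for a representative cell."""

    def convert(v_pp: float, rate_vpp_per_s: float) -> tuple[float, float]:
        return tension_and_rate_at(
            v_pp,
            rate_vpp_per_s,
            cell,
            settings.medium,
            settings.field_model,
            settings.protocol.frequency_hz,
            settings.conventions,
            v_start_vpp=settings.protocol.v_start_vpp,
        )

    return convert


def star_code(p: float) -> str:
    """Significance stars: *** p<0.0005, ** p<0.005, * p<0.05, else n.s."""
    if not 0 <= p <= 1:
        raise ValueError("p-value outside [0, 1]")
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate groups: exact-equality shortcut
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def rate_statistics(
    events: Sequence[RuptureEvent], pairs: str = "consecutive"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-rate rupture-voltage statistics and pairwise Welch tests.

    Returns (summary, pairwise): the summary has one row per loading rate
    (n, mean, sd, censored count); the pairwise table compares consecutive
    rates (or all pairs) with two-sided Welch t-tests, the Fig-style star
    codes, and a Holm-adjusted column.
    """
    groups: dict[float, list[float]] = {}
    censored: dict[float, int] = {}
    for ev in events:
        rate = ev.loading_rate_vpp_per_s
        if ev.censored:
            censored[rate] = censored.get(rate, 0) + 1
        else:
            groups.setdefault(rate, []).append(ev.rupture_voltage_vpp)
    rates = sorted(set(groups) | set(censored))
    usable = [r for r in rates if len(groups.get(r, [])) >= 2]
    if len(usable) < 2:
        raise DataValidationError("rate_statistics needs >= 2 rates with >= 2 events")
    summary = pd.DataFrame(
        {
            "loading_rate_vpp_per_s": rates,
            "n": [len(groups.get(r, [])) for r in rates],
            "mean_rupture_voltage_vpp": [
                float(np.mean(groups[r])) if r in groups else math.nan for r in rates
            ],
            "sd_rupture_voltage_vpp": [
                float(np.std(groups[r], ddof=1)) if len(groups.get(r, [])) > 1 else math.nan
                for r in rates
            ],
            "n_censored": [censored.get(r, 0) for r in rates],
        }
    )
    if pairs == "consecutive":
        pairings = list(zip(usable[:-1], usable[1:]))
    elif pairs == "all":
        pairings = [(a, b) for i, a in enumerate(usable) for b in usable[i + 1 :]]
    else:
        raise ValueError("pairs must be 'consecutive' or 'all'")
    pvals = [
        _welch(np.asarray(groups[a]), np.asarray(groups[b])) for a, b in pairings
    ]
    holm = multipletests(pvals, method="holm")[1] if pvals else []
    pairwise = pd.DataFrame(
        {
            "rate_a": [a for a, _ in pairings],
            "rate_b": [b for _, b in pairings],
            "p_value": pvals,
            "stars": [star_code(p) for p in pvals],
            "p_holm": holm,
            "stars_holm": [star_code(p) for p in holm],
        }
    )
    return summary, pairwise


@dataclass
class ConditionReport:
    """Everything the pipeline derives for one experimental condition."""

    condition: str
    rate_summary: pd.DataFrame
    pairwise: pd.DataFrame
    points: list[TensionPoint]
    fit: BellFitResult
    n_input: int
    n_detected: int
    n_censored: int
    n_failed: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "rate_summary": self.rate_summary.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "tension_points": [
                {
                    "loading_rate_vpp_per_s": p.loading_rate_vpp_per_s,
                    "char_voltage_vpp": p.char_voltage_vpp,
                    "sigma_e_n_per_m": p.sigma_e_n_per_m,
                    "r_sigma_n_per_m_s": p.r_sigma_n_per_m_s,
                    "n": p.n,
                    "voltage_sd_vpp": p.voltage_sd_vpp,
                    "n_censored": p.n_censored,
                }
                for p in self.points
            ],
            "fit": self.fit.to_dict(),
            "counts": {
                "n_input": self.n_input,
                "n_detected": self.n_detected,
                "n_censored": self.n_censored,
                "n_failed": self.n_failed,
            },
        }


@dataclass
class RunConfig:
    """Configuration of a pipeline run over a dataset directory."""

    dataset_path: str | Path
    output_path: str | Path
    settings: Settings = field(default_factory=default_settings)
    estimator: str = "mean"
    pairs: str = "consecutive"
    seed: int = 0
    write_plots: bool = False
    detect_params: dict = field(default_factory=dict)


def _events_by_condition(
    dataset: Dataset, detect_params: dict
) -> tuple[dict[str, list[RuptureEvent]], dict[str, dict]]:
    """Detected (or pre-supplied) events grouped by condition label."""
    condition_of = dict(zip(dataset.cells["cell_id"], dataset.cells["condition"]))
    if dataset.traces is not None:
        traces = traces_from_frame(dataset.traces)
        events, summary = batch_detect(traces, **detect_params)
        summaries_proto = summary
    elif dataset.events is not None:
        events = events_from_frame(dataset.events)
        summaries_proto = None
    else:
        raise DataValidationError("dataset has neither traces nor events")
    by_cond: dict[str, list[RuptureEvent]] = {}
    for ev in events:
        cond = condition_of.get(ev.cell_id)
        if cond is None:
            raise DataValidationError(f"event {ev.cell_id} has no cell-table entry")
        by_cond.setdefault(str(cond), []).append(ev)
    summaries = {}
    for cond, evs in by_cond.items():
        n_cens = sum(e.censored for e in evs)
        summaries[cond] = {
            "n_input": len(evs),
            "n_detected": len(evs) - n_cens,
            "n_censored": n_cens,
            "n_failed": (summaries_proto or {}).get("n_failed", 0),
        }
    return by_cond, summaries


def _condition_report(
    condition: str,
    events: list[RuptureEvent],
    cell: CellElectricalModel,
    settings: Settings,
    estimator: str,
    pairs: str,
    counts: dict,
) -> ConditionReport:
    converter = make_tension_converter(cell, settings)
    summary, pairwise = rate_statistics(events, pairs=pairs)
    points = aggregate_by_rate(events, converter, estimator)
    fit = fit_bell(
        points,
        settings.physics,
        conventions={**settings.conventions.to_dict(), "estimator": estimator},
    )
    return ConditionReport(
        condition=condition,
        rate_summary=summary,
        pairwise=pairwise,
        points=points,
        fit=fit,
        **counts,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run detect -> tension -> fit over a dataset directory and write reports.

    Writes events.csv (if detection ran), tension_points.csv, fit_result.json
    per condition, and a combined report.json.  Deterministic given the
    dataset and configuration.
    """
    dataset = read_dataset(config.dataset_path)
    out = Path(config.output_path)
    out.mkdir(parents=True, exist_ok=True)
    by_cond, counts = _events_by_condition(dataset, config.detect_params)

    reports: dict[str, ConditionReport] = {}
    for cond in sorted(by_cond):
        sub = dataset.cells[dataset.cells["condition"] == cond]
        defaults = config.settings.cell
        cell = CellElectricalModel(
            radius_m=float(sub["radius_m"].mean()),
            crossover_hz=float(sub["fco_hz"].mean()),
            rho_cyt_ohm_m=defaults.rho_cyt_ohm_m,
            eps_cyto=defaults.eps_cyto,
            eps_mem=defaults.eps_mem,
            cell_id=f"representative-{cond}",
            condition=cond,
        )
        reports[cond] = _condition_report(
            cond,
            by_cond[cond],
            cell,
            config.settings,
            config.estimator,
            config.pairs,
            counts[cond],
        )

    report = {
        "settings": config.settings.to_dict(),
        "estimator": config.estimator,
        "seed": config.seed,
        "conditions": {c: r.to_dict() for c, r in reports.items()},
    }
    if len(reports) >= 2:
        table, flags = compare_conditions(list(reports.values()))
        report["comparison"] = {
            "table": table.to_dict(orient="records"),
            "monotonic": flags,
        }
    # per-condition artefacts
    all_events = [ev for evs in by_cond.values() for ev in evs]
    from .synthetic_data import events_to_frame

    events_to_frame(all_events).to_csv(out / "events.csv", index=False, float_format="%.17g")
    points_rows = []
    for cond, rep in reports.items():
        for p in rep.points:
            points_rows.append(
                {
                    "condition": cond,
                    "loading_rate_vpp_per_s": p.loading_rate_vpp_per_s,
                    "char_voltage_vpp": p.char_voltage_vpp,
                    "sigma_e_n_per_m": p.sigma_e_n_per_m,
                    "r_sigma_n_per_m_s": p.r_sigma_n_per_m_s,
                    "n": p.n,
                    "n_censored": p.n_censored,
                }
            )
    pd.DataFrame(points_rows).to_csv(
        out / "tension_points.csv", index=False, float_format="%.17g"
    )
    with open(out / "fit_result.json", "w") as fh:
        json.dump({c: r.fit.to_dict() for c, r in reports.items()}, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if config.write_plots:
        from . import plots

        for cond, rep in reports.items():
            plots.plot_bell_line(rep.points, rep.fit, out / f"bell_line_{cond}.png")
            plots.plot_voltage_histograms(by_cond[cond], out / f"histograms_{cond}.png")
    return report


def compare_conditions(
    reports: Sequence[ConditionReport],
) -> tuple[pd.DataFrame, dict]:
    """Tabulate per-condition estimates and flag monotonic trends.

    Conditions are compared in the order given; the flags report whether the
    fitted slopes increase and the radii and barriers decrease strictly along
    that order (the cholesterol-depletion signature).
    """
    if len(reports) < 2:
        raise DataValidationError("compare_conditions needs >= 2 condition reports")
    table = pd.DataFrame(
        {
            "condition": [r.condition for r in reports],
            "slope_n_per_m": [r.fit.slope_n_per_m for r in reports],
            "pore_radius_nm": [r.fit.pore_radius_nm for r in reports],
            "w0_kbt": [r.fit.w0_kbt for r in reports],
            "k0_per_s": [r.fit.k0_per_s for r in reports],
            "r_squared": [r.fit.r_squared for r in reports],
        }
    )
    radii = table["pore_radius_nm"].to_numpy()
    slopes = table["slope_n_per_m"].to_numpy()
    w0 = table["w0_kbt"].to_numpy()
    flags = {
        "slopes_strictly_increasing": bool(np.all(np.diff(slopes) > 0)),
        "radii_strictly_decreasing": bool(np.all(np.diff(radii) < 0)),
        "w0_strictly_decreasing": bool(np.all(np.diff(w0) < 0)),
    }
    return table, flags


@dataclass
class SyntheticConditionResult:
    """Fit and bookkeeping for one synthetic condition run end to end."""

    condition: str
    truth: SimulationTruth
    fit: BellFitResult
    points: list[TensionPoint]
    report: ConditionReport
    n_cells: int


def run_synthetic_condition(
    pore_radius_m: float,
    k0_per_s: float | None = None,
    settings: Settings | None = None,
    rates: Sequence[float] = STANDARD_RATES,
    n_cells_per_rate: int = 500,
    seed: int = 0,
    condition: str = "synthetic",
    detect: bool = True,
    noise: TraceNoiseSpec | None = None,
    heterogeneity: bool = False,
    estimator: str = "mean",
    dt: float = 0.01,
) -> SyntheticConditionResult:
    """Simulate one condition at several loading rates and run the full chain.

    ``k0_per_s=None`` calibrates k0 so the modal rupture voltage at
    0.05 V_pp/s sits near 6.5 V_pp, emulating conditions whose rupture windows
    coincide while their pore energetics differ.  With ``detect=True`` the
    events are recovered from synthesized brightness traces through the
    detector; otherwise the simulated events are used directly.
    """
    settings = settings or default_settings()
    rep_cell = settings.cell.representative_cell(condition)
    if k0_per_s is None:
        k0_per_s = calibrate_k0(
            pore_radius_m,
            rep_cell,
            settings.medium,
            settings.field_model,
            settings.physics,
            frequency_hz=settings.protocol.frequency_hz,
            conventions=settings.conventions,
        )
    truth = SimulationTruth(
        pore_radius_m=pore_radius_m,
        k0_per_s=k0_per_s,
        attempt_frequency_hz=settings.physics.attempt_frequency_hz,
        temperature_K=settings.physics.temperature_K,
    )
    master = np.random.default_rng(seed)
    noise = noise or TraceNoiseSpec()

    all_events: list[RuptureEvent] = []
    n_failed = 0
    for j, rate in enumerate(rates):
        ramp = settings.protocol.with_rate(rate)
        pop_seed = int(master.integers(2**31))
        sim_seed = int(master.integers(2**31))
        trace_seed = int(master.integers(2**31))
        cells = make_population(
            PopulationSpec(
                n_cells=n_cells_per_rate,
                radius_mean_m=settings.cell.radius_mean_m,
                radius_sd_m=settings.cell.radius_sd_m,
                crossover_mean_hz=settings.cell.crossover_mean_hz,
                crossover_sd_hz=settings.cell.crossover_sd_hz,
                heterogeneity=heterogeneity,
                condition=condition,
                seed=pop_seed,
            ),
            rho_cyt_ohm_m=settings.cell.rho_cyt_ohm_m,
            eps_cyto=settings.cell.eps_cyto,
            eps_mem=settings.cell.eps_mem,
        )
        # unique ids across rates
        cells = [replace(c, cell_id=f"{condition}-r{j}-{i:05d}") for i, c in enumerate(cells)]
        sim_events = simulate_rupture_events(
            cells,
            ramp,
            settings.field_model,
            settings.medium,
            truth,
            dt=dt,
            seed=sim_seed,
            conventions=settings.conventions,
        )
        if detect:
            traces = synthesize_traces(sim_events, ramp, noise, seed=trace_seed)
            events, summary = batch_detect(traces)
            n_failed += summary["n_failed"]
        else:
            events = sim_events
        all_events.extend(events)

    n_cens = sum(e.censored for e in all_events)
    counts = {
        "n_input": len(all_events),
        "n_detected": len(all_events) - n_cens,
        "n_censored": n_cens,
        "n_failed": n_failed,
    }
    report = _condition_report(
        condition, all_events, rep_cell, settings, estimator, "consecutive", counts
    )
    return SyntheticConditionResult(
        condition=condition,
        truth=truth,
        fit=report.fit,
        points=report.points,
        report=report,
        n_cells=len(all_events),
    )
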
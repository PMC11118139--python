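"""Synthetic cell populations, stochastic rupture, and brightness traces.

The generator emulates a microfluidic electroporation run: a population of
cells (radius and DEP crossover frequency, optionally heterogeneous) sits in
trap windows while the peak-to-peak voltage ramps linearly at 41 kHz; each
cell ruptures stochastically under a Bell hazard driven by the membrane
electrical tension,

    k(t) = k0 * exp(sigma_e(t) * A / kB T),

with ``A = pi r^2`` the pore area at the barrier top.  Rupture times are drawn
by inverse-CDF sampling on the numerically integrated cumulative hazard, so
the sampler is a generic first-passage machine that the analytic constant-rate
survival function can cross-check.

Two ramp modes exist:

- ``voltage-ramp``: the experimentally faithful mode; the tension follows the
  electrical chain and its loading rate varies in time (sigma ∝ V²).
- ``tension-ramp``: an idealised constant tension rate ``sigma = R_sigma t``,
  for which the survival function is known in closed form; used for tight
  oracle tests.

Brightness traces are synthesised as baseline + Gaussian noise with a step
increase (optionally a finite rise time) at the rupture moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid

from .electro_model import (
    CellElectricalModel,
    Conventions,
    FieldModel,
    MediumProperties,
    PhysicalContext,
    RampProtocol,
    tension_and_rate_at,
    tension_at,
)
from .exceptions import DataValidationError, GridResolutionError
from .rupture_detect import BrightnessTrace, RuptureEvent

__all__ = [
    "SimulationTruth",
    "PopulationSpec",
    "TraceNoiseSpec",
    "make_population",
    "simulate_rupture_events",
    "synthesize_traces",
    "calibrate_k0",
    "Dataset",
    "write_dataset",
    "read_dataset",
    "traces_from_frame",
    "events_to_frame",
    "events_from_frame",
]

#: cumulative hazard beyond which survival (< 1e-13) is treated as exhausted
_H_MAX = 30.0
#: survival level down to which the hazard-step criterion is enforced
_H_CHECK = -math.log(1e-4)


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of the Bell rupture kinetics.

    ``pore_radius_m`` sets the reaction coordinate as the pore *area*
    ``A = pi r^2``; ``k0_per_s`` is the zero-tension dissociation rate, and the
    implied barrier is ``W0/kBT = ln(v0 / k0)``.
    """

    pore_radius_m: float
    k0_per_s: float
    attempt_frequency_hz: float = 1e13
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.pore_radius_m < 0:
            raise ValueError("pore_radius_m must be >= 0")
        for name in ("k0_per_s", "attempt_frequency_hz", "temperature_K"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not math.isfinite(self.w0_kbt):
            raise ValueError("W0/kBT = ln(v0/k0) must be finite")

    @property
    def pore_area_m2(self) -> float:
        return math.pi * self.pore_radius_m**2

    @property
    def w0_kbt(self) -> float:
        return math.log(self.attempt_frequency_hz / self.k0_per_s)

    def physics(self) -> PhysicalContext:
        return PhysicalContext(
            temperature_K=self.temperature_K,
            attempt_frequency_hz=self.attempt_frequency_hz,
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Cell-population sampling parameters.

    With ``heterogeneity`` off (the default, used for recovery studies) every
    cell is identical at the stated means; with it on, radii and crossover
    frequencies are drawn from truncated-to-positive normals.
    """

    n_cells: int = 200
    radius_mean_m: float = 10e-6
    radius_sd_m: float = 1e-6
    crossover_mean_hz: float = 20e3
    crossover_sd_hz: float = 2e3
    heterogeneity: bool = False
    condition: str = "untreated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.radius_mean_m <= 0 or self.crossover_mean_hz <= 0:
            raise ValueError("population means must be positive")
        if self.radius_sd_m < 0 or self.crossover_sd_hz < 0:
            raise ValueError("population sds must be non-negative")


@dataclass(frozen=True)
class TraceNoiseSpec:
    """Grayscale trace model: baseline + noise, step (with rise time) at rupture."""

    baseline: float = 100.0
    noise_sd: float = 2.0
    jump: float = 10.0
    frame_rate_hz: float | None = None  # fall back to the protocol frame rate
    rise_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.rise_time_s < 0:
            raise ValueError("noise_sd and rise_time_s must be non-negative")
        if self.jump < 0:
            raise ValueError("jump must be non-negative")
        if self.frame_rate_hz is not None and not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")


def _positive_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal draws truncated to positive values by resampling."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def make_population(
    spec: PopulationSpec,
    rho_cyt_ohm_m: float = 2.0,
    eps_cyto: float = 80.0,
    eps_mem: float = 5.0,
) -> list[CellElectricalModel]:
    """Draw a cell population; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    r_sd = spec.radius_sd_m if spec.heterogeneity else 0.0
    f_sd = spec.crossover_sd_hz if spec.heterogeneity else 0.0
    radii = _positive_normal(rng, spec.radius_mean_m, r_sd, spec.n_cells)
    fcos = _positive_normal(rng, spec.crossover_mean_hz, f_sd, spec.n_cells)
    return [
        CellElectricalModel(
            radius_m=float(radii[i]),
            crossover_hz=float(fcos[i]),
            rho_cyt_ohm_m=rho_cyt_ohm_m,
            eps_cyto=eps_cyto,
            eps_mem=eps_mem,
            cell_id=f"{spec.condition}-{i:05d}",
            condition=spec.condition,
        )
        for i in range(spec.n_cells)
    ]


def _check_grid(k: np.ndarray, h: np.ndarray, dt: float) -> None:
    """Enforce the hazard-step criterion where survival mass remains.

    The per-step rupture probability ``k dt`` must stay below 0.1 wherever the
    survival probability exceeds 1e-4; beyond that point the distribution is
    exhausted and the step size no longer affects the sampled times.
    """
    mask = h <= _H_CHECK
    if np.any(mask):
        worst = float(np.max(k[mask]) * dt)
        if worst >= 0.1:
            raise GridResolutionError(
                f"hazard step k*dt reaches {worst:.3g} (>= 0.1) while survival "
                "is non-negligible; reduce dt"
            )


def _sample_first_passage(
    rng: np.random.Generator, t: np.ndarray, h: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-CDF sampling of first-passage times from a cumulative hazard grid."""
    e = rng.exponential(size=n)
    censored = e > h[-1]
    times = np.interp(e, h, t)
    times[censored] = np.nan
    return times, censored


def simulate_rupture_events(
    cells: Sequence[CellElectricalModel],
    ramp: RampProtocol,
    field_model: FieldModel,
    medium: MediumProperties,
    truth: SimulationTruth,
    mode: str = "voltage-ramp",
    dt: float = 0.01,
    seed: int = 0,
    tension_rate_n_per_m_s: float | None = None,
    conventions: Conventions = Conventions(),
) -> list[RuptureEvent]:
    """Simulate per-cell stochastic rupture under the Bell hazard.

    In ``voltage-ramp`` mode the tension follows the electrical chain along the
    protocol ramp; in ``tension-ramp`` mode it grows at the constant rate
    ``tension_rate_n_per_m_s`` (the ramp/field/medium electrical chain is
    bypassed).  Cells that survive the ramp are returned censored.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    physics = truth.physics()
    a_over_kt = truth.pore_area_m2 / physics.kT
    log_k0 = math.log(truth.k0_per_s)

    events: list[RuptureEvent] = []
    if mode == "voltage-ramp":
        t = np.arange(0.0, ramp.duration_s + 0.5 * dt, dt)
        t[-1] = min(t[-1], ramp.duration_s)
        cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for cell in cells:
            key = (
                cell.radius_m,
                cell.crossover_hz,
                cell.rho_cyt_ohm_m,
                cell.eps_cyto,
                cell.eps_mem,
            )
            if key not in cache:
                sigma = np.asarray(
                    tension_at(
                        ramp.voltage_at(t),
                        cell,
                        medium,
                        field_model,
                        ramp.frequency_hz,
                        conventions,
                    )
                )
                k = np.exp(np.minimum(log_k0 + a_over_kt * sigma, 700.0))
                h = cumulative_trapezoid(k, t, initial=0.0)
                _check_grid(k, h, dt)
                cache[key] = (sigma, k, h)
            sigma, k, h = cache[key]
            t_r, censored = _sample_first_passage(rng, t, h, 1)
            t_r, censored = float(t_r[0]), bool(censored[0])
            if censored:
                events.append(
                    RuptureEvent(
                        cell_id=cell.cell_id,
                        rupture_voltage_vpp=math.nan,
                        censored=True,
                        loading_rate_vpp_per_s=ramp.rate_vpp_per_s,
                    )
                )
            else:
                v_r = float(ramp.voltage_at(t_r))
                sig_r = float(np.interp(t_r, t, sigma))
                events.append(
                    RuptureEvent(
                        cell_id=cell.cell_id,
                        rupture_voltage_vpp=v_r,
                        censored=False,
                        rupture_time_s=t_r,
                        rupture_tension_n_per_m=sig_r,
                        loading_rate_vpp_per_s=ramp.rate_vpp_per_s,
                        tension_rate_n_per_m_s=2.0 * sig_r / v_r * ramp.rate_vpp_per_s,
                    )
                )
    elif mode == "tension-ramp":
        if tension_rate_n_per_m_s is None or tension_rate_n_per_m_s <= 0:
            raise ValueError("tension-ramp mode requires a positive tension rate")
        r_sigma = tension_rate_n_per_m_s
        if a_over_kt > 0:
            sigma_end = math.log1p(_H_MAX * a_over_kt * r_sigma / truth.k0_per_s) / a_over_kt
            duration = sigma_end / r_sigma
        else:
            duration = _H_MAX / truth.k0_per_s
        n_grid = int(min(max(duration / dt + 1, 2001), 2_000_001))
        t = np.linspace(0.0, duration, n_grid)
        step = t[1] - t[0]
        sigma = r_sigma * t
        k = np.exp(np.minimum(log_k0 + a_over_kt * sigma, 700.0))
        h = cumulative_trapezoid(k, t, initial=0.0)
        _check_grid(k, h, step)
        times, censored = _sample_first_passage(rng, t, h, len(cells))
        for i, cell in enumerate(cells):
            if censored[i]:
                events.append(
                    RuptureEvent(
                        cell_id=cell.cell_id,
                        rupture_voltage_vpp=math.nan,
                        censored=True,
                        tension_rate_n_per_m_s=r_sigma,
                    )
                )
            else:
                events.append(
                    RuptureEvent(
                        cell_id=cell.cell_id,
                        rupture_voltage_vpp=math.nan,
                        censored=False,
                        rupture_time_s=float(times[i]),
                        rupture_tension_n_per_m=float(r_sigma * times[i]),
                        tension_rate_n_per_m_s=r_sigma,
                    )
                )
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'voltage-ramp' or 'tension-ramp'")
    return events


def calibrate_k0(
    pore_radius_m: float,
    cell: CellElectricalModel,
    medium: MediumProperties,
    field_model: FieldModel,
    physics: PhysicalContext,
    target_voltage_vpp: float = 6.5,
    rate_vpp_per_s: float = 0.05,
    frequency_hz: float = 41e3,
    conventions: Conventions = Conventions(),
) -> float:
    """Zero-tension rate k0 placing the modal rupture voltage at a target.

    Inverts the most-probable-tension relation at the local tension loading
    rate: ``k0 = R_sigma(V*) * (A/kBT) * exp(-sigma(V*) * A/kBT)``.  Used to
    emulate experimental conditions whose rupture-voltage windows coincide
    while their pore energetics differ (e.g. cholesterol depletion).
    """
    sigma, r_sigma = tension_and_rate_at(
        target_voltage_vpp,
        rate_vpp_per_s,
        cell,
        medium,
        field_model,
        frequency_hz,
        conventions,
    )
    a_over_kt = math.pi * pore_radius_m**2 / physics.kT
    return r_sigma * a_over_kt * math.exp(-a_over_kt * sigma)


def synthesize_traces(
    events: Sequence[RuptureEvent],
    ramp: RampProtocol,
    noise: TraceNoiseSpec = TraceNoiseSpec(),
    seed: int = 0,
) -> list[BrightnessTrace]:
    """Synthesize one brightness trace per event at the protocol frame rate.

    Intensity is baseline + Gaussian noise; non-censored cells gain the jump
    (linear rise over ``rise_time_s``) from their rupture time onward.
    """
    frame_rate = noise.frame_rate_hz or ramp.frame_rate_hz
    n_frames = int(math.floor(ramp.duration_s * frame_rate)) + 1
    if n_frames < 10:
        raise DataValidationError(
            f"frame rate x ramp duration gives {n_frames} frames (< 10); "
            "a rupture step would be undetectable"
        )
    for ev in events:
        if not ev.censored:
            if not (
                ramp.v_start_vpp <= ev.rupture_voltage_vpp <= ramp.v_end_vpp
            ) or not math.isfinite(ev.rupture_time_s):
                raise DataValidationError(
                    f"event {ev.cell_id}: rupture outside the ramp range"
                )
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    v = np.asarray(ramp.voltage_at(t))
    traces: list[BrightnessTrace] = []
    for ev in events:
        intensity = noise.baseline + rng.normal(0.0, noise.noise_sd, size=n_frames)
        if not ev.censored:
            if noise.rise_time_s > 0:
                factor = np.clip((t - ev.rupture_time_s) / noise.rise_time_s, 0.0, 1.0)
            else:
                factor = (t >= ev.rupture_time_s).astype(float)
            intensity = intensity + noise.jump * factor
        traces.append(
            BrightnessTrace(
                cell_id=ev.cell_id,
                time_s=t,
                voltage_vpp=v,
                intensity=intensity,
                loading_rate_vpp_per_s=ramp.rate_vpp_per_s,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# dataset I/O (CSV tables + YAML metadata)

_CELL_COLUMNS = ["cell_id", "condition", "radius_m", "fco_hz"]
_TRACE_COLUMNS = ["cell_id", "frame", "time_s", "voltage_vpp", "intensity"]
_EVENT_COLUMNS = ["cell_id", "rupture_voltage_vpp", "censored", "true_rupture_time_s"]


@dataclass
class Dataset:
    """In-memory view of a dataset directory."""

    cells: pd.DataFrame
    events: pd.DataFrame | None = None
    traces: pd.DataFrame | None = None
    meta: dict | None = None


def cells_to_frame(cells: Sequence[CellElectricalModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "condition": [c.condition for c in cells],
            "radius_m": [c.radius_m for c in cells],
            "fco_hz": [c.crossover_hz for c in cells],
        }
    )


def events_to_frame(events: Sequence[RuptureEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [e.cell_id for e in events],
            "rupture_voltage_vpp": [e.rupture_voltage_vpp for e in events],
            "censored": [e.censored for e in events],
            "true_rupture_time_s": [e.rupture_time_s for e in events],
            "loading_rate_vpp_per_s": [e.loading_rate_vpp_per_s for e in events],
            "rupture_tension_n_per_m": [e.rupture_tension_n_per_m for e in events],
        }
    )


def events_from_frame(events: pd.DataFrame) -> list[RuptureEvent]:
    out = []
    for row in events.itertuples(index=False):
        out.append(
            RuptureEvent(
                cell_id=str(row.cell_id),
                rupture_voltage_vpp=float(row.rupture_voltage_vpp),
                censored=bool(row.censored),
                rupture_time_s=float(getattr(row, "true_rupture_time_s", math.nan)),
                rupture_tension_n_per_m=float(
                    getattr(row, "rupture_tension_n_per_m", math.nan)
                ),
                loading_rate_vpp_per_s=float(
                    getattr(row, "loading_rate_vpp_per_s", math.nan)
                ),
            )
        )
    return out


def traces_to_frame(traces: Sequence[BrightnessTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.time_s,
                    "voltage_vpp": tr.voltage_vpp,
                    "intensity": tr.intensity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def traces_from_frame(traces: pd.DataFrame) -> list[BrightnessTrace]:
    out = []
    for cell_id, grp in traces.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            BrightnessTrace(
                cell_id=str(cell_id),
                time_s=grp["time_s"].to_numpy(),
                voltage_vpp=grp["voltage_vpp"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out


def _validate_tables(
    cells: pd.DataFrame,
    events: pd.DataFrame | None,
    traces: pd.DataFrame | None,
) -> None:
    for name, df, cols in (
        ("cells", cells, _CELL_COLUMNS),
        ("events", events, _EVENT_COLUMNS),
        ("traces", traces, _TRACE_COLUMNS),
    ):
        if df is None:
            continue
        missing = set(cols) - set(df.columns)
        if missing:
            raise DataValidationError(f"{name} table missing columns: {sorted(missing)}")
    if cells["cell_id"].duplicated().any():
        dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
        raise DataValidationError(f"duplicate cell_id in cells table: {dups[:5]}")
    known = set(cells["cell_id"])
    for name, df in (("events", events), ("traces", traces)):
        if df is None:
            continue
        if len(df) == 0:
            raise DataValidationError(
                f"{name} table is empty while the cell table is not"
            )
        unknown = set(df["cell_id"]) - known
        if unknown:
            raise DataValidationError(
                f"{name} table references unknown cell ids: {sorted(unknown)[:5]}"
            )
    if events is not None and events["cell_id"].duplicated().any():
        raise DataValidationError("duplicate cell_id in events table")


def write_dataset(
    path: str | Path,
    cells: Sequence[CellElectricalModel] | pd.DataFrame,
    events: Sequence[RuptureEvent] | pd.DataFrame | None = None,
    traces: Sequence[BrightnessTrace] | pd.DataFrame | None = None,
    meta: dict | None = None,
) -> Path:
    """Write a dataset directory (cells.csv, events.csv, traces.csv, meta.yaml).

    The CSV round-trip is lossless for numeric fields (17 significant digits).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells_df = cells if isinstance(cells, pd.DataFrame) else cells_to_frame(cells)
    events_df = (
        events
        if isinstance(events, pd.DataFrame) or events is None
        else events_to_frame(events)
    )
    traces_df = (
        traces
        if isinstance(traces, pd.DataFrame) or traces is None
        else traces_to_frame(traces)
    )
    _validate_tables(cells_df, events_df, traces_df)
    cells_df.to_csv(path / "cells.csv", index=False, float_format="%.17g")
    if events_df is not None:
        events_df.to_csv(path / "events.csv", index=False, float_format="%.17g")
    if traces_df is not None:
        traces_df.to_csv(path / "traces.csv", index=False, float_format="%.17g")
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta or {}, fh, sort_keys=True)
    return path


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    cells_path = path / "cells.csv"
    if not cells_path.exists():
        raise DataValidationError(f"no cells.csv under {path}")
    cells = pd.read_csv(cells_path, float_precision="round_trip")
    events = None
    traces = None
    if (path / "events.csv").exists():
        events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    if (path / "traces.csv").exists():
        traces = pd.read_csv(path / "traces.csv", float_precision="round_trip")
    meta = None
    if (path / "meta.yaml").exists():
        with open(path / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
    _validate_tables(cells, events, traces)
    return Dataset(cells=cells, events=events, traces=traces, meta=meta)
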
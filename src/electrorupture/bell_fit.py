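"""Bell/Arrhenius analysis of rupture-tension versus loading-rate data.

Dynamic force spectroscopy applied to membrane rupture: under a (locally)
constant tension loading rate ``R_sigma``, the most probable rupture tension
grows with the logarithm of the rate,

    sigma* = (kB T / A) * ln( R_sigma * A / (kB T * k0) ),

where ``A = pi r^2`` is the pore area at the barrier top and ``k0`` the
zero-tension dissociation rate.  A straight line fitted to characteristic
tensions against ``ln R_sigma`` therefore yields

    slope  s = kB T / A          ->  pore radius r = sqrt(kB T / (pi s))
    intercept b = s * ln(A / (kB T k0))  ->  k0 = (1/s) * exp(-b / s)

with ``R_sigma`` expressed in N m^-1 s^-1 against a reference of
1 N m^-1 s^-1 (the logarithm needs an explicit unit reference; it is recorded
in the result so ``k0`` is reproducible).  The barrier follows from the
attempt frequency: ``W0 / kB T = ln(v0 / k0)`` and the zero-tension lifetime
is ``tau0 = 1 / k0``.

The module also carries the closed-form rupture-tension distribution under a
constant tension rate,

    S(sigma) = exp( -(kB T k0 / (A R_sigma)) * (exp(A sigma / kB T) - 1) ),

which is the independent oracle for the stochastic simulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .electro_model import PhysicalContext
from .exceptions import DataValidationError, ModelFitError, SpontaneousRuptureError
from .rupture_detect import RuptureEvent
from .synthetic_data import SimulationTruth

__all__ = [
    "TensionPoint",
    "BellFitResult",
    "bell_slope",
    "characteristic_value",
    "aggregate_by_rate",
    "fit_bell",
    "most_probable_tension",
    "RuptureTensionDistribution",
    "rupture_tension_distribution",
    "RecoveryReport",
    "recover_parameters",
]

_EULER_GAMMA = 0.5772156649015329

Estimator = Literal["mean", "mode", "gumbel-corrected-mean"]
#: converts a characteristic rupture voltage and its loading rate into
#: (tension, tension rate); built from the electrical chain
TensionConverter = Callable[[float, float], tuple[float, float]]


@dataclass
class TensionPoint:
    """Per-loading-rate aggregate entering the Bell line."""

    loading_rate_vpp_per_s: float
    char_voltage_vpp: float
    sigma_e_n_per_m: float
    r_sigma_n_per_m_s: float
    n: int
    voltage_sd_vpp: float
    voltage_se_vpp: float
    sigma_se_n_per_m: float
    n_censored: int = 0


@dataclass
class BellFitResult:
    """Line fit and the derived pore energetics."""

    slope_n_per_m: float
    intercept_n_per_m: float
    slope_se: float
    intercept_se: float
    r_squared: float
    pore_area_m2: float
    pore_radius_m: float
    pore_radius_se_m: float
    k0_per_s: float
    log_k0_se: float
    tau0_s: float
    w0_joule: float
    w0_kbt: float
    w0_kbt_se: float
    n_points: int
    conventions: dict = field(default_factory=dict)

    @property
    def pore_radius_nm(self) -> float:
        return self.pore_radius_m * 1e9

    def to_dict(self) -> dict:
        return {
            "slope_n_per_m": self.slope_n_per_m,
            "intercept_n_per_m": self.intercept_n_per_m,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "r_squared": self.r_squared,
            "pore_area_m2": self.pore_area_m2,
            "pore_radius_nm": self.pore_radius_nm,
            "pore_radius_se_nm": self.pore_radius_se_m * 1e9,
            "k0_per_s": self.k0_per_s,
            "log_k0_se": self.log_k0_se,
            "tau0_s": self.tau0_s,
            "w0_joule": self.w0_joule,
            "w0_kbt": self.w0_kbt,
            "w0_kbt_se": self.w0_kbt_se,
            "n_points": self.n_points,
            "conventions": self.conventions,
        }


def bell_slope(pore_radius_m: float, physics: PhysicalContext = PhysicalContext()) -> float:
    """Bell-line slope kB·T / (pi r²) in N/m implied by a pore radius."""
    if pore_radius_m <= 0:
        raise ValueError("pore_radius_m must be positive")
    return physics.kT / (math.pi * pore_radius_m**2)


def characteristic_value(x: np.ndarray, estimator: Estimator = "mean") -> float:
    """Location statistic of a rupture-voltage (or -tension) sample.

    ``mean`` averages; ``mode`` takes the argmax of a Gaussian KDE;
    ``gumbel-corrected-mean`` adds the mean-vs-mode offset of a reversed
    Gumbel distribution (gamma * sd * sqrt(6)/pi), appropriate because
    first-passage ruptures under an exponentially growing hazard are
    asymptotically reversed-Gumbel (left-skewed): the sample mean sits that
    far below the mode that the Bell relation describes.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if estimator == "mean":
        return float(x.mean())
    if estimator == "gumbel-corrected-mean":
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        return float(x.mean() + _EULER_GAMMA * sd * math.sqrt(6.0) / math.pi)
    if estimator == "mode":
        if x.size < 5 or np.ptp(x) == 0:
            return float(np.median(x))
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 2048)
        dens = kde(grid)
        i = int(np.argmax(dens))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda v: -kde(v)[0], bounds=(lo, hi), method="bounded")
        return float(res.x)
    raise ValueError(f"unknown estimator {estimator!r}")


def aggregate_by_rate(
    events: Sequence[RuptureEvent],
    tension_converter: TensionConverter,
    estimator: Estimator = "mean",
) -> list[TensionPoint]:
    """Collapse events into one tension point per loading rate.

    Censored events are excluded from the location statistic but counted;
    rates with fewer than two non-censored events are dropped with a warning.
    The characteristic voltage is converted to (sigma_e, R_sigma_e) through
    the supplied electrical-chain converter.
    """
    groups: dict[float, list[RuptureEvent]] = {}
    for ev in events:
        if not math.isfinite(ev.loading_rate_vpp_per_s):
            raise DataValidationError(
                f"event {ev.cell_id} carries no loading rate; cannot aggregate"
            )
        groups.setdefault(ev.loading_rate_vpp_per_s, []).append(ev)

    points: list[TensionPoint] = []
    for rate in sorted(groups):
        evs = groups[rate]
        volts = np.array(
            [e.rupture_voltage_vpp for e in evs if not e.censored], dtype=float
        )
        n_cens = sum(e.censored for e in evs)
        if volts.size < 2:
            warnings.warn(
                f"loading rate {rate} has {volts.size} non-censored events; dropped",
                stacklevel=2,
            )
            continue
        v_char = characteristic_value(volts, estimator)
        sd = float(volts.std(ddof=1))
        se = sd / math.sqrt(volts.size)
        sigma, r_sigma = tension_converter(v_char, rate)
        # delta method through sigma ∝ V²: d sigma / dV = 2 sigma / V
        sigma_se = 2.0 * sigma / v_char * se if v_char > 0 else math.nan
        points.append(
            TensionPoint(
                loading_rate_vpp_per_s=rate,
                char_voltage_vpp=v_char,
                sigma_e_n_per_m=sigma,
                r_sigma_n_per_m_s=r_sigma,
                n=int(volts.size),
                voltage_sd_vpp=sd,
                voltage_se_vpp=se,
                sigma_se_n_per_m=sigma_se,
                n_censored=int(n_cens),
            )
        )
    if not points:
        raise DataValidationError("all loading rates were dropped; nothing to fit")
    return points


def fit_bell(
    points: Sequence[TensionPoint],
    physics: PhysicalContext = PhysicalContext(),
    weighting: Literal["none", "by-se"] = "none",
    conventions: dict | None = None,
) -> BellFitResult:
    """Least-squares Bell line sigma_e = s·ln(R_sigma_e) + b and derived energetics.

    Requires at least three points with distinct tension rates.  A
    non-positive fitted slope means the data contradict the model (the implied
    pore area would be negative) and raises :class:`ModelFitError` rather than
    returning a complex radius.  Standard errors for the derived quantities
    follow from the parameter covariance by the delta method.
    """
    if len(points) < 3:
        raise DataValidationError("fit_bell needs >= 3 tension points")
    x = np.array([p.r_sigma_n_per_m_s for p in points], dtype=float)
    y = np.array([p.sigma_e_n_per_m for p in points], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise DataValidationError("tension points must have positive sigma and rate")
    if np.unique(x).size < 3:
        raise DataValidationError("fit_bell needs >= 3 distinct tension rates")
    lx = np.log(x)  # R_sigma in N m^-1 s^-1 against a 1 N m^-1 s^-1 reference
    X = sm.add_constant(lx)
    if weighting == "by-se":
        se = np.array([p.sigma_se_n_per_m for p in points], dtype=float)
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise DataValidationError("by-se weighting requires finite positive SEs")
        model = sm.WLS(y, X, weights=1.0 / se**2)
    elif weighting == "none":
        model = sm.OLS(y, X)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    res = model.fit()
    b, s = float(res.params[0]), float(res.params[1])
    if s <= 0:
        raise ModelFitError(
            f"fitted slope {s:.3g} N/m is non-positive: data are inconsistent "
            "with the Bell model (no real pore radius)"
        )
    cov = np.asarray(res.cov_params())
    se_b, se_s = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    kT = physics.kT
    area = kT / s
    radius = math.sqrt(area / math.pi)
    se_area = kT / s**2 * se_s
    se_radius = se_area / (2.0 * math.pi * radius)
    # ln k0 = -ln s - b/s; gradient wrt (b, s)
    g = np.array([-1.0 / s, -1.0 / s + b / s**2])
    var_log_k0 = float(g @ cov @ g)
    log_k0 = -math.log(s) - b / s
    k0 = math.exp(log_k0)
    w0_kbt = math.log(physics.attempt_frequency_hz) - log_k0
    return BellFitResult(
        slope_n_per_m=s,
        intercept_n_per_m=b,
        slope_se=se_s,
        intercept_se=se_b,
        r_squared=float(res.rsquared),
        pore_area_m2=area,
        pore_radius_m=radius,
        pore_radius_se_m=se_radius,
        k0_per_s=k0,
        log_k0_se=math.sqrt(max(var_log_k0, 0.0)),
        tau0_s=1.0 / k0,
        w0_joule=kT * w0_kbt,
        w0_kbt=w0_kbt,
        w0_kbt_se=math.sqrt(max(var_log_k0, 0.0)),
        n_points=len(points),
        conventions={
            "rate_reference_n_per_m_s": 1.0,
            "temperature_K": physics.temperature_K,
            "attempt_frequency_hz": physics.attempt_frequency_hz,
            "weighting": weighting,
            **(conventions or {}),
        },
    )


def most_probable_tension(
    pore_area_m2: float,
    k0_per_s: float,
    r_sigma_n_per_m_s: float,
    physics: PhysicalContext = PhysicalContext(),
) -> float:
    """Most probable rupture tension under a constant tension loading rate.

    ``sigma* = (kB T / A) ln( R_sigma A / (kB T k0) )``; requires the
    logarithm argument to exceed 1, otherwise the density mode sits at zero
    tension (spontaneous-rupture regime) and the statistic is undefined.
    """
    if pore_area_m2 <= 0 or k0_per_s <= 0 or r_sigma_n_per_m_s <= 0:
        raise ValueError("pore area, k0, and tension rate must be positive")
    kT = physics.kT
    arg = r_sigma_n_per_m_s * pore_area_m2 / (kT * k0_per_s)
    if arg <= 1.0:
        raise SpontaneousRuptureError(
            f"loading too slow for a tension mode: R_sigma A / (kB T k0) = {arg:.3g} <= 1"
        )
    return kT / pore_area_m2 * math.log(arg)


@dataclass(frozen=True)
class RuptureTensionDistribution:
    """Closed-form rupture-tension law under a constant tension rate.

    With ``a = A / kB T`` and ``c = k0 / (a R_sigma)``:
    ``S(sigma) = exp(-c (e^{a sigma} - 1))`` and the density is
    ``f(sigma) = (k0 / R_sigma) e^{a sigma} S(sigma)``.
    """

    pore_area_m2: float
    k0_per_s: float
    r_sigma_n_per_m_s: float
    physics: PhysicalContext = PhysicalContext()

    def __post_init__(self) -> None:
        if (
            self.pore_area_m2 <= 0
            or self.k0_per_s <= 0
            or self.r_sigma_n_per_m_s <= 0
        ):
            raise ValueError("all distribution parameters must be positive")

    @property
    def _a(self) -> float:
        return self.pore_area_m2 / self.physics.kT

    @property
    def _c(self) -> float:
        return self.k0_per_s / (self._a * self.r_sigma_n_per_m_s)

    def survival(self, sigma) -> np.ndarray | float:
        sig = np.asarray(sigma, dtype=float)
        out = np.exp(-self._c * np.expm1(self._a * sig))
        return out if out.ndim else float(out)

    def cdf(self, sigma) -> np.ndarray | float:
        out = 1.0 - np.asarray(self.survival(sigma))
        return out if out.ndim else float(out)

    def pdf(self, sigma) -> np.ndarray | float:
        sig = np.asarray(sigma, dtype=float)
        out = (
            self.k0_per_s
            / self.r_sigma_n_per_m_s
            * np.exp(self._a * sig)
            * np.exp(-self._c * np.expm1(self._a * sig))
        )
        return out if out.ndim else float(out)

    @property
    def mode(self) -> float:
        return most_probable_tension(
            self.pore_area_m2, self.k0_per_s, self.r_sigma_n_per_m_s, self.physics
        )


def rupture_tension_distribution(
    pore_area_m2: float,
    k0_per_s: float,
    r_sigma_n_per_m_s: float,
    physics: PhysicalContext = PhysicalContext(),
) -> RuptureTensionDistribution:
    """Factory for :class:`RuptureTensionDistribution`."""
    return RuptureTensionDistribution(pore_area_m2, k0_per_s, r_sigma_n_per_m_s, physics)


@dataclass
class RecoveryReport:
    """Comparison of a fit against the generating simulation truth."""

    fit: BellFitResult
    truth: SimulationTruth
    rel_err_radius: float
    rel_err_k0: float
    abs_err_w0_kbt: float
    ci_radius_nm: tuple[float, float]
    ci_w0_kbt: tuple[float, float]
    n_bootstrap: int


def recover_parameters(
    events: Sequence[RuptureEvent],
    tension_converter: TensionConverter,
    truth: SimulationTruth,
    estimator: Estimator = "mean",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> RecoveryReport:
    """Fit the Bell line to events and report errors against the truth.

    Bootstrap resamples cells within each loading rate (percentile CIs on the
    pore radius and the barrier).
    """
    physics = truth.physics()
    points = aggregate_by_rate(events, tension_converter, estimator)
    fit = fit_bell(points, physics)

    rng = np.random.default_rng(seed)
    volts_by_rate = {}
    for ev in events:
        if not ev.censored:
            volts_by_rate.setdefault(ev.loading_rate_vpp_per_s, []).append(
                ev.rupture_voltage_vpp
            )
    volts_by_rate = {k: np.asarray(v) for k, v in volts_by_rate.items()}
    radii = np.empty(n_bootstrap)
    w0s = np.empty(n_bootstrap)
    kT = physics.kT
    for i in range(n_bootstrap):
        xs, ys = [], []
        for rate, volts in sorted(volts_by_rate.items()):
            res = volts[rng.integers(0, volts.size, size=volts.size)]
            v_char = characteristic_value(res, estimator)
            sigma, r_sigma = tension_converter(v_char, rate)
            xs.append(math.log(r_sigma))
            ys.append(sigma)
        s_i, b_i = np.polyfit(xs, ys, 1)
        if s_i <= 0:
            radii[i] = np.nan
            w0s[i] = np.nan
            continue
        radii[i] = math.sqrt(kT / s_i / math.pi)
        log_k0 = -math.log(s_i) - b_i / s_i
        w0s[i] = math.log(physics.attempt_frequency_hz) - log_k0
    ci_r = tuple(np.nanpercentile(radii, [2.5, 97.5]) * 1e9)
    ci_w = tuple(np.nanpercentile(w0s, [2.5, 97.5]))
    return RecoveryReport(
        fit=fit,
        truth=truth,
        rel_err_radius=fit.pore_radius_m / truth.pore_radius_m - 1.0,
        rel_err_k0=fit.k0_per_s / truth.k0_per_s - 1.0,
        abs_err_w0_kbt=fit.w0_kbt - truth.w0_kbt,
        ci_radius_nm=ci_r,
        ci_w0_kbt=ci_w,
        n_bootstrap=n_bootstrap,
    )
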
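"""Passive electrical response of a spherical cell in a ramped AC field.

The chain implemented here converts an applied peak-to-peak voltage into a
membrane electrical tension, the mechanical load that drives pore formation:

1. The dielectrophoretic crossover frequency encodes the area-specific
   membrane capacitance through the single-shell result
   ``C_mem = sqrt(2) * sigma_med / (2 pi r f_co)``.
2. The applied voltage maps to the local field at the membrane pole,
   ``E = g * (V_pp / 2) / d``, with ``g`` a dimensionless geometry factor
   standing in for the interdigitated-electrode field distribution and ``d``
   the electrode gap.
3. The field induces a transmembrane potential with first-order (Schwan-type)
   frequency attenuation:
   ``|U_tmp| = 1.5 E r |cos θ| / sqrt(1 + (2 pi f r C_mem (x_cyt + x_med/2))^2)``.
4. The transmembrane potential stores capacitive energy that acts as a lateral
   membrane tension, ``sigma = 0.5 * C_LW * U_tmp^2``, where
   ``C_LW = C_mem * (((eps_med + eps_cyto)/2) / eps_mem - 1)`` is the change in
   specific capacitance when water displaces lipid in a pore.

Because the chain is linear up to the final square, ``sigma`` is exactly
quadratic in the applied voltage, and the instantaneous tension loading rate
under a linear voltage ramp is ``R_sigma = (2 sigma / V) * R_V``.

All quantities are SI unless a name says otherwise; applied voltages are
peak-to-peak (``V_pp``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "MediumProperties",
    "CellElectricalModel",
    "FieldModel",
    "RampProtocol",
    "PhysicalContext",
    "Conventions",
    "membrane_capacitance",
    "field_strength",
    "transmembrane_potential",
    "water_lipid_capacitance",
    "electrical_tension",
    "tension_at",
    "tension_and_rate_at",
]

#: CODATA value of the Boltzmann constant, J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

ArrayLike = Union[float, np.ndarray]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class MediumProperties:
    """Suspension-medium electrical properties.

    Defaults correspond to a low-conductivity dielectrophoresis buffer
    (60 µS/cm, i.e. 6.0e-3 S/m) with water-like permittivity.
    """

    conductivity_S_per_m: float = 6.0e-3
    eps_rel: float = 80.0

    def __post_init__(self) -> None:
        _require_positive(
            conductivity_S_per_m=self.conductivity_S_per_m, eps_rel=self.eps_rel
        )

    @property
    def resistivity_ohm_m(self) -> float:
        """Medium resistivity, the reciprocal of its conductivity."""
        return 1.0 / self.conductivity_S_per_m


@dataclass(frozen=True)
class CellElectricalModel:
    """Per-cell passive electrical description.

    Parameters
    ----------
    radius_m : cell radius (m).
    crossover_hz : DEP crossover frequency (Hz); encodes membrane capacitance.
    rho_cyt_ohm_m : cytoplasm resistivity (Ω·m); default 2.0 (conductivity 0.5 S/m).
    eps_cyto, eps_mem : relative permittivities of cytoplasm and membrane.
    """

    radius_m: float
    crossover_hz: float
    rho_cyt_ohm_m: float = 2.0
    eps_cyto: float = 80.0
    eps_mem: float = 5.0
    cell_id: str = ""
    condition: str = "untreated"

    def __post_init__(self) -> None:
        _require_positive(
            radius_m=self.radius_m,
            crossover_hz=self.crossover_hz,
            rho_cyt_ohm_m=self.rho_cyt_ohm_m,
            eps_cyto=self.eps_cyto,
            eps_mem=self.eps_mem,
        )

    def membrane_capacitance(
        self, medium: MediumProperties, prefactor: str = "sqrt2"
    ) -> float:
        """Area-specific membrane capacitance (F/m²) from the crossover frequency."""
        return membrane_capacitance(
            medium, self.radius_m, self.crossover_hz, prefactor=prefactor
        )


@dataclass(frozen=True)
class FieldModel:
    """Parametric map from applied voltage to the local field at the membrane.

    ``gap_m`` is the electrode gap of the interdigitated array (10 µm default);
    ``geometry_factor`` absorbs the non-uniform field distribution into a single
    dimensionless factor; ``cos_theta`` selects the membrane position relative
    to the field (1 at the pole, where the transmembrane potential is maximal).
    """

    gap_m: float = 10e-6
    geometry_factor: float = 0.3
    cos_theta: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(gap_m=self.gap_m, geometry_factor=self.geometry_factor)
        if not abs(self.cos_theta) <= 1:
            raise ValueError(f"cos_theta must lie in [-1, 1], got {self.cos_theta}")


@dataclass(frozen=True)
class RampProtocol:
    """Linearly ramped AC voltage protocol.

    The ramp runs from ``v_start_vpp`` to ``v_end_vpp`` at ``rate_vpp_per_s``
    while the AC carrier stays at ``frequency_hz``; its duration is derived
    from range and rate.
    """

    rate_vpp_per_s: float = 0.05
    v_start_vpp: float = 2.0
    v_end_vpp: float = 10.0
    frequency_hz: float = 41e3
    frame_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        _require_positive(
            rate_vpp_per_s=self.rate_vpp_per_s,
            frequency_hz=self.frequency_hz,
            frame_rate_hz=self.frame_rate_hz,
        )
        if not self.v_end_vpp > self.v_start_vpp:
            raise ValueError("v_end_vpp must exceed v_start_vpp")

    @property
    def duration_s(self) -> float:
        return (self.v_end_vpp - self.v_start_vpp) / self.rate_vpp_per_s

    def voltage_at(self, t: ArrayLike) -> ArrayLike:
        """Applied peak-to-peak voltage at time ``t`` (s) since ramp start."""
        return self.v_start_vpp + self.rate_vpp_per_s * np.asarray(t, dtype=float)

    def time_of_voltage(self, v_pp: ArrayLike) -> ArrayLike:
        """Time since ramp start at which the ramp reaches ``v_pp``."""
        return (np.asarray(v_pp, dtype=float) - self.v_start_vpp) / self.rate_vpp_per_s

    def with_rate(self, rate_vpp_per_s: float) -> "RampProtocol":
        return replace(self, rate_vpp_per_s=rate_vpp_per_s)


@dataclass(frozen=True)
class PhysicalContext:
    """Temperature and attempt frequency entering the Arrhenius/Bell kinetics."""

    temperature_K: float = 298.15
    attempt_frequency_hz: float = 1e13
    boltzmann_J_per_K: float = BOLTZMANN_J_PER_K

    def __post_init__(self) -> None:
        _require_positive(
            temperature_K=self.temperature_K,
            attempt_frequency_hz=self.attempt_frequency_hz,
        )

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in joules."""
        return self.boltzmann_J_per_K * self.temperature_K


_CROSSOVER_PREFACTORS = {"sqrt2": np.sqrt(2.0), "2": 2.0}
_VOLTAGE_CONVENTIONS = ("amplitude", "rms")
_RATE_CONVENTIONS = ("instantaneous", "secant")


@dataclass(frozen=True)
class Conventions:
    """Switchable conventions that affect absolute tension values.

    crossover_prefactor : "sqrt2" (single-shell literature value, default) or
        "2" (literal reading of the capacitance formula).
    voltage : "amplitude" (E from V_pp/2, default) or "rms" (V_pp/(2·sqrt(2))).
    rate : "instantaneous" (local tension rate dσ/dt at the characteristic
        voltage, default) or "secant" (σ divided by time since ramp start).
    """

    crossover_prefactor: str = "sqrt2"
    voltage: str = "amplitude"
    rate: str = "instantaneous"

    def __post_init__(self) -> None:
        if self.crossover_prefactor not in _CROSSOVER_PREFACTORS:
            raise ValueError(
                f"crossover_prefactor must be one of {sorted(_CROSSOVER_PREFACTORS)}"
            )
        if self.voltage not in _VOLTAGE_CONVENTIONS:
            raise ValueError(f"voltage convention must be one of {_VOLTAGE_CONVENTIONS}")
        if self.rate not in _RATE_CONVENTIONS:
            raise ValueError(f"rate convention must be one of {_RATE_CONVENTIONS}")

    def to_dict(self) -> dict:
        return {
            "crossover_prefactor": self.crossover_prefactor,
            "voltage": self.voltage,
            "rate": self.rate,
        }


def membrane_capacitance(
    medium: MediumProperties,
    radius_m: float,
    crossover_hz: float,
    prefactor: str = "sqrt2",
) -> float:
    """Area-specific membrane capacitance (F/m²) from the DEP crossover frequency.

    ``C_mem = c * sigma_med / (2 pi r f_co)`` with ``c = sqrt(2)`` under the
    standard single-shell convention (``prefactor="sqrt2"``) or ``c = 2``.
    """
    _require_positive(radius_m=radius_m, crossover_hz=crossover_hz)
    c = _CROSSOVER_PREFACTORS[prefactor]
    return c * medium.conductivity_S_per_m / (2.0 * np.pi * radius_m * crossover_hz)


def field_strength(
    v_pp: ArrayLike, field_model: FieldModel, convention: str = "amplitude"
) -> ArrayLike:
    """Local field magnitude (V/m) at the membrane for an applied V_pp.

    Amplitude convention uses the voltage amplitude V_pp/2; the rms option
    divides by a further sqrt(2).
    """
    v = np.asarray(v_pp, dtype=float)
    if np.any(v < 0):
        raise ValueError("v_pp must be non-negative")
    amplitude = v / 2.0
    if convention == "rms":
        amplitude = amplitude / np.sqrt(2.0)
    elif convention != "amplitude":
        raise ValueError(f"unknown voltage convention {convention!r}")
    out = field_model.geometry_factor * amplitude / field_model.gap_m
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def transmembrane_potential(
    e_field: ArrayLike,
    cell: CellElectricalModel,
    medium: MediumProperties,
    frequency_hz: float,
    cos_theta: float = 1.0,
    c_mem: float | None = None,
    prefactor: str = "sqrt2",
) -> ArrayLike:
    """Magnitude of the induced transmembrane potential (V).

    First-order membrane-charging attenuation: the relaxation term
    ``Theta = 2 pi f r C_mem (x_cyt + x_med / 2)`` is dimensionless, and
    ``|U_tmp| = 1.5 E r |cos θ| / sqrt(1 + Theta²)``.
    """
    _require_positive(frequency_hz=frequency_hz)
    if not abs(cos_theta) <= 1:
        raise ValueError("cos_theta must lie in [-1, 1]")
    if c_mem is None:
        c_mem = cell.membrane_capacitance(medium, prefactor=prefactor)
    theta = (
        2.0
        * np.pi
        * frequency_hz
        * cell.radius_m
        * c_mem
        * (cell.rho_cyt_ohm_m + medium.resistivity_ohm_m / 2.0)
    )
    e = np.asarray(e_field, dtype=float)
    out = 1.5 * e * cell.radius_m * abs(cos_theta) / np.sqrt(1.0 + theta**2)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def water_lipid_capacitance(
    cell: CellElectricalModel,
    medium: MediumProperties,
    c_mem: float | None = None,
    prefactor: str = "sqrt2",
) -> float:
    """Change of specific capacitance (F/m²) as water displaces lipid in a pore.

    ``C_LW = C_mem * (((eps_med + eps_cyto)/2) / eps_mem - 1)``.  The model is
    only physical while the water/cytoplasm average permittivity exceeds the
    membrane permittivity; otherwise the stored capacitive energy could not
    favour pore formation and the input is rejected.
    """
    if c_mem is None:
        c_mem = cell.membrane_capacitance(medium, prefactor=prefactor)
    eps_avg = (medium.eps_rel + cell.eps_cyto) / 2.0
    if cell.eps_mem >= eps_avg:
        raise ValueError(
            "eps_mem must be below the water/cytoplasm average permittivity "
            f"({cell.eps_mem} >= {eps_avg}): C_LW would be non-positive"
        )
    return c_mem * (eps_avg / cell.eps_mem - 1.0)


def electrical_tension(c_lw: float, u_tmp: ArrayLike) -> ArrayLike:
    """Membrane electrical tension (N/m): ``sigma = 0.5 * C_LW * U_tmp²``."""
    _require_positive(c_lw=c_lw)
    u = np.asarray(u_tmp, dtype=float)
    out = 0.5 * c_lw * u**2
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def tension_at(
    v_pp: ArrayLike,
    cell: CellElectricalModel,
    medium: MediumProperties,
    field_model: FieldModel,
    frequency_hz: float,
    conventions: Conventions = Conventions(),
) -> ArrayLike:
    """Electrical tension (N/m) at applied voltage ``v_pp``, composing the chain."""
    c_mem = cell.membrane_capacitance(medium, prefactor=conventions.crossover_prefactor)
    e = field_strength(v_pp, field_model, convention=conventions.voltage)
    u = transmembrane_potential(
        e,
        cell,
        medium,
        frequency_hz,
        cos_theta=field_model.cos_theta,
        c_mem=c_mem,
    )
    c_lw = water_lipid_capacitance(cell, medium, c_mem=c_mem)
    return electrical_tension(c_lw, u)


def tension_and_rate_at(
    v_pp: float,
    rate_vpp_per_s: float,
    cell: CellElectricalModel,
    medium: MediumProperties,
    field_model: FieldModel,
    frequency_hz: float,
    conventions: Conventions = Conventions(),
    v_start_vpp: float = 2.0,
) -> tuple[float, float]:
    """Electrical tension and its loading rate at voltage ``v_pp``.

    The chain is linear up to the final square, so ``sigma ∝ V²`` and the
    instantaneous rate is available in closed form,
    ``R_sigma = dσ/dV · R_V = (2 σ / V) · R_V``.  The secant convention
    divides the tension by the time elapsed since the ramp start instead.
    """
    if rate_vpp_per_s < 0:
        raise ValueError("rate_vpp_per_s must be non-negative")
    sigma = float(tension_at(v_pp, cell, medium, field_model, frequency_hz, conventions))
    if conventions.rate == "instantaneous":
        if v_pp <= 0:
            raise ValueError("instantaneous rate undefined at V = 0")
        r_sigma = 2.0 * sigma / v_pp * rate_vpp_per_s
    else:  # secant
        if v_pp <= v_start_vpp:
            raise ValueError("secant rate undefined at or before the ramp start")
        elapsed = (v_pp - v_start_vpp) / rate_vpp_per_s if rate_vpp_per_s > 0 else np.inf
        r_sigma = sigma / elapsed if np.isfinite(elapsed) else 0.0
    if rate_vpp_per_s == 0:
        r_sigma = 0.0
    return sigma, r_sigma
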
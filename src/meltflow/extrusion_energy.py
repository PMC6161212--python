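"""Extrusion energy: specific mechanical energy and a 1D dissipation model.

Specific mechanical energy (SME) from twin-screw telemetry:

    SME = 2π · n · (τ − τ_idle) / (60 · ṁ)

with screw speed n in rpm, net torque per shaft τ in N·m and feed rate
ṁ in kg/h; the result in W/(kg/h) ≡ W·h/kg is reported as kWh/t (the two
are numerically identical).

`simulate_energy_1d` is an intentionally simple one-dimensional
viscous-dissipation DEMONSTRATOR, not a substitute for a commercial
extrusion solver. It assumes fully filled channels, melt at barrel
temperature, no pressure/die coupling and no melting enthalpy. Per
screw element the mean channel shear rate is γ̇ = πDN/h (D screw
diameter, N rev/s, h channel depth), the dissipated power is
η(γ̇, T)·γ̇²·V with the channel volume V ≈ πDhL, and the barrel supplies
by conduction whatever part of the feed's heating duty
ṁ·cp·(T_barrel − T_feed) dissipation does not cover (capped by a
film-conduction limit k/h·A·ΔT). Melting energy is deliberately zero:
where a softening input is demanded the blend's glass transition
temperature stands in. Every simplification is echoed in the returned
report so the numbers cannot be mistaken for a full solver's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .rheology import FlowCurveFit, WLFParams, eval_viscosity_at

__all__ = [
    "ExtrusionRun",
    "ScrewElement",
    "EnergyBreakdown",
    "compute_sme",
    "simulate_energy_1d",
    "default_screw_configuration",
    "read_runs_csv",
    "read_screw_csv",
]

#: idle (no-load) torque of the 12 mm lab extruder, N·m
DEFAULT_IDLE_TORQUE = 1.2


@dataclass(frozen=True)
class ExtrusionRun:
    """One extrusion operating point from the run log."""

    screw_speed: float  # rpm
    feed_rate: float  # kg/h
    torque: float  # N·m per shaft, as measured
    idle_torque: float = DEFAULT_IDLE_TORQUE

    def __post_init__(self) -> None:
        if self.screw_speed < 0 or self.torque < 0 or self.idle_torque < 0:
            raise ValueError("screw speed and torques must be non-negative")
        if not self.feed_rate > 0:
            raise ValueError(f"feed_rate must be > 0 kg/h, got {self.feed_rate}")


@dataclass(frozen=True)
class ScrewElement:
    """One screw element: conveying (pitch in mm) or kneading (stagger in °)."""

    kind: str  # "conveying" | "kneading"
    length: float  # mm
    pitch_or_stagger: float  # mm (conveying) or degrees (kneading)
    channel_depth: float = 2.4  # mm; default 0.2·D for a 12 mm screw

    def __post_init__(self) -> None:
        if self.kind not in ("conveying", "kneading"):
            raise ValueError(f"kind must be 'conveying' or 'kneading', got {self.kind!r}")
        if not (self.length > 0 and self.pitch_or_stagger > 0):
            raise ValueError("element dimensions must be positive")
        if not self.channel_depth > 0:
            raise ValueError("channel depth must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy per tonne of extrudate; ``sme = dissipated + conduction``."""

    sme: float
    dissipated: float
    conduction: float
    assumptions: tuple[str, ...] = ()


_DEMONSTRATOR_ASSUMPTIONS = (
    "simplified 1D energy balance (demonstrator, not a commercial solver)",
    "fully filled channels; no pressure or die back-flow coupling",
    "melt isothermal at barrel temperature",
    "melting energy zero; glass transition stands in for a softening point",
    "mean channel shear rate pi*D*N/h per element",
)


def compute_sme(run: ExtrusionRun) -> float:
    """Specific mechanical energy (kWh/t) of one run.

    Net torque below zero (measured torque under the idle value) clamps
    to zero with a warning rather than producing a negative energy.
    """
    net = run.torque - run.idle_torque
    if net < 0:
        warnings.warn(
            f"measured torque {run.torque} N·m is below the idle torque "
            f"{run.idle_torque} N·m; clamping net torque to zero",
            stacklevel=2,
        )
        net = 0.0
    power_w = 2.0 * math.pi * run.screw_speed * net / 60.0
    return power_w / run.feed_rate  # W per (kg/h) == W·h/kg == kWh/t


def default_screw_configuration() -> list[ScrewElement]:
    """25:1 L/D layout for a 12 mm screw: conveying runs with three kneading blocks."""
    return [
        ScrewElement("conveying", 90.0, 18.0),
        ScrewElement("kneading", 30.0, 30.0),
        ScrewElement("conveying", 60.0, 12.0),
        ScrewElement("kneading", 30.0, 60.0),
        ScrewElement("conveying", 36.0, 12.0),
        ScrewElement("kneading", 24.0, 90.0),
        ScrewElement("conveying", 30.0, 9.0),
    ]


def simulate_energy_1d(
    screw: Sequence[ScrewElement],
    flow: FlowCurveFit,
    wlf: WLFParams,
    run: ExtrusionRun,
    barrel_temp: float,
    material: dict,
    screw_diameter_mm: float = 12.0,
    feed_temp: float = 25.0,
) -> EnergyBreakdown:
    """Lumped 1D viscous-dissipation energy balance (demonstrator).

    ``material`` must carry ``cp`` in J/(g·K); ``density`` (kg/m³) and
    ``thermal_conductivity`` (W/(m·K), default 0.18) are used for the
    conduction cap. Returns energies in kWh/t with the assumption list
    attached.
    """
    if not screw:
        raise ValueError("screw configuration must contain at least one element")
    cp = float(material["cp"])  # J/(g·K) == kJ/(kg·K)
    k_therm = float(material.get("thermal_conductivity", 0.18))
    d_m = screw_diameter_mm / 1000.0
    n_rev_s = run.screw_speed / 60.0
    m_dot_kg_s = run.feed_rate / 3600.0

    dissipated_w = 0.0
    area_m2 = 0.0
    for el in screw:
        h_m = el.channel_depth / 1000.0
        l_m = el.length / 1000.0
        gamma_dot = math.pi * d_m * n_rev_s / h_m
        eta = eval_viscosity_at(flow, wlf, gamma_dot, barrel_temp)
        volume = math.pi * d_m * h_m * l_m
        dissipated_w += eta * gamma_dot**2 * volume
        area_m2 += math.pi * d_m * l_m

    dt = max(barrel_temp - feed_temp, 0.0)
    heating_duty_w = m_dot_kg_s * cp * 1000.0 * dt
    h_mean = sum(el.channel_depth for el in screw) / len(screw) / 1000.0
    conduction_cap_w = (k_therm / h_mean) * area_m2 * dt
    conduction_w = min(max(heating_duty_w - dissipated_w, 0.0), conduction_cap_w)

    # W / (kg/h) == W·h/kg == kWh/t
    dissipated = dissipated_w / run.feed_rate
    conduction = conduction_w / run.feed_rate
    return EnergyBreakdown(
        sme=dissipated + conduction,
        dissipated=dissipated,
        conduction=conduction,
        assumptions=_DEMONSTRATOR_ASSUMPTIONS,
    )


def read_runs_csv(path: str | Path) -> list[ExtrusionRun]:
    """Read extrusion run logs (screw_speed_rpm, feed_rate_kg_h, torque_Nm[, idle_torque_Nm])."""
    df = pd.read_csv(path)
    required = {"screw_speed_rpm", "feed_rate_kg_h", "torque_Nm"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    runs = []
    for _, row in df.iterrows():
        idle = row.get("idle_torque_Nm")
        runs.append(
            ExtrusionRun(
                screw_speed=float(row["screw_speed_rpm"]),
                feed_rate=float(row["feed_rate_kg_h"]),
                torque=float(row["torque_Nm"]),
                idle_torque=float(idle) if idle is not None and pd.notna(idle)
                else DEFAULT_IDLE_TORQUE,
            )
        )
    return runs


def read_screw_csv(path: str | Path) -> list[ScrewElement]:
    """Read a screw configuration (kind, length_mm, pitch_or_stagger[, channel_depth_mm])."""
    df = pd.read_csv(path)
    required = {"kind", "length_mm", "pitch_or_stagger"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        depth = row.get("channel_depth_mm")
        out.append(
            ScrewElement(
                kind=str(row["kind"]).strip(),
                length=float(row["length_mm"]),
                pitch_or_stagger=float(row["pitch_or_stagger"]),
                channel_depth=float(depth) if depth is not None and pd.notna(depth) else 2.4,
            )
        )
    return out
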
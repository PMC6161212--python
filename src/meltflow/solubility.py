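"""Drug-in-polymer solubility phase diagrams from annealing calorimetry.

The phase boundary is probed indirectly: a supersaturated blend is held
(annealed) well above its predicted Tg so that the dissolved drug
fraction equilibrates, and the Tg measured immediately afterwards
reflects the composition of the amorphous phase. Inverting the blend's
Tg-vs-composition curve (the BCKV polynomial) therefore converts each
annealed-sample Tg into a soluble drug fraction at the annealing
temperature. The resulting (fraction, temperature) points are fitted to
an exponential boundary

    T_annealing(x) = y0 + A·exp(R0·x),

with y0 initialised at (but not fixed to) the drug's melting point, and
the boundary is extrapolated to ambient temperature (25 °C) to report
the equilibrium solubility. Blends whose boundary never reaches ambient
temperature are reported as insoluble rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import FitError, OutOfRangeError
from .tg_models import BCKVParams, bckv_tg

__all__ = [
    "AnnealingRecord",
    "SolubilityCurve",
    "SolubilityFitResult",
    "InversionResult",
    "SolubilityResult",
    "soluble_fraction_from_tg",
    "phase_boundary_points",
    "fit_solubility_curve",
    "solubility_at",
]


@dataclass(frozen=True)
class AnnealingRecord:
    """One annealing experiment: nominal loading, hold temperature, Tg after."""

    nominal_w_api: float
    t_annealing: float
    tg_annealed: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nominal_w_api <= 1.0:
            raise ValueError("nominal_w_api must be in [0, 1]")
        if not self.t_annealing > self.tg_annealed:
            raise ValueError(
                "annealing must happen above the annealed sample's Tg "
                f"(T_annealing={self.t_annealing}, Tg={self.tg_annealed})"
            )


@dataclass(frozen=True)
class SolubilityCurve:
    """Exponential phase boundary T(x) = y0 + A·exp(R0·x) (temperatures in °C)."""

    y0: float
    A: float
    r0: float

    def temperature_at(self, w_soluble):
        """Boundary (full-dissolution) temperature at drug fraction ``w_soluble``."""
        x = np.asarray(w_soluble, dtype=float)
        t = self.y0 + self.A * np.exp(self.r0 * x)
        return float(t) if np.isscalar(w_soluble) else t


@dataclass(frozen=True)
class SolubilityFitResult:
    curve: SolubilityCurve
    adjusted_r2: float
    r2: float
    stderr: tuple[float, float, float]
    n_points: int


@dataclass(frozen=True)
class InversionResult:
    """Soluble fraction recovered from an annealed-sample Tg."""

    w_soluble: float
    multiple_roots: bool
    roots: tuple[float, ...]


@dataclass(frozen=True)
class SolubilityResult:
    """Soluble fraction at a temperature, with degeneracy flags."""

    w_soluble: float
    insoluble: bool = False
    clipped: bool = False


def soluble_fraction_from_tg(
    tg_annealed: float,
    bckv: BCKVParams,
    nominal_w_api: float | None = None,
    grid: int = 2001,
    tol: float = 1e-9,
) -> InversionResult:
    """Invert the BCKV curve: find w with Tg(w) = ``tg_annealed``.

    The curve is scanned on a regular grid over [0, 1] for sign changes
    and each bracket is polished by Brent's method to ``tol``. BCKV
    curves with strong corrections can be non-monotone; when several
    roots exist the one nearest ``nominal_w_api`` is returned and the
    multiplicity is flagged.
    """
    w = np.linspace(0.0, 1.0, grid)
    f = bckv_tg(bckv, w) - tg_annealed
    roots: list[float] = []
    for i in range(grid - 1):
        if f[i] == 0.0:
            roots.append(float(w[i]))
        elif f[i] * f[i + 1] < 0.0:
            roots.append(float(brentq(
                lambda x: bckv_tg(bckv, x) - tg_annealed, w[i], w[i + 1], xtol=tol
            )))
    if f[-1] == 0.0:
        roots.append(1.0)
    # dedupe roots that met at a grid node
    uniq: list[float] = []
    for r in roots:
        if not uniq or abs(r - uniq[-1]) > 10 * tol:
            uniq.append(r)
    if not uniq:
        raise OutOfRangeError(
            f"Tg = {tg_annealed} °C is not attained by the BCKV curve on [0, 1] "
            f"(range {f.min() + tg_annealed:.2f} to {f.max() + tg_annealed:.2f} °C)"
        )
    if nominal_w_api is None:
        chosen = uniq[0]
    else:
        chosen = min(uniq, key=lambda r: abs(r - nominal_w_api))
    return InversionResult(
        w_soluble=chosen, multiple_roots=len(uniq) > 1, roots=tuple(uniq)
    )


def phase_boundary_points(
    records: Iterable[AnnealingRecord],
    bckv: BCKVParams,
    dissolved_tol: float = 0.02,
) -> list[tuple[float, float]]:
    """Convert annealing records to (soluble fraction, T_annealing) points.

    Records whose recovered fraction equals the nominal loading (within
    ``dissolved_tol``) were fully dissolved at the annealing temperature;
    they only bound the curve from below and are excluded from fitting.
    """
    pts = []
    for rec in records:
        inv = soluble_fraction_from_tg(rec.tg_annealed, bckv, rec.nominal_w_api)
        if inv.w_soluble < rec.nominal_w_api - dissolved_tol:
            pts.append((inv.w_soluble, rec.t_annealing))
    return pts


def fit_solubility_curve(
    points: Sequence[tuple[float, float]],
    y0_init: float | None = None,
) -> SolubilityFitResult:
    """Fit T = y0 + A·exp(R0·x) to (soluble fraction, temperature) points.

    Needs at least 4 points over at least 3 distinct temperatures (three
    parameters). ``y0_init`` seeds the offset — pass the drug's melting
    point when known; otherwise a data-driven start is used.
    """
    pts = [(float(x), float(t)) for x, t in points]
    temps = {round(t, 9) for _, t in pts}
    if len(pts) < 4 or len(temps) < 3:
        raise FitError(
            "fit_solubility_curve needs >= 4 points spanning >= 3 distinct "
            f"temperatures (got {len(pts)} points, {len(temps)} temperatures)"
        )
    x = np.array([p[0] for p in pts])
    t = np.array([p[1] for p in pts])

    def model(x_, y0, A, r0):
        return y0 + A * np.exp(r0 * x_)

    # Data-driven start: decide the branch (A, R0 same sign for a
    # monotone-increasing boundary) from the observed slope.
    slope = np.polyfit(x, t, 1)[0]
    starts = []
    if y0_init is not None:
        starts.append((y0_init, -(y0_init - t.min()), -5.0))
        starts.append((y0_init, y0_init - t.min(), 5.0))
    if slope >= 0:
        starts.append((t.max() + 5.0, -(t.max() - t.min() + 10.0), -5.0))
        starts.append((t.min() - 5.0, 1.0, 5.0))
    else:
        starts.append((t.min() - 5.0, t.max() - t.min() + 10.0, -5.0))
    last_exc: Exception | None = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(model, x, t, p0=p0, maxfev=20000)
            break
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - fallback path
            last_exc = exc
    else:
        raise FitError(f"solubility-curve fit did not converge: {last_exc}")

    resid = t - model(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    n = len(pts)
    dof = n - 4
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
    stderr = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, None)))
    return SolubilityFitResult(
        curve=SolubilityCurve(y0=float(popt[0]), A=float(popt[1]), r0=float(popt[2])),
        adjusted_r2=adj,
        r2=r2,
        stderr=stderr,  # type: ignore[arg-type]
        n_points=n,
    )


def solubility_at(curve: SolubilityCurve, temperature: float) -> SolubilityResult:
    """Soluble drug fraction at ``temperature`` by inverting the boundary.

    x = ln((T − y0)/A)/R0, clipped to [0, 1] with a flag. When
    (T − y0)/A ≤ 0 the boundary has no solution at that temperature:
    the drug is reported insoluble (fraction 0) rather than raising,
    which is the physically meaningful answer at ambient temperature.
    """
    ratio = (temperature - curve.y0) / curve.A
    if ratio <= 0.0:
        return SolubilityResult(w_soluble=0.0, insoluble=True)
    x = math.log(ratio) / curve.r0
    if x <= 0.0:
        return SolubilityResult(w_soluble=0.0, insoluble=True, clipped=x < 0.0)
    if x > 1.0:
        return SolubilityResult(w_soluble=1.0, clipped=True)
    return SolubilityResult(w_soluble=x)
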
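"""Oscillatory-shear rheology: master curves, Carreau–Yasuda and WLF fits.

Small-amplitude oscillatory shear (SAOS) frequency sweeps taken at
several temperatures are merged into a single master curve by
time–temperature superposition (TTS): each sweep is shifted horizontally
on the log-frequency axis by a factor a_T until it superposes with the
curve at the reference temperature. The merged curve is described by a
reduced Carreau–Yasuda (CY) model with no infinite-shear term,

    η(γ̇) = η0 · [1 + (λ·γ̇)^a]^((n−1)/a),

and the temperature dependence of the shift factors by the WLF equation

    log10 a_T = −C1·(T − T0) / (C2 + (T − T0)).

Conventions adopted here:

* Cox–Merz: |η*|(ω) is treated as η(γ̇) with γ̇ ≡ ω, so SAOS-derived fits
  can feed steady-shear process models.
* Horizontal shifting only — no vertical (density) correction; the
  master curve stores (ω·a_T, |η*|) pairs unchanged in viscosity.
* Evaluation at an off-reference temperature applies a_T to the
  relaxation time λ (standard TTS semantics): η(γ̇, T) = η_ref(a_T·γ̇).
* Frequencies given in Hz are converted to rad/s on ingestion (ω = 2πf);
  all internal rates are rad/s ≡ 1/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares, minimize_scalar

from .errors import FitError, OverlapError, SchemaError

__all__ = [
    "FrequencySweep",
    "MasterCurve",
    "FlowCurveFit",
    "WLFParams",
    "CYFitResult",
    "WLFFitResult",
    "read_saos_csv",
    "build_master_curve",
    "fit_carreau_yasuda",
    "fit_wlf",
    "eval_viscosity",
    "eval_viscosity_at",
]


@dataclass(frozen=True)
class FrequencySweep:
    """One isothermal frequency sweep: |η*| versus angular frequency."""

    temperature: float
    omega: np.ndarray
    eta_star: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        eta = np.asarray(self.eta_star, dtype=float)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "eta_star", eta)
        if omega.shape != eta.shape or omega.ndim != 1:
            raise ValueError("omega and eta_star must be 1-D arrays of equal length")
        d = np.diff(omega)
        if omega.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("omega must be strictly monotone")
        if np.any(omega <= 0) or np.any(eta <= 0):
            raise ValueError("omega and eta_star must be positive")


@dataclass(frozen=True)
class MasterCurve:
    """TTS-merged flow curve at a reference temperature.

    ``points`` holds (reduced frequency ω·a_T, |η*|) pairs sorted by
    frequency; ``shift_factors`` maps each sweep temperature to its a_T
    with a_T(t_ref) = 1.
    """

    t_ref: float
    shift_factors: Mapping[float, float]
    omega_reduced: np.ndarray
    eta_star: np.ndarray


@dataclass(frozen=True)
class FlowCurveFit:
    """Reduced Carreau–Yasuda parameter set at a reference temperature."""

    eta0: float
    lam: float
    a: float
    n: float
    t_ref: float

    def __post_init__(self) -> None:
        if not (self.eta0 > 0 and self.lam > 0 and self.a > 0):
            raise ValueError("eta0, lam and a must be positive")
        if not 0.0 < self.n <= 1.0:
            raise ValueError(f"n must lie in (0, 1] for shear-thinning melts, got {self.n}")


@dataclass(frozen=True)
class WLFParams:
    """WLF constants C1, C2 (>0) at reference temperature t0 (°C)."""

    c1: float
    c2: float
    t0: float

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("C1 and C2 must be positive")

    def log_at(self, temperature) -> np.ndarray | float:
        dt = np.asarray(temperature, dtype=float) - self.t0
        val = -self.c1 * dt / (self.c2 + dt)
        return float(val) if np.isscalar(temperature) else val

    def a_t(self, temperature) -> np.ndarray | float:
        return 10.0 ** self.log_at(temperature)


@dataclass(frozen=True)
class CYFitResult:
    fit: FlowCurveFit
    rms_log_residual: float
    # standard errors in the internal basis (ln η0, ln λ, ln a, n)
    stderr: tuple[float, float, float, float]
    dof: int  # residual degrees of freedom; CIs need t-quantiles at this dof
    reduced: bool = False


@dataclass(frozen=True)
class WLFFitResult:
    params: WLFParams
    rms_log_residual: float
    stderr: tuple[float, float]  # on (C1, C2)
    dof: int


def read_saos_csv(path: str | Path) -> list[FrequencySweep]:
    """Read frequency sweeps from a rheometer CSV export.

    Required: ``temperature_C`` plus either ``omega_rad_s`` or
    ``frequency_Hz`` (converted as ω = 2πf), and either
    ``eta_star_Pa_s`` or the moduli pair ``g_prime_Pa`` /
    ``g_double_prime_Pa`` from which |η*| = √(G′² + G″²)/ω is formed.
    Rows are grouped by temperature; each group becomes one sweep sorted
    by descending frequency.
    """
    df = pd.read_csv(path)
    if "temperature_C" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'temperature_C'")
    if "omega_rad_s" in df.columns:
        omega = df["omega_rad_s"].to_numpy(float)
    elif "frequency_Hz" in df.columns:
        omega = 2.0 * np.pi * df["frequency_Hz"].to_numpy(float)
    else:
        raise SchemaError(f"{path}: need 'omega_rad_s' or 'frequency_Hz'")
    if "eta_star_Pa_s" in df.columns:
        eta = df["eta_star_Pa_s"].to_numpy(float)
    elif {"g_prime_Pa", "g_double_prime_Pa"} <= set(df.columns):
        g1 = df["g_prime_Pa"].to_numpy(float)
        g2 = df["g_double_prime_Pa"].to_numpy(float)
        eta = np.sqrt(g1**2 + g2**2) / omega
    else:
        raise SchemaError(
            f"{path}: need 'eta_star_Pa_s' or 'g_prime_Pa' + 'g_double_prime_Pa'"
        )
    sweeps = []
    temps = df["temperature_C"].to_numpy(float)
    for t in sorted(set(temps)):
        sel = temps == t
        order = np.argsort(omega[sel])[::-1]
        sweeps.append(
            FrequencySweep(temperature=float(t), omega=omega[sel][order],
                           eta_star=eta[sel][order])
        )
    return sweeps


def _shift_one(
    log_w: np.ndarray,
    log_eta: np.ndarray,
    master_w: np.ndarray,
    master_eta: np.ndarray,
) -> float:
    """Log10 shift minimising squared log–log distance to the master curve.

    The master is interpolated with a monotone cubic (PCHIP); a chord
    interpolant would bias the shift on the curved knee of the flow curve.
    """
    mwu, idx = np.unique(master_w, return_index=True)
    interp = PchipInterpolator(mwu, master_eta[idx])

    def sse(s: float) -> float:
        x = log_w + s
        inside = (x >= mwu[0]) & (x <= mwu[-1])
        if int(inside.sum()) < 2:
            return np.inf
        r = log_eta[inside] - interp(x[inside])
        return float(np.mean(r**2))

    lo = mwu[0] - log_w.max()
    hi = mwu[-1] - log_w.min()
    grid = np.linspace(lo, hi, 801)
    vals = np.array([sse(s) for s in grid])
    if not np.isfinite(vals).any():
        raise OverlapError("no shift yields at least two overlapping points")
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x if res.fun <= vals[i] else grid[i])


def build_master_curve(
    sweeps: Sequence[FrequencySweep], t_ref: float
) -> MasterCurve:
    """Merge sweeps into one master curve by horizontal log-frequency shifts.

    The sweep at ``t_ref`` (which must be one of the sweep temperatures)
    anchors the curve with a_T = 1. Remaining sweeps are shifted one at a
    time, nearest temperature first, each against the master curve grown
    so far; the shift minimises the mean squared log–log distance in the
    overlap window. A single refinement pass then re-optimises each
    sweep's shift against the master assembled from all the others,
    removing most of the order dependence of the sequential sweep.
    Sweeps whose viscosity range does not intersect the master's cannot
    be superposed by a horizontal shift and raise
    :class:`~meltflow.errors.OverlapError` naming the pair.
    """
    if not sweeps:
        raise ValueError("need at least one sweep")
    temps = [s.temperature for s in sweeps]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate sweep temperatures")
    try:
        i_ref = next(i for i, t in enumerate(temps) if abs(t - t_ref) < 1e-9)
    except StopIteration:
        raise ValueError(f"t_ref={t_ref} °C must equal one sweep temperature {temps}")

    ref = sweeps[i_ref]
    order = np.argsort(ref.omega)
    master_w = np.log10(ref.omega[order])
    master_eta = np.log10(ref.eta_star[order])
    shifts: dict[float, float] = {ref.temperature: 1.0}
    merged_temps = [ref.temperature]

    rest = sorted(
        (s for i, s in enumerate(sweeps) if i != i_ref),
        key=lambda s: (abs(s.temperature - t_ref), s.temperature),
    )
    for sw in rest:
        log_w = np.log10(sw.omega)
        log_eta = np.log10(sw.eta_star)
        if log_eta.max() < master_eta.min() or log_eta.min() > master_eta.max():
            nearest = min(merged_temps, key=lambda t: abs(t - sw.temperature))
            raise OverlapError(
                f"sweep at {sw.temperature} °C shares no viscosity range with the "
                f"master curve (nearest merged sweep: {nearest} °C); horizontal "
                "shifting cannot superpose them"
            )
        try:
            s = _shift_one(log_w, log_eta, master_w, master_eta)
        except OverlapError as exc:
            raise OverlapError(f"sweep at {sw.temperature} °C: {exc}") from exc
        shifts[sw.temperature] = float(10.0**s)
        new_w = np.concatenate([master_w, log_w + s])
        new_eta = np.concatenate([master_eta, log_eta])
        order = np.argsort(new_w)
        master_w, master_eta = new_w[order], new_eta[order]
        merged_temps.append(sw.temperature)

    # refinement pass: re-shift each sweep against all the others
    by_temp = {s.temperature: s for s in sweeps}
    log_shift = {t: np.log10(a) for t, a in shifts.items()}
    for sw in rest:
        other_w = np.concatenate(
            [np.log10(by_temp[t].omega) + log_shift[t]
             for t in log_shift if t != sw.temperature]
        )
        other_eta = np.concatenate(
            [np.log10(by_temp[t].eta_star)
             for t in log_shift if t != sw.temperature]
        )
        order = np.argsort(other_w)
        s = _shift_one(np.log10(sw.omega), np.log10(sw.eta_star),
                       other_w[order], other_eta[order])
        log_shift[sw.temperature] = s
        shifts[sw.temperature] = float(10.0**s)

    master_w = np.concatenate(
        [np.log10(by_temp[t].omega) + log_shift[t] for t in log_shift]
    )
    master_eta = np.concatenate(
        [np.log10(by_temp[t].eta_star) for t in log_shift]
    )
    order = np.argsort(master_w)
    return MasterCurve(
        t_ref=t_ref,
        shift_factors=dict(sorted(shifts.items())),
        omega_reduced=10.0 ** master_w[order],
        eta_star=10.0 ** master_eta[order],
    )


def _cy_log_eta(theta: np.ndarray, log_rate: np.ndarray, fixed_a: float | None) -> np.ndarray:
    if fixed_a is None:
        ln_eta0, ln_lam, ln_a, n = theta
        a = np.exp(ln_a)
    else:
        ln_eta0, ln_lam, n = theta
        a = fixed_a
    lam = np.exp(ln_lam)
    rate = 10.0**log_rate
    # log form keeps the plateau/thinning transition well-conditioned
    return ln_eta0 + (n - 1.0) / a * np.log1p((lam * rate) ** a)


def fit_carreau_yasuda(
    curve: MasterCurve | tuple[np.ndarray, np.ndarray],
    t_ref: float | None = None,
) -> CYFitResult:
    """Fit the reduced Carreau–Yasuda model in log-viscosity.

    Accepts a :class:`MasterCurve` or a raw ``(rate, viscosity)`` pair
    (Cox–Merz: reduced frequencies count as shear rates). Fewer than five
    points, or data that do not span both the plateau and the thinning
    region (viscosity ratio < 2), trigger a warning and a reduced fit
    with the transition breadth fixed at a = 2.
    """
    if isinstance(curve, MasterCurve):
        rate, eta = curve.omega_reduced, curve.eta_star
        t_ref = curve.t_ref if t_ref is None else t_ref
    else:
        rate = np.asarray(curve[0], dtype=float)
        eta = np.asarray(curve[1], dtype=float)
        if t_ref is None:
            raise TypeError("t_ref is required when fitting raw points")
    if np.any(rate <= 0) or np.any(eta <= 0):
        raise ValueError("rates and viscosities must be positive")
    log_rate = np.log10(rate)
    log_eta_data = np.log(eta)

    reduced = len(rate) < 5 or (eta.max() / eta.min()) < 2.0
    fixed_a = 2.0 if reduced else None
    if reduced:
        warnings.warn(
            "flow curve does not resolve both plateau and thinning; "
            "fitting with transition breadth fixed at a = 2",
            stacklevel=2,
        )

    eta0_init = float(eta.max())
    lam_init = 1.0 / float(np.median(rate))
    if fixed_a is None:
        x0 = np.array([np.log(eta0_init), np.log(lam_init), np.log(2.0), 0.3])
        lb = np.array([-np.inf, -np.inf, -np.inf, 1e-6])
        ub = np.array([np.inf, np.inf, np.inf, 1.0])
    else:
        x0 = np.array([np.log(eta0_init), np.log(lam_init), 0.3])
        lb = np.array([-np.inf, -np.inf, 1e-6])
        ub = np.array([np.inf, np.inf, 1.0])

    def resid(theta: np.ndarray) -> np.ndarray:
        return _cy_log_eta(theta, log_rate, fixed_a) - log_eta_data

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"Carreau–Yasuda fit did not converge: {sol.message}")
    if fixed_a is None:
        ln_eta0, ln_lam, ln_a, n = sol.x
        a_val = float(np.exp(ln_a))
    else:
        ln_eta0, ln_lam, n = sol.x
        a_val = fixed_a
    fit = FlowCurveFit(
        eta0=float(np.exp(ln_eta0)),
        lam=float(np.exp(ln_lam)),
        a=a_val,
        n=float(min(n, 1.0)),
        t_ref=float(t_ref),
    )
    dof = max(len(rate) - len(sol.x), 1)
    sigma2 = 2.0 * sol.cost / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        se = np.full(len(sol.x), np.nan)
    if fixed_a is not None:
        se = np.array([se[0], se[1], 0.0, se[2]])
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return CYFitResult(fit=fit, rms_log_residual=rms,
                       stderr=tuple(float(s) for s in se), dof=dof, reduced=reduced)


def fit_wlf(shift_factors: Mapping[float, float], t0: float) -> WLFFitResult:
    """Least-squares WLF constants from a temperature → a_T map.

    Needs shift factors at no fewer than three temperatures besides the
    reference ``t0`` (two parameters plus one degree of freedom).
    """
    temps = np.array([t for t in shift_factors if abs(t - t0) > 1e-9])
    if temps.size < 3:
        raise FitError(
            f"fit_wlf needs >= 3 temperatures besides t0, got {temps.size}"
        )
    log_at = np.array([np.log10(shift_factors[t]) for t in temps])
    dt = temps - t0

    def resid(p: np.ndarray) -> np.ndarray:
        c1, c2 = p
        return -c1 * dt / (c2 + dt) - log_at

    sol = least_squares(resid, x0=np.array([8.0, 120.0]),
                        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"WLF fit did not converge: {sol.message}")
    dof = max(temps.size - 2, 1)
    sigma2 = 2.0 * sol.cost / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.array([np.nan, np.nan])
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return WLFFitResult(
        params=WLFParams(c1=float(sol.x[0]), c2=float(sol.x[1]), t0=float(t0)),
        rms_log_residual=rms,
        stderr=(float(se[0]), float(se[1])),
        dof=dof,
    )


def eval_viscosity(fit: FlowCurveFit, gamma_dot):
    """Carreau–Yasuda viscosity (Pa·s) at shear rate ``gamma_dot`` (1/s)."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    eta = fit.eta0 * (1.0 + (fit.lam * g) ** fit.a) ** ((fit.n - 1.0) / fit.a)
    return float(eta) if np.isscalar(gamma_dot) else eta


def eval_viscosity_at(
    fit: FlowCurveFit, wlf: WLFParams, gamma_dot, temperature: float
):
    """Viscosity at an off-reference temperature via horizontal TTS.

    The shift a_T(T)/a_T(t_ref) multiplies the relaxation time, i.e.
    η(γ̇, T) = η_ref(a_T·γ̇); the plateau itself is unshifted, matching
    the horizontal-only master-curve construction.
    """
    ratio = float(wlf.a_t(temperature)) / float(wlf.a_t(fit.t_ref))
    shifted = FlowCurveFit(eta0=fit.eta0, lam=fit.lam * ratio, a=fit.a,
                           n=fit.n, t_ref=temperature)
    return eval_viscosity(shifted, gamma_dot)
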
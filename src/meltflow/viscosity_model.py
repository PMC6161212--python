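"""Model-based melt viscosity: predict a blend's flow curve from its Tg.

The zero-shear viscosity of a drug/polymer glass-former correlates
exponentially with its glass transition temperature at a fixed melt
temperature,

    η0 = a · exp(b · Tg),

with ``a`` (Pa·s) specific to the reference temperature and ``b`` (1/°C)
essentially temperature-independent. Once the pure polymer's
Carreau–Yasuda/WLF description is known, a blend's full flow curve
follows from its Tg alone: η0 is taken from the correlation, the
relaxation time is rescaled by the same ratio,

    r = η0,blend / η0,polymer,      λ_blend = r · λ_polymer,

and the shape parameters n and a plus the WLF constants are inherited
from the polymer. This collapses the experimental effort for a new
formulation to a single DSC measurement of the blend Tg.

The correlation shipped by :func:`default_correlation` is calibrated to
the packaged (Tg, η0-estimated) pairs at 150 °C from the reference
dataset; recalibrate with :func:`calibrate_correlation` for other
polymers or reference temperatures.

The correlation carries no information about specific drug–polymer
interactions (hydrogen bonding, dissolution of the drug in the melt), so
predictions for blends at or above ~30 % drug loading of a drug that is
soluble in the polymer are flagged with a warning rather than trusted
silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FitError
from .materials import load_reference_dataset
from .rheology import FlowCurveFit, WLFParams

__all__ = [
    "TgViscosityCorrelation",
    "HighLoadingWarning",
    "calibrate_correlation",
    "default_correlation",
    "predict_eta0",
    "generate_model_flow_curve",
]


class HighLoadingWarning(UserWarning):
    """Prediction requested outside the correlation's trusted regime."""


@dataclass(frozen=True)
class TgViscosityCorrelation:
    """Calibrated η0 = a·exp(b·Tg) at a stated reference temperature.

    ``a_coeff`` is in Pa·s (temperature-dependent), ``b_coeff`` in 1/°C
    with Tg in °C. ``r2`` refers to the log-linear calibration fit.
    """

    a_coeff: float
    b_coeff: float
    t_ref: float
    calibration_points: tuple[tuple[float, float], ...]
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if not self.a_coeff > 0:
            raise ValueError("a_coeff must be positive")
        if not self.b_coeff > 0:
            raise ValueError("b_coeff must be positive (higher Tg ⇒ higher η0)")


def calibrate_correlation(
    points: list[tuple[float, float]], t_ref: float
) -> TgViscosityCorrelation:
    """Least squares on ln η0 = ln a + b·Tg over (Tg °C, η0 Pa·s) points."""
    if len(points) < 2:
        raise FitError("calibration needs at least two (Tg, η0) points")
    tg = np.array([p[0] for p in points], dtype=float)
    eta0 = np.array([p[1] for p in points], dtype=float)
    if np.any(eta0 <= 0):
        raise ValueError("η0 values must be positive")
    if np.ptp(tg) == 0:
        raise FitError("calibration points must span distinct Tg values")
    y = np.log(eta0)
    b, ln_a = np.polyfit(tg, y, 1)
    resid = y - (ln_a + b * tg)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return TgViscosityCorrelation(
        a_coeff=float(np.exp(ln_a)),
        b_coeff=float(b),
        t_ref=float(t_ref),
        calibration_points=tuple((float(t), float(e)) for t, e in points),
        r2=r2,
    )


def default_correlation() -> TgViscosityCorrelation:
    """Correlation calibrated to the packaged η0-estimated pairs at 150 °C."""
    ds = load_reference_dataset()
    pts = [
        (p.tg, p.eta0_estimated)
        for p in ds.viscosity_pairs.values()
        if p.eta0_estimated is not None
    ]
    t_ref = {p.temperature for p in ds.viscosity_pairs.values()}.pop()
    return calibrate_correlation(pts, t_ref=t_ref)


def predict_eta0(corr: TgViscosityCorrelation, tg_blend: float) -> float:
    """Zero-shear viscosity (Pa·s) of a blend with glass transition ``tg_blend`` (°C)."""
    return corr.a_coeff * math.exp(corr.b_coeff * tg_blend)


def generate_model_flow_curve(
    polymer_fit: FlowCurveFit,
    polymer_wlf: WLFParams,
    corr: TgViscosityCorrelation,
    tg_blend: float,
    w_api: float | None = None,
    api_soluble: bool | None = None,
) -> FlowCurveFit:
    """Blend flow curve from its Tg and the pure polymer's description.

    η0 comes from the correlation; λ is the polymer's scaled by
    r = η0,blend/η0,polymer; n and a are copied unchanged, as are the
    WLF constants (callers keep using ``polymer_wlf``). All three inputs
    must share one reference temperature.

    Passing ``w_api``/``api_soluble`` enables a regime check: at drug
    weight fractions ≥ 0.30 of a drug soluble in the polymer the
    correlation is known to drift, and a :class:`HighLoadingWarning`
    is emitted.
    """
    refs = {round(polymer_fit.t_ref, 6), round(corr.t_ref, 6), round(polymer_wlf.t0, 6)}
    if len(refs) != 1:
        raise ValueError(
            "polymer fit, WLF and correlation must share one reference "
            f"temperature; got {sorted(refs)} °C"
        )
    if w_api is not None and api_soluble and w_api >= 0.30:
        warnings.warn(
            f"drug weight fraction {w_api:.2f} with a polymer-soluble drug is "
            "outside the correlation's validated regime; specific interactions "
            "may depress the true melt viscosity",
            HighLoadingWarning,
            stacklevel=2,
        )
    eta0_blend = predict_eta0(corr, tg_blend)
    r = eta0_blend / polymer_fit.eta0
    return FlowCurveFit(
        eta0=eta0_blend,
        lam=polymer_fit.lam * r,
        a=polymer_fit.a,
        n=polymer_fit.n,
        t_ref=polymer_fit.t_ref,
    )
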
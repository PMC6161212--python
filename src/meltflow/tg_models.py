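"""Glass-transition mixing models for drug/polymer blends.

Two models are provided. The Couchman–Karasz (CK) rule predicts the Tg of
an ideally mixed blend from the component Tgs and the ratio of their
heat-capacity steps,

    Tg = (w1·Tg1 + k·(1−w1)·Tg2) / (w1 + k·(1−w1)),   k = ΔCp2/ΔCp1,

with component 1 the drug and component 2 the polymer, evaluated on the
absolute (Kelvin) scale. The BCKV polynomial extends the linear mixing
rule with a composition-dependent correction,

    Tg(w1) = w1·Tg1 + (1−w1)·Tg2 + w1(1−w1)·[a0 + a1·u + a2·u²],

where u = 2·w1 − 1, so positive and negative departures from ideal mixing
can be captured. The signed gap between a measured blend Tg and the CK
prediction is the standard diagnostic for specific drug–polymer
interactions; both the per-composition deviation and the extremum of the
BCKV−CK difference over the full composition range are exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FitError
from .materials import BlendRecord, BlendSpec, MaterialProps

__all__ = [
    "KELVIN_OFFSET",
    "CKParams",
    "BCKVParams",
    "BCKVFitResult",
    "ck_tg",
    "bckv_tg",
    "fit_bckv",
    "ck_deviation",
    "ck_bckv_extremum",
]

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class CKParams:
    """Couchman–Karasz inputs: component Tgs (K) and k = ΔCp2/ΔCp1."""

    tg_api_K: float
    tg_polymer_K: float
    k_ck: float

    def __post_init__(self) -> None:
        if not self.k_ck > 0:
            raise ValueError(f"k_ck must be > 0, got {self.k_ck}")
        if not (self.tg_api_K > 0 and self.tg_polymer_K > 0):
            raise ValueError("component Tgs must be positive on the Kelvin scale")

    @classmethod
    def from_materials(cls, api: MaterialProps, polymer: MaterialProps) -> "CKParams":
        if api.delta_cp <= 0 or polymer.delta_cp <= 0:
            raise ValueError("both components need a positive ΔCp at Tg")
        return cls(
            tg_api_K=api.tg + KELVIN_OFFSET,
            tg_polymer_K=polymer.tg + KELVIN_OFFSET,
            k_ck=polymer.delta_cp / api.delta_cp,
        )


@dataclass(frozen=True)
class BCKVParams:
    """BCKV polynomial: endpoint Tgs (°C) and correction coefficients (°C)."""

    tg_api: float
    tg_polymer: float
    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0

    def __post_init__(self) -> None:
        for c in (self.a0, self.a1, self.a2):
            if not math.isfinite(c):
                raise ValueError("BCKV coefficients must be finite")


@dataclass(frozen=True)
class BCKVFitResult:
    """Fitted BCKV coefficients with goodness of fit."""

    params: BCKVParams
    adjusted_r2: float
    r2: float
    n_points: int
    n_coefficients: int
    residuals: tuple[float, ...]


def ck_tg(blend: BlendSpec | CKParams, w_api: float | None = None) -> float:
    """Couchman–Karasz blend Tg in °C.

    Accepts either a :class:`~meltflow.materials.BlendSpec` (weight
    fraction taken from the spec) or explicit :class:`CKParams` plus
    ``w_api``. The mixing rule is evaluated in Kelvin and converted back.
    """
    if isinstance(blend, BlendSpec):
        if blend.api is None:
            return blend.polymer.tg
        params = CKParams.from_materials(blend.api, blend.polymer)
        w = blend.w_api
    else:
        params = blend
        if w_api is None:
            raise TypeError("w_api is required when passing CKParams directly")
        w = w_api
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w_api must be in [0, 1], got {w}")
    k = params.k_ck
    tg_K = (w * params.tg_api_K + k * (1.0 - w) * params.tg_polymer_K) / (
        w + k * (1.0 - w)
    )
    return tg_K - KELVIN_OFFSET


def bckv_tg(params: BCKVParams, w_api):
    """BCKV blend Tg (°C) at drug weight fraction ``w_api`` (scalar or array)."""
    w = np.asarray(w_api, dtype=float)
    if np.any(w < 0.0) or np.any(w > 1.0):
        raise ValueError("w_api must be in [0, 1]")
    u = 2.0 * w - 1.0
    corr = w * (1.0 - w) * (params.a0 + params.a1 * u + params.a2 * u * u)
    tg = w * params.tg_api + (1.0 - w) * params.tg_polymer + corr
    return float(tg) if np.isscalar(w_api) else tg


def fit_bckv(
    points: list[tuple[float, float]], tg_api: float, tg_polymer: float
) -> BCKVFitResult:
    """Least-squares fit of the BCKV correction coefficients.

    The endpoints are pinned to the pure-component Tgs (the functional
    form vanishes there), so only interior compositions (0 < w < 1)
    inform the fit. With at least three interior points all of
    (a0, a1, a2) are fitted; with two, a2 is fixed at zero; with one,
    only a0 is fitted. The fit is linear in the coefficients, so plain
    linear least squares is exact.
    """
    pts = [(float(w), float(tg)) for w, tg in points]
    interior = [(w, tg) for w, tg in pts if 0.0 < w < 1.0]
    if not interior:
        raise FitError("fit_bckv needs at least one interior composition (0 < w < 1)")
    n_coef = min(3, len(interior))
    w = np.array([p[0] for p in interior])
    tg = np.array([p[1] for p in interior])
    u = 2.0 * w - 1.0
    weight = w * (1.0 - w)
    design = np.column_stack([weight * u**j for j in range(n_coef)])
    y = tg - (w * tg_api + (1.0 - w) * tg_polymer)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a = np.zeros(3)
    a[:n_coef] = coef
    params = BCKVParams(tg_api=tg_api, tg_polymer=tg_polymer, a0=a[0], a1=a[1], a2=a[2])

    pred = bckv_tg(params, np.array([p[0] for p in pts]))
    obs = np.array([p[1] for p in pts])
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    n = len(pts)
    dof = n - n_coef - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
    return BCKVFitResult(
        params=params,
        adjusted_r2=adj,
        r2=r2,
        n_points=n,
        n_coefficients=n_coef,
        residuals=tuple(float(r) for r in resid),
    )


def ck_deviation(record: BlendRecord) -> float:
    """Signed gap (°C) between the measured blend Tg and the CK prediction.

    Positive means the blend vitrifies above the ideal-mixing
    prediction (e.g. hydrogen-bond-forming drug/polymer pairs).
    """
    return record.tg_measured - ck_tg(record.blend)


def ck_bckv_extremum(
    bckv: BCKVParams, ck: CKParams, step: float = 0.001
) -> tuple[float, float]:
    """Largest-magnitude BCKV−CK gap over w ∈ [0, 1] on a regular grid.

    Returns ``(w_at_extremum, signed_deviation_degC)``. Useful when a
    deviation is quoted for a curve rather than a single composition.
    """
    w = np.arange(0.0, 1.0 + step / 2, step)
    ck_curve = np.array([ck_tg(ck, wi) for wi in w])
    diff = bckv_tg(bckv, w) - ck_curve
    i = int(np.argmax(np.abs(diff)))
    return float(w[i]), float(diff[i])
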
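"""Ground-truth synthetic data generators for every fitting stage.

No public measurement archive accompanies the melt-viscosity workflow,
so each fit is validated against data generated from known parameters:

* SAOS frequency sweeps from a Carreau–Yasuda/WLF ground truth, with
  multiplicative log-normal noise on the viscosity (rheometer-typical);
* Tg-vs-composition sets from a BCKV ground truth, with additive
  Gaussian noise in kelvin (DSC-typical);
* annealing records from a ground-truth solubility boundary plus the
  BCKV curve: the soluble fraction at the hold temperature is
  min(nominal loading, boundary value), and the recorded Tg is the BCKV
  value at that fraction plus noise.

All generators are pure functions of their spec, whose ``seed`` makes
the output reproducible byte for byte. Default noise levels are 2 %
(relative, viscosity) and 0.5 K (Tg); both are configurable.

The emulated measurement designs mirror small-scale practice: sweeps
from 10 Hz down to 0.1 Hz in 10 K temperature steps, and annealing
holds placed well above (≈60 °C) the predicted blend Tg so the melt is
mobile enough to equilibrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rheology import FlowCurveFit, FrequencySweep, WLFParams
from .solubility import AnnealingRecord, SolubilityCurve
from .tg_models import BCKVParams, bckv_tg

__all__ = [
    "SaosSpec",
    "TgDatasetSpec",
    "AnnealingSpec",
    "make_saos_dataset",
    "make_tg_dataset",
    "make_annealing_dataset",
    "default_polymer_truth",
    "cxb_like_solubility_truth",
]


def default_polymer_truth() -> tuple[FlowCurveFit, WLFParams]:
    """A copovidone-like melt at 150 °C: stiff plateau, broad thinning."""
    cy = FlowCurveFit(eta0=1.0e4, lam=0.5, a=2.0, n=0.3, t_ref=150.0)
    wlf = WLFParams(c1=8.0, c2=120.0, t0=150.0)
    return cy, wlf


def cxb_like_solubility_truth(
    solubility_at_25: float = 0.33, melting_point: float = 160.9, r0: float = -8.0
) -> SolubilityCurve:
    """Exponential boundary anchored at the drug melting point.

    ``A`` is chosen so the boundary passes through
    (``solubility_at_25``, 25 °C); with ``r0`` < 0 the offset ``y0``
    equals the full-dissolution (melting) temperature at w → 1.
    """
    A = (25.0 - melting_point) / np.exp(r0 * solubility_at_25)
    return SolubilityCurve(y0=melting_point, A=float(A), r0=r0)


@dataclass(frozen=True)
class SaosSpec:
    """Design of a synthetic SAOS campaign."""

    cy: FlowCurveFit = field(default_factory=lambda: default_polymer_truth()[0])
    wlf: WLFParams = field(default_factory=lambda: default_polymer_truth()[1])
    temperatures: tuple[float, ...] = (130.0, 140.0, 150.0, 160.0, 170.0)
    freq_max_hz: float = 10.0
    freq_min_hz: float = 0.1
    n_freq: int = 9
    noise_sigma: float = 0.02  # relative, multiplicative log-normal
    seed: int = 0


@dataclass(frozen=True)
class TgDatasetSpec:
    """Design of a synthetic Tg-vs-composition study."""

    bckv: BCKVParams
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    noise_sigma_K: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class AnnealingSpec:
    """Design of a synthetic annealing-DSC solubility study."""

    bckv: BCKVParams
    solubility: SolubilityCurve
    nominal_w_api: tuple[float, ...] = (0.95,) * 8
    t_annealing: tuple[float, ...] = (100.0, 110.0, 120.0, 130.0, 140.0, 148.0, 154.0, 158.0)
    noise_sigma_K: float = 0.5
    seed: int = 0


def make_saos_dataset(spec: SaosSpec) -> list[FrequencySweep]:
    """Frequency sweeps with |η*|(ω, T) = CY(ω·a_T) and log-normal noise."""
    rng = np.random.default_rng(spec.seed)
    freqs = np.geomspace(spec.freq_max_hz, spec.freq_min_hz, spec.n_freq)
    omega = 2.0 * np.pi * freqs  # descending
    sweeps = []
    for t in spec.temperatures:
        a_t = float(spec.wlf.a_t(t)) / float(spec.wlf.a_t(spec.cy.t_ref))
        reduced = omega * a_t
        eta = spec.cy.eta0 * (
            1.0 + (spec.cy.lam * reduced) ** spec.cy.a
        ) ** ((spec.cy.n - 1.0) / spec.cy.a)
        if spec.noise_sigma > 0:
            eta = eta * np.exp(rng.normal(0.0, spec.noise_sigma, size=eta.shape))
        sweeps.append(FrequencySweep(temperature=float(t), omega=omega.copy(), eta_star=eta))
    return sweeps


def make_tg_dataset(spec: TgDatasetSpec) -> list[tuple[float, float]]:
    """(w_api, Tg °C) points on the BCKV ground truth plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.fractions, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("fractions must lie in [0, 1]")
    tg = bckv_tg(spec.bckv, w)
    if spec.noise_sigma_K > 0:
        tg = tg + rng.normal(0.0, spec.noise_sigma_K, size=tg.shape)
    return [(float(wi), float(ti)) for wi, ti in zip(w, tg)]


def make_annealing_dataset(spec: AnnealingSpec) -> list[AnnealingRecord]:
    """Annealing records consistent with the ground-truth phase boundary.

    At each hold the dissolved fraction is min(nominal, boundary value at
    the hold temperature) — samples loaded below the boundary dissolve
    completely — and the recorded Tg is the BCKV value there plus noise.
    """
    if len(spec.nominal_w_api) != len(spec.t_annealing):
        raise ValueError("nominal_w_api and t_annealing must have equal length")
    rng = np.random.default_rng(spec.seed)
    records = []
    for w_nom, t_ann in zip(spec.nominal_w_api, spec.t_annealing):
        # invert the monotone boundary T(x) at t_ann
        ratio = (t_ann - spec.solubility.y0) / spec.solubility.A
        x_curve = np.log(ratio) / spec.solubility.r0 if ratio > 0 else 0.0
        soluble = min(float(w_nom), float(np.clip(x_curve, 0.0, 1.0)))
        tg = bckv_tg(spec.bckv, soluble)
        if spec.noise_sigma_K > 0:
            tg = tg + float(rng.normal(0.0, spec.noise_sigma_K))
        records.append(
            AnnealingRecord(nominal_w_api=float(w_nom), t_annealing=float(t_ann),
                            tg_annealed=float(tg))
        )
    return records
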
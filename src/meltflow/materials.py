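"""Substance and blend property containers plus the packaged reference dataset.

The packaged dataset describes copovidone (COP, the vinylpyrrolidone-vinyl
acetate copolymer used as the amorphous matrix) together with four BCS
class II model drugs — celecoxib (CXB), loratadine (LOR), naproxen (NAP)
and praziquantel (PZQ). It carries three tables:

* pure-substance thermal constants (glass transition Tg, heat-capacity
  step ΔCp at Tg, melting point, molecular weight);
* blend records at 0/10/30 % drug weight fraction (measured blend Tg,
  true densities of powder and extrudate, specific heat at 25/150 °C);
* zero-shear viscosity pairs at 150 °C — the rheometer-measured η₀ of a
  blend next to the value estimated from its Tg via the exponential
  Tg–η₀ correlation. These pairs are the default calibration data for
  :mod:`meltflow.viscosity_model`.

Temperatures are stored in °C throughout; conversion to Kelvin happens
explicitly where a thermodynamic formula demands it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError

__all__ = [
    "MaterialProps",
    "BlendSpec",
    "BlendRecord",
    "ViscosityPair",
    "ReferenceDataset",
    "load_reference_dataset",
    "read_materials_csv",
    "write_materials_csv",
    "read_blends_csv",
]

_MATERIAL_COLUMNS = ("name", "tg_C", "delta_cp_J_per_gK")
_BLEND_COLUMNS = ("label", "api", "w_api", "tg_C")


@dataclass(frozen=True)
class MaterialProps:
    """Thermal constants of a pure substance.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"Copovidone"``.
    tg:
        Glass transition temperature in °C.
    delta_cp:
        Heat-capacity step at Tg in J/(g·K); must be positive.
    melting_point:
        Melting point in °C; absent for amorphous polymers.
    molecular_weight:
        g/mol; optional (polydisperse polymers have none).
    note:
        Free-text provenance remark (e.g. how an unstable Tg was obtained).
    """

    name: str
    tg: float
    delta_cp: float
    melting_point: float | None = None
    molecular_weight: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not self.delta_cp > 0:
            raise ValueError(f"{self.name}: delta_cp must be > 0, got {self.delta_cp}")
        if self.melting_point is not None and not self.tg < self.melting_point:
            raise ValueError(
                f"{self.name}: tg ({self.tg} °C) must lie below the melting "
                f"point ({self.melting_point} °C)"
            )


@dataclass(frozen=True)
class BlendSpec:
    """A drug/polymer pair at a given drug weight fraction.

    ``w_api`` is the weight fraction of the drug (component 1); the
    polymer is component 2. ``api`` may be ``None`` only for the pure
    polymer (``w_api == 0``).
    """

    api: MaterialProps | None
    polymer: MaterialProps
    w_api: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_api <= 1.0:
            raise ValueError(f"w_api must be in [0, 1], got {self.w_api}")
        if self.api is None and self.w_api > 0:
            raise ValueError("api material is required when w_api > 0")


@dataclass(frozen=True)
class BlendRecord:
    """Measured properties of one physical blend (or the pure polymer)."""

    label: str
    blend: BlendSpec
    tg_measured: float
    density_powder: float | None = None
    density_extrudate: float | None = None
    cp_25: float | None = None
    cp_150: float | None = None

    def __post_init__(self) -> None:
        for attr in ("density_powder", "density_extrudate"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValueError(f"{self.label}: {attr} must be > 0, got {v}")
        if self.cp_25 is not None and self.cp_150 is not None:
            if not self.cp_150 > self.cp_25:
                raise ValueError(
                    f"{self.label}: cp at 150 °C must exceed cp at 25 °C"
                )


@dataclass(frozen=True)
class ViscosityPair:
    """Measured vs. Tg-model-estimated zero-shear viscosity of a blend."""

    blend_label: str
    tg: float
    temperature: float
    eta0_measured: float | None = None
    eta0_estimated: float | None = None

    def __post_init__(self) -> None:
        for attr in ("eta0_measured", "eta0_estimated"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValueError(f"{self.blend_label}: {attr} must be > 0, got {v}")


@dataclass(frozen=True)
class ReferenceDataset:
    """The packaged copovidone + four-drug dataset, keyed by name/label."""

    materials: Mapping[str, MaterialProps]
    blends: Mapping[str, BlendRecord]
    viscosity_pairs: Mapping[str, ViscosityPair]


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("meltflow").joinpath("data", filename)))


def _opt_float(cell: str | float | None) -> float | None:
    if cell is None:
        return None
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def read_materials_csv(path: str | Path) -> list[MaterialProps]:
    """Read pure-substance constants from a CSV file.

    Required columns: ``name``, ``tg_C``, ``delta_cp_J_per_gK``. Optional:
    ``melting_point_C``, ``molecular_weight``, ``note``. Empty optional
    cells yield absent fields.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MATERIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out: list[MaterialProps] = []
    for i, row in df.iterrows():
        try:
            out.append(
                MaterialProps(
                    name=str(row["name"]).strip(),
                    tg=float(row["tg_C"]),
                    delta_cp=float(row["delta_cp_J_per_gK"]),
                    melting_point=_opt_float(row.get("melting_point_C")),
                    molecular_weight=_opt_float(row.get("molecular_weight")),
                    note=(str(row["note"]).strip() or None)
                    if "note" in df.columns and pd.notna(row.get("note"))
                    else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_materials_csv(materials: Iterable[MaterialProps], path: str | Path) -> None:
    """Write materials in the same schema :func:`read_materials_csv` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["name", "tg_C", "delta_cp_J_per_gK", "melting_point_C",
             "molecular_weight", "note"]
        )
        for m in materials:
            w.writerow(
                [
                    m.name,
                    m.tg,
                    m.delta_cp,
                    "" if m.melting_point is None else m.melting_point,
                    "" if m.molecular_weight is None else m.molecular_weight,
                    m.note or "",
                ]
            )


def read_blends_csv(
    path: str | Path, materials: Mapping[str, MaterialProps], polymer: str = "Copovidone"
) -> list[BlendRecord]:
    """Read blend records, resolving drug names against ``materials``.

    The ``api`` cell may be empty only for the pure-polymer row
    (``w_api == 0``).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _BLEND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if polymer not in materials:
        raise SchemaError(f"polymer {polymer!r} not found in the materials table")
    out: list[BlendRecord] = []
    for i, row in df.iterrows():
        try:
            api_name = str(row["api"]).strip() if pd.notna(row["api"]) else ""
            api = materials[api_name] if api_name else None
            spec = BlendSpec(api=api, polymer=materials[polymer], w_api=float(row["w_api"]))
            out.append(
                BlendRecord(
                    label=str(row["label"]).strip(),
                    blend=spec,
                    tg_measured=float(row["tg_C"]),
                    density_powder=_opt_float(row.get("density_powder_kg_m3")),
                    density_extrudate=_opt_float(row.get("density_extrudate_kg_m3")),
                    cp_25=_opt_float(row.get("cp25_J_per_gK")),
                    cp_150=_opt_float(row.get("cp150_J_per_gK")),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: row {i + 2}: unknown material {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def load_reference_dataset() -> ReferenceDataset:
    """Load the packaged dataset (5 materials, 9 blend records, 5 η₀ pairs)."""
    materials = {m.name: m for m in read_materials_csv(_data_path("materials.csv"))}
    blends = {
        b.label: b
        for b in read_blends_csv(_data_path("blends.csv"), materials)
    }
    pairs_df = pd.read_csv(_data_path("viscosity_pairs.csv"), dtype=str)
    pairs = {}
    for _, row in pairs_df.iterrows():
        p = ViscosityPair(
            blend_label=str(row["label"]),
            tg=float(row["tg_C"]),
            temperature=float(row["temperature_C"]),
            eta0_measured=_opt_float(row["eta0_measured_Pa_s"]),
            eta0_estimated=_opt_float(row["eta0_estimated_Pa_s"]),
        )
        pairs[p.blend_label] = p
    return ReferenceDataset(materials=materials, blends=blends, viscosity_pairs=pairs)
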
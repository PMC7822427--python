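"""Derived root-morphology traits and the ratio decomposition.

From raw measurements per root type — length L (cm), volume V (cm^3), dry
weight DW (g) — and the whole-plant dry weight PDW (g), the derived traits
are

* root length ratio      RLR = L / PDW   (cm g^-1)
* root mass ratio        RMR = DW / PDW  (g g^-1)
* root fineness          RF  = L / V     (cm cm^-3)
* root tissue density    RTD = DW / V    (g cm^-3)

which satisfy the exact algebraic identity ``RLR = RMR * RF / RTD`` for
every plant and root type, since (DW/PDW)(L/V)/(DW/V) = L/PDW.  Axis root
types (primary, seminal) additionally carry a branching density
BD = lateral count / branching-zone length (n cm^-1); lateral classes
carry their number and average length (total length / count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TIDY_COLUMNS

__all__ = [
    "RawRootRecord",
    "DerivedTraits",
    "derive_traits",
    "plant_totals",
    "derive_dataset",
    "IncompletePlantError",
]

AXIS_TYPES = ("primary", "seminal")
ALL_ROOT_TYPES = ("primary", "seminal", "primary_lateral", "seminal_lateral")


class IncompletePlantError(ValueError):
    """A plant is missing one or more root types required for totals."""


@dataclass(frozen=True)
class RawRootRecord:
    """Raw measurements of one root type of one plant (units: cm, cm^2,
    cm^3, g; counts dimensionless)."""

    plant_id: str
    root_type: str
    length: float
    volume: float
    dry_weight: float
    fresh_weight: float = math.nan
    surface_area: float = math.nan
    lateral_count: float = math.nan
    root_zone: float = math.nan
    branching_zone: float = math.nan

    def __post_init__(self) -> None:
        if self.length <= 0 or self.volume <= 0:
            raise ValueError("length and volume must be positive")
        if self.dry_weight <= 0:
            raise ValueError("dry weight must be positive")
        if not math.isnan(self.fresh_weight) and self.dry_weight > self.fresh_weight:
            raise ValueError("dry weight cannot exceed fresh weight")


@dataclass(frozen=True)
class DerivedTraits:
    """Derived ratio traits of one root type of one plant."""

    RLR: float
    RMR: float
    fineness: float
    tissue_density: float
    branching_density: float = math.nan
    number: float = math.nan
    average_length: float = math.nan


def derive_traits(raw: RawRootRecord, plant_dry_weight: float) -> DerivedTraits:
    """Compute the derived traits of one root record.

    Branching density is computed only when the record carries both a
    lateral count and a positive branching zone (the axis case); number
    and average length only when a count is present without a branching
    zone (the lateral case).
    """
    if plant_dry_weight <= 0:
        raise ValueError("plant dry weight must be positive")
    rlr = raw.length / plant_dry_weight
    rmr = raw.dry_weight / plant_dry_weight
    rf = raw.length / raw.volume
    rtd = raw.dry_weight / raw.volume

    bd = math.nan
    number = math.nan
    avg_len = math.nan
    has_count = not math.isnan(raw.lateral_count)
    has_bz = not math.isnan(raw.branching_zone)
    if has_count and has_bz:
        if raw.branching_zone <= 0:
            raise ValueError("branching zone must be positive for branching density")
        bd = raw.lateral_count / raw.branching_zone
    elif has_count:
        number = raw.lateral_count
        if raw.lateral_count > 0:
            avg_len = raw.length / raw.lateral_count
    return DerivedTraits(RLR=rlr, RMR=rmr, fineness=rf, tissue_density=rtd,
                         branching_density=bd, number=number, average_length=avg_len)


def plant_totals(
    records: list[RawRootRecord],
    shoot_fresh_weight: float,
    shoot_dry_weight: float,
    required_types: tuple[str, ...] = ALL_ROOT_TYPES,
) -> tuple[float, float, float, float]:
    """Whole-root and whole-plant fresh/dry weights (RFW, RDW, PFW, PDW).

    Root totals are sums over the root types; plant totals add the shoot.
    All ``required_types`` must be present exactly once.
    """
    present = [r.root_type for r in records]
    missing = [t for t in required_types if t not in present]
    if missing:
        raise IncompletePlantError(f"missing root types: {missing}")
    if len(present) != len(set(present)):
        raise IncompletePlantError("duplicate root-type records for one plant")
    rfw = float(sum(r.fresh_weight for r in records))
    rdw = float(sum(r.dry_weight for r in records))
    return rfw, rdw, shoot_fresh_weight + rfw, shoot_dry_weight + rdw


def derive_dataset(raw: pd.DataFrame, plants: pd.DataFrame) -> pd.DataFrame:
    """Tidy trait table (raw fields + derived traits) from raw frames.

    ``raw`` has one row per plant x root type with the measurement
    columns; ``plants`` carries shoot weights per plant.  The output is
    the tidy dialect consumed by the statistical modules, including the
    plant-level totals as root type ``plant``.
    """
    shoot = plants.set_index("plant_id")
    rows: list[tuple] = []
    for plant_id, grp in raw.groupby("plant_id", sort=False):
        treatment = grp["treatment"].iloc[0]
        records = [
            RawRootRecord(
                plant_id=plant_id,
                root_type=r.root_type,
                length=r.length,
                volume=r.volume,
                dry_weight=r.dry_weight,
                fresh_weight=r.fresh_weight,
                surface_area=r.surface_area,
                lateral_count=r.lateral_count,
                root_zone=r.root_zone,
                branching_zone=r.branching_zone,
            )
            for r in grp.itertuples()
        ]
        required = tuple(t for t in ALL_ROOT_TYPES if t in set(grp["root_type"]))
        rfw, rdw, pfw, pdw = plant_totals(
            records,
            shoot.at[plant_id, "shoot_fresh_weight"],
            shoot.at[plant_id, "shoot_dry_weight"],
            required_types=required,
        )
        for rec in records:
            derived = derive_traits(rec, pdw)
            pairs = [
                ("length", rec.length),
                ("surface_area", rec.surface_area),
                ("fresh_weight", rec.fresh_weight),
                ("dry_weight", rec.dry_weight),
                ("root_zone", rec.root_zone),
                ("branching_zone", rec.branching_zone),
                ("RLR", derived.RLR),
                ("RMR", derived.RMR),
                ("fineness", derived.fineness),
                ("tissue_density", derived.tissue_density),
                ("branching_density", derived.branching_density),
                ("number", derived.number),
                ("average_length", derived.average_length),
            ]
            rows.extend(
                (plant_id, treatment, rec.root_type, trait, value)
                for trait, value in pairs
                if not (isinstance(value, float) and math.isnan(value))
            )
        rows.extend([
            (plant_id, treatment, "plant", "root_fresh_weight", rfw),
            (plant_id, treatment, "plant", "root_dry_weight", rdw),
            (plant_id, treatment, "plant", "fresh_weight", pfw),
            (plant_id, treatment, "plant", "dry_weight", pdw),
        ])
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)
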
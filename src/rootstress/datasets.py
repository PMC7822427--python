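"""Tidy per-plant trait containers and their CSV dialects.

The central container is :class:`PlantDataset`, which holds one value per
(plant, root type, trait) in tidy form plus, optionally, the raw
measurements (lengths, volumes, weights, lateral counts, zone lengths) and
per-plant shoot weights from which derived traits are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIDY_COLUMNS = ["plant_id", "treatment", "root_type", "trait", "value"]

#: raw measurement columns, one row per plant x root type
RAW_COLUMNS = [
    "plant_id", "treatment", "root_type",
    "length", "surface_area", "volume", "fresh_weight", "dry_weight",
    "lateral_count", "root_zone", "branching_zone",
]

#: per-plant shoot weights
PLANT_COLUMNS = ["plant_id", "treatment", "shoot_fresh_weight", "shoot_dry_weight"]


class DatasetError(ValueError):
    """Raised when a trait table violates the tidy contract."""


@dataclass
class PlantDataset:
    """Per-plant, per-root-type trait observations for a factorial design.

    Parameters
    ----------
    traits
        Tidy frame with columns ``plant_id, treatment, root_type, trait,
        value``; at most one value per (plant_id, root_type, trait).
    raw
        Optional raw measurements (one row per plant x root type) from
        which derived traits can be recomputed.
    plants
        Optional per-plant table carrying shoot fresh/dry weights.
    """

    traits: pd.DataFrame
    raw: pd.DataFrame | None = None
    plants: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in TIDY_COLUMNS if c not in self.traits.columns]
        if missing:
            raise DatasetError(f"trait table missing columns: {missing}")
        dup = self.traits.duplicated(subset=["plant_id", "root_type", "trait"])
        if dup.any():
            raise DatasetError(
                f"{int(dup.sum())} duplicate (plant_id, root_type, trait) rows"
            )
        values = self.traits["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise DatasetError("non-finite trait values")

    @property
    def treatments(self) -> list[str]:
        """Treatment labels in order of first appearance."""
        return list(pd.unique(self.traits["treatment"]))

    @property
    def root_types(self) -> list[str]:
        return list(pd.unique(self.traits["root_type"]))

    def n_plants(self) -> int:
        return self.traits["plant_id"].nunique()

    def to_wide(self) -> pd.DataFrame:
        """One row per plant, one ``root_type.trait`` column per trait.

        The ``treatment`` label is carried as the first column.
        """
        df = self.traits.copy()
        df["column"] = df["root_type"] + "." + df["trait"]
        wide = df.pivot(index="plant_id", columns="column", values="value")
        labels = df.drop_duplicates("plant_id").set_index("plant_id")["treatment"]
        wide.insert(0, "treatment", labels.reindex(wide.index))
        wide.columns.name = None
        return wide

    def summary(self) -> pd.DataFrame:
        """Per treatment x root type x trait: mean, SE and n.

        This is the content of a published summary-table cell.
        """
        g = self.traits.groupby(["root_type", "trait", "treatment"], sort=False)["value"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        out["se"] = out["sd"] / np.sqrt(out["n"])
        return out.drop(columns="sd")

    # -- CSV I/O -----------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        """Write the tidy trait table; raw/plant tables go to sibling files."""
        path = Path(path)
        self.traits.to_csv(path, index=False)
        if self.raw is not None:
            self.raw.to_csv(path.with_name(path.stem + ".raw.csv"), index=False)
        if self.plants is not None:
            self.plants.to_csv(path.with_name(path.stem + ".plants.csv"), index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PlantDataset":
        path = Path(path)
        traits = pd.read_csv(path)
        raw_path = path.with_name(path.stem + ".raw.csv")
        plants_path = path.with_name(path.stem + ".plants.csv")
        raw = pd.read_csv(raw_path) if raw_path.exists() else None
        plants = pd.read_csv(plants_path) if plants_path.exists() else None
        return cls(traits=traits, raw=raw, plants=plants)


@dataclass
class TreatmentSummary:
    """Published-style summary: mean, SE and n per treatment for one trait."""

    root_type: str
    trait: str
    unit: str
    means: dict[str, float]
    ses: dict[str, float]
    n: int = 4
    letters: dict[str, str] = field(default_factory=dict)
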
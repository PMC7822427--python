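"""Synthetic factorial datasets calibrated to the published trait tables.

The study design is 4 stress treatments (Control, Drought, Heat, Combined)
x 4 replicate plants x 4 root types, with only per-treatment means and
standard errors published per trait.  This module regenerates per-plant
data with exactly that statistical structure so every downstream stage
(univariate screen, interaction classifier, PERMANOVA, sPLS-DA) is
exercisable without access to the original raw data.

Two generation modes are supported:

``trait_level``
    each (plant, root type, trait) value is drawn independently from a
    normal law with the calibrated mean and SD = SE * sqrt(n), truncated
    to positive values by resampling;
``raw_level``
    raw measurements (lengths, volumes, weights, counts, zone lengths)
    are drawn so that the derived ratio traits are centred on the
    calibrated values, and derived traits are then *computed* from the
    raw fields — so the ratio decomposition RLR = RMR x RF / RTD holds
    exactly per plant by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from . import _tables
from .datasets import PLANT_COLUMNS, RAW_COLUMNS, TIDY_COLUMNS, PlantDataset

__all__ = [
    "TraitSpec",
    "FixtureCollection",
    "SyntheticConfig",
    "sd_from_se",
    "builtin_table_fixtures",
    "generate_dataset",
]


class ConfigError(ValueError):
    """Invalid synthetic-design configuration."""


def sd_from_se(se: float, n: int) -> float:
    """Recover a sampling standard deviation from a standard error.

    Published tables report the standard error of the mean over ``n``
    replicates; the plant-to-plant SD is ``se * sqrt(n)``.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"replicate count must be a positive integer, got {n}")
    if se < 0:
        raise ValueError(f"standard error must be non-negative, got {se}")
    return float(se) * float(np.sqrt(n))


@dataclass(frozen=True)
class TraitSpec:
    """One summary-table cell: a trait's mean and SE under one treatment."""

    root_type: str
    trait: str
    treatment: str
    mean: float
    se: float
    n: int = 4
    unit: str = ""

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ConfigError(f"negative SE for {self.root_type}/{self.trait}")
        if self.n < 2:
            raise ConfigError("n must be >= 2")

    @property
    def sd(self) -> float:
        return sd_from_se(self.se, self.n)


class FixtureCollection(Mapping[tuple[str, str, str], TraitSpec]):
    """Mapping of (root_type, trait, treatment) -> :class:`TraitSpec`."""

    def __init__(self, specs: Iterable[TraitSpec]):
        self._specs = {(s.root_type, s.trait, s.treatment): s for s in specs}

    def __getitem__(self, key: tuple[str, str, str]) -> TraitSpec:
        return self._specs[key]

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def traits_of(self, root_type: str) -> list[str]:
        seen: dict[str, None] = {}
        for rt, trait, _ in self._specs:
            if rt == root_type:
                seen.setdefault(trait, None)
        return list(seen)

    def mean(self, root_type: str, trait: str, treatment: str) -> float:
        return self[(root_type, trait, treatment)].mean

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "root_type": s.root_type, "trait": s.trait, "unit": s.unit,
                "treatment": s.treatment, "mean": s.mean, "se": s.se, "n": s.n,
            }
            for s in self._specs.values()
        ]
        return pd.DataFrame(rows)


def builtin_table_fixtures() -> FixtureCollection:
    """All published (root type x trait x treatment) mean/SE cells.

    11 traits for each embryonic axis (primary, seminal) and 10 for each
    lateral class, under all four treatments.
    """
    specs = []
    for (root_type, trait), (unit, cells) in _tables.TABLE_CELLS.items():
        for treatment, (mean, se, _letters) in zip(_tables.TREATMENTS, cells):
            specs.append(TraitSpec(
                root_type=root_type, trait=trait, treatment=treatment,
                mean=mean, se=se, n=_tables.N_REPLICATES, unit=unit,
            ))
    return FixtureCollection(specs)


def builtin_letters() -> dict[tuple[str, str, str], str]:
    """Published Tukey letter groupings, for reference and comparison."""
    out = {}
    for (root_type, trait), (_unit, cells) in _tables.TABLE_CELLS.items():
        for treatment, (_m, _s, letters) in zip(_tables.TREATMENTS, cells):
            out[(root_type, trait, treatment)] = letters
    return out


@dataclass
class SyntheticConfig:
    """Design of a synthetic experiment.

    ``seed`` is mandatory and fully determines the output.
    """

    seed: int
    treatments: tuple[str, ...] = _tables.TREATMENTS
    n_per_treatment: int = _tables.N_REPLICATES
    mode: str = "trait_level"
    specs: FixtureCollection = field(default_factory=builtin_table_fixtures)
    #: raw_level only: relative SD of whole-plant dry weight across plants
    plant_dw_cv: float = 0.10
    #: raw_level only: whole-plant dry-matter fraction linking PFW to PDW
    dry_matter_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigError("treatment labels must be unique")
        if self.n_per_treatment < 2:
            raise ConfigError("n_per_treatment must be >= 2")
        if self.mode not in ("trait_level", "raw_level"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        known = {t for (_rt, _tr, t) in self.specs}
        unknown = [t for t in self.treatments if t not in known]
        if unknown:
            raise ConfigError(f"no specs for treatments: {unknown}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load from JSON or YAML; omitted ``specs`` default to the
        built-in published tables."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "seed" not in data:
            raise ConfigError("config file must set a seed")
        if "treatments" in data:
            data["treatments"] = tuple(data["treatments"])
        if "specs" in data:
            data["specs"] = FixtureCollection(
                TraitSpec(**row) for row in data.pop("specs")
            )
        return cls(**data)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to positives by resampling."""
    if sd == 0:
        if mean <= 0:
            raise ConfigError("degenerate spec with non-positive mean")
        return float(mean)
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)


def generate_dataset(config: SyntheticConfig) -> PlantDataset:
    """Draw a per-plant dataset under the configured factorial design.

    Identical config and seed give byte-identical output.  Plants are
    labelled ``P{treatment}{index}``.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "trait_level":
        return _generate_trait_level(config, rng)
    return _generate_raw_level(config, rng)


def _generate_trait_level(config: SyntheticConfig, rng: np.random.Generator) -> PlantDataset:
    keys = list(config.specs)  # stable insertion order
    rows = []
    for treatment in config.treatments:
        t_keys = [k for k in keys if k[2] == treatment]
        for i in range(1, config.n_per_treatment + 1):
            plant_id = f"P{treatment}{i}"
            for key in t_keys:
                spec = config.specs[key]
                value = _positive_normal(rng, spec.mean, spec.sd)
                rows.append((plant_id, treatment, spec.root_type, spec.trait, value))
    return PlantDataset(traits=pd.DataFrame(rows, columns=TIDY_COLUMNS))


# axes carry zone lengths and a lateral count; laterals carry their number
_AXES = ("primary", "seminal")
_LATERAL_OF = {"primary": "primary_lateral", "seminal": "seminal_lateral"}


def _spec_or_none(specs: FixtureCollection, rt: str, trait: str, treatment: str):
    try:
        return specs[(rt, trait, treatment)]
    except KeyError:
        return None


def _generate_raw_level(config: SyntheticConfig, rng: np.random.Generator) -> PlantDataset:
    from .traits import derive_dataset  # deferred: avoids import cycle

    specs = config.specs
    root_types = [rt for rt in _tables.ROOT_TYPES if specs.traits_of(rt)]
    for rt in root_types:
        for needed in ("length", "dry_weight", "fineness"):
            if all(_spec_or_none(specs, rt, needed, t) is None for t in config.treatments):
                raise ConfigError(f"raw_level needs a {needed!r} spec for {rt}")

    raw_rows, plant_rows = [], []
    for treatment in config.treatments:
        # whole-plant dry weight anchored on the primary axis's mass ratio
        dw = specs[("primary", "dry_weight", treatment)].mean
        rmr = specs[("primary", "RMR", treatment)].mean
        pdw_mean = dw / rmr
        for i in range(1, config.n_per_treatment + 1):
            plant_id = f"P{treatment}{i}"
            pdw = _positive_normal(rng, pdw_mean, config.plant_dw_cv * pdw_mean)
            counts: dict[str, float] = {}
            type_rows = {}
            for rt in root_types:
                def draw(trait: str, default: float | None = None) -> float | None:
                    s = _spec_or_none(specs, rt, trait, treatment)
                    if s is None:
                        return default
                    return _positive_normal(rng, s.mean, s.sd)

                length = draw("length")
                dry = draw("dry_weight")
                fineness = draw("fineness")
                fresh = draw("fresh_weight", default=2.0 * dry)
                fresh = max(fresh, 1.05 * dry)  # DW <= FW constraint
                surface = draw("surface_area", default=np.nan)
                if rt in _AXES:
                    root_zone = draw("root_zone", default=0.0)
                    branching_zone = draw("branching_zone")
                    length = max(length, root_zone + branching_zone)
                else:
                    root_zone = np.nan
                    branching_zone = np.nan
                    s_num = _spec_or_none(specs, rt, "number", treatment)
                    counts[rt] = float(max(1, round(_positive_normal(rng, s_num.mean, s_num.sd)))) \
                        if s_num is not None else np.nan
                volume = length / fineness  # after the zone-length bump
                type_rows[rt] = [plant_id, treatment, rt, length, surface, volume,
                                 fresh, dry, np.nan, root_zone, branching_zone]
            # the axis's lateral count is its lateral class's number
            for axis, lat in _LATERAL_OF.items():
                if axis in type_rows and lat in counts:
                    type_rows[axis][8] = counts[lat]
                if lat in type_rows:
                    type_rows[lat][8] = counts.get(lat, np.nan)
            raw_rows.extend(type_rows[rt] for rt in root_types)

            root_dw = sum(type_rows[rt][7] for rt in root_types)
            root_fw = sum(type_rows[rt][6] for rt in root_types)
            pdw = max(pdw, 1.1 * root_dw)  # shoot mass must stay positive
            pfw = pdw / config.dry_matter_fraction
            plant_rows.append((plant_id, treatment, pfw - root_fw, pdw - root_dw))

    raw = pd.DataFrame(raw_rows, columns=RAW_COLUMNS)
    plants = pd.DataFrame(plant_rows, columns=PLANT_COLUMNS)
    traits = derive_dataset(raw, plants)
    return PlantDataset(traits=traits, raw=raw, plants=plants)
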
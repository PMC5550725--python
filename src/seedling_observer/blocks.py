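"""Measurement blocks and the per-seedling dataset container.

A greenhouse seedling trial produces, for every sampled seedling, one
environmental block E (8 climate parameters), four physiological blocks
P1..P4 (10 leaf gas-exchange / chlorophyll-fluorescence parameters measured
on days 0, 3, 6 and 9 of the treatment) and three growth blocks G1..G3
(per-day increments of plant height and leaf area for days 0-3, 4-6 and 7-9,
plus fresh and dry weight determined once at day 9 and shared by all three
growth blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENV_PARAMS: tuple[str, ...] = tuple(f"e{i}" for i in range(1, 9))
PHYSIO_PARAMS: tuple[str, ...] = tuple(f"p{i}" for i in range(1, 11))
GROWTH_PARAMS: tuple[str, ...] = ("g1", "g2", "g3", "g4")

#: Human-readable names for the short parameter ids.
ENV_NAMES = {
    "e1": "T_D", "e2": "T_N", "e3": "CO2", "e4": "RH",
    "e5": "AH", "e6": "PARo", "e7": "Ratio_W/B", "e8": "Ratio_W/R",
}
PHYSIO_NAMES = {
    "p1": "Pn", "p2": "Cond", "p3": "Ci", "p4": "Fv'/Fm'", "p5": "PhiPS2",
    "p6": "PhiCO2", "p7": "qP", "p8": "ETR", "p9": "Tr", "p10": "VpdL",
}
GROWTH_NAMES = {
    "g1": "Plant_Height", "g2": "Leaf_Area",
    "g3": "Fresh_Weight", "g4": "Dry_Weight",
}

ENV_UNITS = {
    "e1": "degC", "e2": "degC", "e3": "umol/mol", "e4": "%",
    "e5": "mmolH2O/mol", "e6": "umol/m2/s", "e7": "ratio", "e8": "ratio",
}
PHYSIO_UNITS = {
    "p1": "umolCO2/m2/s", "p2": "molH2O/m2/s", "p3": "umolCO2/mol",
    "p4": "[0,1]", "p5": "[0,1]", "p6": "[0,1]", "p7": "[0,1]",
    "p8": "umol/m2/s", "p9": "molH2O/m2/s", "p10": "kPa",
}
GROWTH_UNITS = {"g1": "cm/d", "g2": "cm2/d", "g3": "g/d", "g4": "g/d"}

#: Physiological parameters bounded to [0, 1] by definition.
BOUNDED_PHYSIO = ("p4", "p5", "p6", "p7")

#: Measurement day of each physiological block.
PHYSIO_STAGE_DAYS = {"P1": 0, "P2": 3, "P3": 6, "P4": 9}
#: Closing day of each growth stage (per-day increments over that stage).
GROWTH_STAGE_DAYS = {"G1": 3, "G2": 6, "G3": 9}

#: The growth block measured contemporaneously with each physiological block.
STAGE_PAIRING = {"G1": "P2", "G2": "P3", "G3": "P4"}


def physio_columns(block: str) -> list[str]:
    """CSV column names of a physiological block, e.g. P2 -> p1_d3..p10_d3."""
    day = PHYSIO_STAGE_DAYS[block]
    return [f"{p}_d{day}" for p in PHYSIO_PARAMS]


def growth_columns(block: str) -> list[str]:
    """CSV column names of a growth block; g3/g4 are single day-9 columns."""
    day = GROWTH_STAGE_DAYS[block]
    return [f"g1_d{day}", f"g2_d{day}", "g3", "g4"]


#: Full flat-CSV schema, in order.
SCHEMA_COLUMNS: tuple[str, ...] = (
    ("sample_id", "trial_id")
    + ENV_PARAMS
    + tuple(c for b in ("P1", "P2", "P3", "P4") for c in physio_columns(b))
    + ("g1_d3", "g2_d3", "g1_d6", "g2_d6", "g1_d9", "g2_d9", "g3", "g4")
)

BLOCK_NAMES = ("E", "P1", "P2", "P3", "P4", "G1", "G2", "G3")


class DimensionError(ValueError):
    """Incompatible shapes between blocks or matrices."""


class DegenerateInputError(ValueError):
    """A measurement column is constant or otherwise unusable."""


@dataclass
class MeasurementBlock:
    """A named sample-by-parameter matrix of measurements.

    Parameters are identified by the short ids used throughout the package
    (``e1..e8``, ``p1..p10``, ``g1..g4``); ``values`` has one column per id.
    """

    name: str
    parameter_ids: tuple[str, ...]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parameter_ids = tuple(self.parameter_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(f"block {self.name!r}: values must be 2-D")
        if self.values.shape[1] != len(self.parameter_ids):
            raise DimensionError(
                f"block {self.name!r}: {self.values.shape[1]} columns but "
                f"{len(self.parameter_ids)} parameter ids"
            )
        if self.values.shape[0] < 2:
            raise DimensionError(f"block {self.name!r}: need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            bad = [
                pid for j, pid in enumerate(self.parameter_ids)
                if not np.all(np.isfinite(self.values[:, j]))
            ]
            raise DegenerateInputError(
                f"block {self.name!r}: non-finite values in {bad}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def column(self, parameter_id: str) -> np.ndarray:
        return self.values[:, self.parameter_ids.index(parameter_id)]


@dataclass
class SeedlingDataset:
    """A full trial dataset backed by a flat data frame in schema order.

    ``ground_truth`` optionally carries generator metadata (effect maps,
    declared null parameters, seed) when the dataset is synthetic.
    """

    frame: pd.DataFrame
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DimensionError(f"dataset missing columns: {missing}")
        self.frame = self.frame.loc[:, list(SCHEMA_COLUMNS)].reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def trial_ids(self) -> np.ndarray:
        return self.frame["trial_id"].to_numpy()

    def block(self, name: str) -> MeasurementBlock:
        """Extract a measurement block (E, P1..P4, G1..G3) by name."""
        if name == "E":
            cols, ids, units = list(ENV_PARAMS), ENV_PARAMS, ENV_UNITS
        elif name in PHYSIO_STAGE_DAYS:
            cols, ids, units = physio_columns(name), PHYSIO_PARAMS, PHYSIO_UNITS
        elif name in GROWTH_STAGE_DAYS:
            cols, ids, units = growth_columns(name), GROWTH_PARAMS, GROWTH_UNITS
        else:
            raise KeyError(f"unknown block {name!r}; expected one of {BLOCK_NAMES}")
        return MeasurementBlock(
            name=name,
            parameter_ids=ids,
            values=self.frame[cols].to_numpy(dtype=float),
            units=dict(units),
        )
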
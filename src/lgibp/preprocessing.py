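"""Battery loading, score-direction conventions, outlier masking, z-scoring.

Missingness is carried as an explicit boolean mask (True = observed); masked
cells never hold meaningful values and never contribute to any statistic.
The preprocessing order is: direction conventions, then the finger-tapping
tap-count filter, then column z-scoring, so that filtered outliers cannot
contaminate column means and SDs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FINGER_TAPPING_ID, MeasureSchema

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A data file does not match the measure schema."""


class ParseError(ValueError):
    """A non-empty cell could not be parsed as a number."""


class DegenerateColumnError(ValueError):
    """A column has zero variance over its observed cells."""


class InsufficientDataError(ValueError):
    """A column has fewer than two observed cells."""


@dataclass(frozen=True)
class RawBattery:
    """Participants x measures raw scores with a missingness mask.

    ``values[i, d]`` is meaningful only where ``mask[i, d]`` is True.
    Column order always follows the schema.
    """

    participant_ids: tuple
    values: np.ndarray
    mask: np.ndarray
    schema: MeasureSchema

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != len(self.schema):
            raise ValueError(
                f"battery has {self.values.shape[1]} columns, schema has "
                f"{len(self.schema)} measures")
        if len(self.participant_ids) != self.values.shape[0]:
            raise ValueError("participant_ids length does not match rows")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_measures(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schema.measure_ids,
                          index=pd.Index(self.participant_ids,
                                         name="participant_id"))
        return df.mask(~self.mask)


@dataclass(frozen=True)
class StandardizedBattery:
    """z-scored battery: per column, observed cells have mean 0 and SD 1.

    ``column_means`` / ``column_sds`` record the raw-scale statistics used,
    for audit and for mapping new data onto the same scale.
    """

    participant_ids: tuple
    values: np.ndarray
    mask: np.ndarray
    schema: MeasureSchema
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_measures(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schema.measure_ids,
                          index=pd.Index(self.participant_ids,
                                         name="participant_id"))
        return df.mask(~self.mask)

    def write_csv(self, path, audit_path=None) -> None:
        """Write z-scores as CSV, optionally with a JSON sidecar of the
        column means/SDs used."""
        self.to_dataframe().to_csv(path)
        if audit_path is not None:
            audit = {
                m: {"mean": float(mu), "sd": float(sd)}
                for m, mu, sd in zip(self.schema.measure_ids,
                                     self.column_means, self.column_sds)
            }
            Path(audit_path).write_text(json.dumps(audit, indent=2))


def load_battery(path, schema: MeasureSchema,
                 id_column: str = "participant_id") -> RawBattery:
    """Read a delimited battery file into a :class:`RawBattery`.

    The file must have a participant-id column and one column per schema
    measure; empty cells mean missing.  Column order in the file is
    irrelevant — the result follows schema order.  ``.tsv`` files are read
    tab-delimited, anything else comma-delimited.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise SchemaError(f"missing participant-id column {id_column!r}")
    missing = [m for m in schema.measure_ids if m not in df.columns]
    if missing:
        raise SchemaError(f"file is missing schema measure(s): {missing}")

    n, d = len(df), len(schema)
    values = np.zeros((n, d))
    mask = np.zeros((n, d), dtype=bool)
    for j, mid in enumerate(schema.measure_ids):
        col = df[mid].str.strip()
        for i, cell in enumerate(col):
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i + 1}, "
                    f"column {mid!r}") from exc
            mask[i, j] = True
    return RawBattery(tuple(df[id_column]), values, mask, schema)


def apply_direction_conventions(b: RawBattery) -> RawBattery:
    """Negate reverse-scored columns so higher always means better.

    An involution: applying it twice returns the original battery.
    """
    values = b.values.copy()
    for mid in b.schema.reverse_scored_ids:
        j = b.schema.index_of(mid)
        values[:, j] = -values[:, j]
    return replace(b, values=values)


def finger_tapping_filter(b: RawBattery, low: float = 10.0,
                          high: float = 151.0,
                          measure_id: str = FINGER_TAPPING_ID) -> RawBattery:
    """Mask implausible finger-tapping counts (< ``low`` or > ``high``).

    Boundary values are retained.  Such counts typically reflect technical
    recording issues rather than performance.  The number of newly masked
    cells is logged.
    """
    if measure_id not in b.schema.measure_ids:
        return b
    j = b.schema.index_of(measure_id)
    mask = b.mask.copy()
    col, obs = b.values[:, j], b.mask[:, j]
    bad = obs & ((col < low) | (col > high))
    mask[bad, j] = False
    if bad.any():
        logger.info("finger_tapping_filter: masked %d implausible tap "
                    "count(s)", int(bad.sum()))
    return replace(b, mask=mask)


def zscore_columns(b: RawBattery) -> StandardizedBattery:
    """Standardize each column over its observed cells (sample SD, n-1).

    Raises :class:`InsufficientDataError` for columns with fewer than two
    observed cells and :class:`DegenerateColumnError` for zero variance.
    """
    values = b.values.copy()
    means = np.zeros(b.n_measures)
    sds = np.zeros(b.n_measures)
    for j, mid in enumerate(b.schema.measure_ids):
        obs = b.mask[:, j]
        n_obs = int(obs.sum())
        if n_obs < 2:
            raise InsufficientDataError(
                f"measure {mid!r} has {n_obs} observed value(s); "
                "need at least 2 to standardize")
        col = b.values[obs, j]
        mu, sd = col.mean(), col.std(ddof=1)
        if sd == 0:
            raise DegenerateColumnError(
                f"measure {mid!r} has zero variance over observed cells")
        means[j], sds[j] = mu, sd
        values[obs, j] = (col - mu) / sd
        values[~obs, j] = 0.0  # placeholder; masked cells carry no information
    return StandardizedBattery(b.participant_ids, values, b.mask.copy(),
                               b.schema, means, sds)


def standardize_battery(b: RawBattery, tap_low: float = 10.0,
                        tap_high: float = 151.0) -> StandardizedBattery:
    """Full preprocessing pipeline: directions -> tap filter -> z-score."""
    return zscore_columns(
        finger_tapping_filter(apply_direction_conventions(b),
                              low=tap_low, high=tap_high))
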
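"""CSV/JSON schemas and the crop data container.

All tabular interchange uses plain CSV with fixed column names; lengths are
in mm (one decimal on output, matching ruler resolution), times in °Cd since
bud break.  Schemas:

* lengths:    ``plant_id,kind,absolute_rank,t_cd,length_mm``
* appearance: ``plant_id,relative_rank,t_first_seen_cd``
* metadata:   ``plant_id,n_phytomers`` (optionally ``budbreak_date``)
* predictions: ``plant_id,kind,relative_rank,t_cd,length_pred_mm``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .logistic import OrganSeries
from .topology import relative_rank

__all__ = ["SchemaError", "Crop", "read_lengths", "read_appearance",
           "read_metadata", "write_lengths", "write_appearance",
           "write_metadata", "write_predictions"]

LENGTHS_COLS = ["plant_id", "kind", "absolute_rank", "t_cd", "length_mm"]
APPEARANCE_COLS = ["plant_id", "relative_rank", "t_first_seen_cd"]
METADATA_COLS = ["plant_id", "n_phytomers"]


class SchemaError(ValueError):
    """Input table does not conform to the documented schema."""


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV missing column(s): {', '.join(missing)}")


def read_lengths(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, LENGTHS_COLS, "lengths")
    bad = ~df["kind"].isin(["lea", "int"])
    if bad.any():
        raise SchemaError(f"lengths CSV: unknown kind at row {int(np.nonzero(bad.to_numpy())[0][0]) + 2}")
    df["plant_id"] = df["plant_id"].astype(str)
    return df


def read_appearance(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, APPEARANCE_COLS, "appearance")
    df["plant_id"] = df["plant_id"].astype(str)
    return df


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, METADATA_COLS, "metadata")
    df["plant_id"] = df["plant_id"].astype(str)
    return df


def _round_col(df: pd.DataFrame, col: str, ndigits: int = 1) -> pd.DataFrame:
    out = df.copy()
    out[col] = out[col].astype(float).round(ndigits)
    return out


def write_lengths(df: pd.DataFrame, path) -> None:
    _check_columns(df, LENGTHS_COLS, "lengths")
    _round_col(_round_col(df[LENGTHS_COLS], "length_mm"), "t_cd").to_csv(path, index=False)


def write_appearance(df: pd.DataFrame, path) -> None:
    _check_columns(df, APPEARANCE_COLS, "appearance")
    _round_col(df[APPEARANCE_COLS], "t_first_seen_cd").to_csv(path, index=False)


def write_metadata(df: pd.DataFrame, path) -> None:
    _check_columns(df, METADATA_COLS, "metadata")
    df.to_csv(path, index=False)


def write_predictions(df: pd.DataFrame, path) -> None:
    _check_columns(df, ["plant_id", "kind", "relative_rank", "t_cd", "length_pred_mm"],
                   "predictions")
    _round_col(_round_col(df, "length_pred_mm"), "t_cd").to_csv(path, index=False)


@dataclass
class Crop:
    """A crop of measured plants: long length table + appearance + metadata."""

    lengths: pd.DataFrame
    appearance: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_columns(self.lengths, LENGTHS_COLS, "lengths")
        _check_columns(self.appearance, APPEARANCE_COLS, "appearance")
        _check_columns(self.metadata, METADATA_COLS, "metadata")

    @property
    def plant_ids(self):
        return list(self.metadata["plant_id"])

    def n_phytomers(self, plant_id: str) -> int:
        row = self.metadata[self.metadata["plant_id"] == plant_id]
        if row.empty:
            raise KeyError(f"unknown plant {plant_id!r}")
        return int(row["n_phytomers"].iloc[0])

    def organ_series(self, plant_id: Optional[str] = None):
        """Iterate OrganSeries for every (plant, kind, rank) in the length table."""
        df = self.lengths
        if plant_id is not None:
            df = df[df["plant_id"] == plant_id]
        for (pid, kind, rank), grp in df.groupby(["plant_id", "kind", "absolute_rank"],
                                                 sort=True):
            grp = grp.sort_values("t_cd")
            i = relative_rank(int(rank), self.n_phytomers(pid))
            yield OrganSeries(plant_id=pid, kind=kind, relative_rank=i,
                              t=grp["t_cd"].to_numpy(),
                              length=grp["length_mm"].to_numpy())

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_lengths(self.lengths, directory / "lengths.csv")
        write_appearance(self.appearance, directory / "appearance.csv")
        write_metadata(self.metadata, directory / "metadata.csv")

    @classmethod
    def load(cls, directory) -> "Crop":
        directory = Path(directory)
        return cls(lengths=read_lengths(directory / "lengths.csv"),
                   appearance=read_appearance(directory / "appearance.csv"),
                   metadata=read_metadata(directory / "metadata.csv"))
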
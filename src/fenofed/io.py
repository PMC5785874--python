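"""Dataset container and NONMEM-style delimited text IO.

Dialect (one header row, comma- or whitespace-delimited):

======  =====================================================
column  meaning
======  =====================================================
ID      subject identifier (integer)
TIME    time within the occasion, h
AMT     dose amount, mg (0 on observation rows)
DV      observed fenofibric acid concentration, ug/mL
EVID    1 = dose event, 0 = observation
MDV     1 = DV missing/ignored (dose rows, pre-dose zeros)
OCC     occasion (crossover period) index, 1-based
FOOD    food type code: 0 fasted, 1 standard, 2 high fat
CAL     meal calories, kcal, carried on the dose row
======  =====================================================

Meals are encoded on dose rows (``CAL > 0``): the meal is taken at the dose
time (the 10-minute offset between meal and capsule is negligible against a
16 h gastric-emptying half-life).  Unknown extra columns are preserved as
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .events import DoseEvent, EventSchedule, FoodType, MealEvent

__all__ = ["REQUIRED_COLUMNS", "PKDataset", "OccasionData",
           "read_dataset", "write_dataset"]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV", "OCC",
                    "FOOD", "CAL")


@dataclass
class OccasionData:
    """One subject-occasion ready for simulation/estimation."""

    subject: int
    occasion: int
    food_type: FoodType
    schedule: EventSchedule
    t_obs: np.ndarray      # observation times with MDV == 0
    y: np.ndarray          # observed concentrations


class PKDataset:
    """Tidy event/observation records of a PK study.

    Thin validated wrapper around a :class:`pandas.DataFrame` with the
    column dialect above.  Iteration yields per-subject lists of
    :class:`OccasionData`.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        df = frame.copy()
        for col in ("ID", "EVID", "MDV", "OCC", "FOOD"):
            df[col] = df[col].astype(int)
        for col in ("TIME", "AMT", "DV", "CAL"):
            df[col] = df[col].astype(float)
        self._validate(df)
        self.frame = df.reset_index(drop=True)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad = df.index[(df["EVID"] == 0) & (df["MDV"] == 0) & (df["DV"] < 0)]
        if len(bad):
            raise ValueError(
                f"negative DV on observation rows {list(bad + 1)}")
        bad = df.index[(df["EVID"] == 1) & (df["MDV"] == 0)]
        if len(bad):
            raise ValueError(
                f"dose rows must not carry a DV (MDV must be 1); "
                f"rows {list(bad + 1)}")
        bad = df.index[~df["FOOD"].isin([int(f) for f in FoodType])]
        if len(bad):
            raise ValueError(f"unknown FOOD codes on rows {list(bad + 1)}")
        if (df["TIME"] < 0).any():
            bad = df.index[df["TIME"] < 0]
            raise ValueError(f"negative TIME on rows {list(bad + 1)}")
        for (sid, occ), g in df.groupby(["ID", "OCC"]):
            t = g["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                row = g.index[np.argmax(np.diff(t) < 0) + 1] + 1
                raise ValueError(
                    f"times not sorted within subject {sid} occasion {occ} "
                    f"(first offending row {row})")

    # ------------------------------------------------------------------
    @property
    def subjects(self) -> list[int]:
        return sorted(self.frame["ID"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        f = self.frame
        return int(((f["EVID"] == 0) & (f["MDV"] == 0)).sum())

    def occasions(self, subject: int) -> list[OccasionData]:
        g = self.frame[self.frame["ID"] == subject]
        out = []
        for occ, go in g.groupby("OCC"):
            doses = go[go["EVID"] == 1]
            food = FoodType(int(doses["FOOD"].max()) if len(doses)
                            else int(go["FOOD"].max()))
            dose_events = tuple(
                DoseEvent(r.TIME, r.AMT) for r in doses.itertuples()
                if r.AMT > 0)
            meal_events = tuple(
                MealEvent(r.TIME, r.CAL, FoodType(int(r.FOOD)))
                for r in doses.itertuples() if r.CAL > 0)
            obs = go[(go["EVID"] == 0) & (go["MDV"] == 0)]
            out.append(OccasionData(
                subject=int(subject), occasion=int(occ), food_type=food,
                schedule=EventSchedule(dose_events, meal_events),
                t_obs=obs["TIME"].to_numpy(),
                y=obs["DV"].to_numpy(),
            ))
        return out

    def iter_subjects(self) -> Iterator[tuple[int, list[OccasionData]]]:
        for sid in self.subjects:
            yield sid, self.occasions(sid)

    def subset(self, subjects) -> "PKDataset":
        """New dataset restricted to the given subjects (order preserved)."""
        frames = [self.frame[self.frame["ID"] == s] for s in subjects]
        if not frames:
            raise ValueError("subset would be empty")
        return PKDataset(pd.concat(frames, ignore_index=True))

    def __len__(self) -> int:
        return len(self.frame)


def read_dataset(path: str | Path) -> PKDataset:
    """Read a delimited dataset file (comma separated, '#' comments)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {', '.join(missing)}")
    return PKDataset(df)


def write_dataset(dataset: PKDataset, path: str | Path) -> None:
    """Write the dataset back as comma-separated text (lossless round trip)."""
    dataset.frame.to_csv(path, index=False)
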
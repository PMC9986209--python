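"""Mapping irregular EMA prompts onto an equidistant time grid.

The dynamic model needs observations at (approximately) equal 4-hour
intervals.  Records are assigned to absolute bins of width ``delta``
anchored at a fixed clock hour on the first study day; bins without a
record become explicit missing slots (including the overnight stretch),
so that the lag-1 structure of the model refers to a constant interval.

Collision handling (two records falling in one bin) is configurable.  The
default, ``"shift"``, pushes the later record into the next free bin — the
"forced to be approximately equidistant" convention under which every
answered prompt keeps a slot of its own.  Alternatives: ``"earlier"`` /
``"latest"`` keep one record and drop the rest, ``"mean"`` averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import MINUTES_PER_DAY, shift_assign

__all__ = [
    "AlignedSeries",
    "TimeGridder",
    "build_grid",
    "align_dataset",
    "missingness_fraction",
    "compliance_fraction",
]

logger = logging.getLogger(__name__)

_VALUE_COLS = ("stress_sum", "affect_sum")


@dataclass
class AlignedSeries:
    """One person's (stress, affect) series on the equidistant grid.

    ``values`` is ``(n_slots, 2)`` with ``NaN`` marking missing slots;
    slot ``k`` covers ``[origin + k*delta, origin + (k+1)*delta)`` minutes.
    """

    person_id: object
    values: np.ndarray
    origin: float
    delta: float = 240.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be (n_slots, 2)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not np.isfinite(self.values).any():
            raise ValueError("aligned series needs at least one observed cell")

    @property
    def n_slots(self) -> int:
        return self.values.shape[0]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values).any(axis=1)

    def slot_time(self, k: int) -> float:
        """Minutes-from-study-start of the left edge of slot ``k``."""
        return self.origin + k * self.delta


def _assign_bins(t: np.ndarray, origin: float, delta: float, policy: str):
    """Assign sorted record times to bins under the collision policy.

    Returns (bins, keep_mask, groups) where ``groups`` maps each kept bin to
    the record indices averaged into it (only used for the mean policy).
    """
    raw = np.floor((t - origin) / delta).astype(np.int64)
    if policy == "shift":
        return shift_assign(raw), np.ones(t.size, dtype=bool), None
    if policy in ("earlier", "latest"):
        keep = np.ones(t.size, dtype=bool)
        seen: dict[int, int] = {}
        for i, b in enumerate(raw):
            if b in seen:
                drop = i if policy == "earlier" else seen[b]
                keep[drop] = False
                if policy == "latest":
                    seen[b] = i
                logger.info("collision in bin %d: dropping record %d", b, drop)
            else:
                seen[b] = i
        return raw[keep], keep, None
    if policy == "mean":
        uniq, inv = np.unique(raw, return_inverse=True)
        groups = [np.flatnonzero(inv == g) for g in range(uniq.size)]
        return uniq, None, groups
    raise ValueError(f"unknown collision policy {policy!r}")


def build_grid(
    records: pd.DataFrame,
    delta: float = 240.0,
    origin: float | None = None,
    origin_hour: float = 10.0,
    collision: str = "shift",
    value_cols: Sequence[str] = _VALUE_COLS,
) -> AlignedSeries:
    """Grid one person's records onto equidistant slots.

    ``records`` needs ``t_minutes`` plus the two score columns.  The grid
    origin defaults to ``origin_hour`` o'clock on the day of the earliest
    record (kept identical across persons when all started the same day).
    """
    if len(records) == 0:
        raise ValueError("cannot grid an empty record set")
    if delta <= 0:
        raise ValueError("delta must be positive")
    rec = records.sort_values("t_minutes", kind="stable")
    t = rec["t_minutes"].to_numpy(dtype=float)
    vals = rec.loc[:, list(value_cols)].to_numpy(dtype=float)

    if origin is None:
        origin = np.floor(t[0] / MINUTES_PER_DAY) * MINUTES_PER_DAY + origin_hour * 60.0
        if origin > t[0]:
            origin -= delta * np.ceil((origin - t[0]) / delta)

    bins, keep, groups = _assign_bins(t, origin, delta, collision)
    n_slots = int(max(bins.max(), np.floor((t[-1] - origin) / delta))) + 1
    grid = np.full((n_slots, 2), np.nan)
    if groups is None:
        grid[bins] = vals[keep]
    else:
        for b, idx in zip(bins, groups):
            grid[b] = vals[idx].mean(axis=0)

    pid = records["person_id"].iloc[0] if "person_id" in records else None
    return AlignedSeries(person_id=pid, values=grid, origin=float(origin), delta=float(delta))


def align_dataset(
    ema: pd.DataFrame,
    delta: float = 240.0,
    origin_hour: float = 10.0,
    collision: str = "shift",
) -> list[AlignedSeries]:
    """Grid every person of a long-format EMA table (sorted by person id).

    The grid origin is shared: ``origin_hour`` o'clock on the first study
    day observed anywhere in the table, so day structure stays aligned
    across persons (a person whose first answered prompt comes later
    simply starts with missing slots).
    """
    t0 = ema["t_minutes"].min()
    day0 = np.floor(t0 / MINUTES_PER_DAY) * MINUTES_PER_DAY
    origin = day0 + origin_hour * 60.0
    if origin > t0:
        origin -= delta * np.ceil((origin - t0) / delta)
    out = []
    for pid, grp in ema.groupby("person_id", sort=True):
        out.append(build_grid(grp, delta=delta, origin=origin, collision=collision))
    return out


def missingness_fraction(series: Iterable[AlignedSeries]) -> float:
    """Pooled fraction of missing cells across persons."""
    series = list(series)
    if not series:
        raise ValueError("no aligned series given")
    miss = sum(int(s.missing.sum()) for s in series)
    total = sum(s.n_slots for s in series)
    return miss / total


def compliance_fraction(schedule: pd.DataFrame) -> float:
    """Answered prompts / issued prompts."""
    if len(schedule) == 0:
        raise ValueError("schedule contains no prompts")
    return float(schedule["answered"].mean())


class TimeGridder(BaseEstimator, TransformerMixin):
    """Transformer from long EMA records to aligned equidistant series.

    Parameters
    ----------
    delta : grid spacing in minutes (default 240 = 4 hours).
    origin_hour : clock hour anchoring slot 0 on the first study day.
    collision : "shift" (default), "earlier", "latest" or "mean".
    """

    def __init__(self, delta: float = 240.0, origin_hour: float = 10.0,
                 collision: str = "shift"):
        self.delta = delta
        self.origin_hour = origin_hour
        self.collision = collision

    def fit(self, X: pd.DataFrame, y=None):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        self.n_persons_ = X["person_id"].nunique()
        return self

    def transform(self, X: pd.DataFrame) -> list[AlignedSeries]:
        series = align_dataset(
            X, delta=self.delta, origin_hour=self.origin_hour, collision=self.collision
        )
        self.missingness_ = missingness_fraction(series)
        return series

    def report(self, series: list[AlignedSeries]) -> dict:
        """JSON-serialisable missingness report."""
        per_person = {
            str(s.person_id): {
                "n_slots": int(s.n_slots),
                "n_missing": int(s.missing.sum()),
            }
            for s in series
        }
        return {
            "delta_minutes": self.delta,
            "collision_policy": self.collision,
            "pooled_missingness": missingness_fraction(series),
            "persons": per_person,
        }


def to_wide(series: list[AlignedSeries]) -> pd.DataFrame:
    """One row per person-slot, for CSV export."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "person_id": s.person_id,
                    "slot": np.arange(s.n_slots),
                    "t_minutes": s.origin + np.arange(s.n_slots) * s.delta,
                    "stress": s.values[:, 0],
                    "affect": s.values[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
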
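"""Expression profiles: reading, replicate averaging, actin normalization and
monotone interpolation onto the common time grid.

Raw recordings are sparse in time (miRNAs on days 0/1/3/6, mRNAs on 0/3/6,
proteins on 0/1.5/3/6).  Replicates are averaged per day, Western-blot protein
intensities are divided by their lane's actin control, and every molecule is
brought onto a shared 19-point grid over the 6-day differentiation course by
shape-preserving PCHIP interpolation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import (
    AlignmentError,
    ExtrapolationError,
    InsufficientDataError,
    InvalidControlError,
    MissingDataError,
    TableParseError,
)

__all__ = [
    "Kind",
    "Condition",
    "TimeGrid",
    "RawRecording",
    "Profile",
    "ProfileKey",
    "average_replicates",
    "normalize_by_actin",
    "interpolate_profile",
    "build_profiles",
    "read_expression_table",
    "write_expression_table",
    "write_profiles",
    "read_profiles",
]


class Kind(str, enum.Enum):
    MIRNA = "miRNA"
    MRNA = "mRNA"
    PROTEIN = "protein"


class Condition(str, enum.Enum):
    WT = "WT"
    KO = "KO"


@dataclass(frozen=True)
class TimeGrid:
    """The shared interpolation grid: 19 points, t = 0, 1/3, ..., 6 days."""

    points: tuple[float, ...] = tuple(np.linspace(0.0, 6.0, 19))

    def __post_init__(self):
        pts = np.asarray(self.points)
        if len(pts) != 19 or pts[0] != 0.0 or pts[-1] != 6.0:
            raise ValueError("time grid must hold 19 points spanning [0, 6]")
        if not np.allclose(np.diff(pts), 1.0 / 3.0):
            raise ValueError("time grid spacing must be 1/3 day")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RawRecording:
    """One replicate measurement of one molecule on one day."""

    molecule_id: str
    kind: Kind
    condition: Condition
    day: float
    replicate: int
    value: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"negative intensity for {self.molecule_id}")
        if not 0.0 <= self.day <= 6.0:
            raise ValueError(f"day {self.day} outside [0, 6]")
        if self.replicate < 1:
            raise ValueError("replicate index must be positive")


@dataclass(frozen=True)
class Profile:
    """One molecule's expression on the 19-point grid for one condition."""

    molecule_id: str
    kind: Kind
    condition: Condition
    values: tuple[float, ...]
    knot_days: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if len(self.values) != 19:
            raise ValueError("profile must hold 19 values")
        if any(v < 0 for v in self.values):
            raise ValueError("profile values must be nonnegative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values)


def average_replicates(
    recordings: Iterable[RawRecording],
) -> dict[tuple[str, Condition, float], float]:
    """Arithmetic mean of replicate values per (molecule, condition, day).

    Missing replicates are simply absent from the mean; no outlier rejection.
    """
    sums: dict[tuple[str, Condition, float], list[float]] = {}
    for rec in recordings:
        sums.setdefault((rec.molecule_id, rec.condition, rec.day), []).append(rec.value)
    if not sums:
        raise MissingDataError("no recordings supplied")
    return {key: float(np.mean(vals)) for key, vals in sums.items()}


def normalize_by_actin(intensity: float, actin: float) -> float:
    """Divide a Western-blot intensity by its lane's actin loading control."""
    if actin <= 0:
        raise InvalidControlError(f"actin intensity must be positive, got {actin}")
    if intensity < 0:
        raise ValueError("intensity must be nonnegative")
    return intensity / actin


def interpolate_profile(
    knot_days: Sequence[float],
    knot_values: Sequence[float],
    grid: TimeGrid | None = None,
) -> np.ndarray:
    """Evaluate the monotone-preserving PCHIP interpolant on the 19-point grid.

    The interpolant reproduces the knot values exactly and, between two knots,
    never leaves the closed interval spanned by those knot values.
    """
    grid = grid or TimeGrid()
    days = np.asarray(knot_days, dtype=float)
    vals = np.asarray(knot_values, dtype=float)
    if len(days) < 2:
        raise InsufficientDataError("at least 2 knots are required")
    if np.any(np.diff(days) <= 0):
        raise ValueError("knot days must be strictly increasing")
    if np.any(vals < 0):
        raise ValueError("knot values must be nonnegative")
    if days[0] > grid.points[0] or days[-1] < grid.points[-1]:
        raise ExtrapolationError(
            f"knot days [{days[0]}, {days[-1]}] do not cover [0, 6]; "
            "no extrapolation is performed"
        )
    out = PchipInterpolator(days, vals)(grid.array)
    # PCHIP is shape preserving; clip only latent -0.0 round-off
    return np.maximum(out, 0.0)


#: profiles are keyed by (molecule_id, kind, condition): a gene's mRNA and
#: its protein conventionally share the molecule name
ProfileKey = tuple[str, Kind, Condition]


def build_profiles(
    recordings: Iterable[RawRecording],
    grid: TimeGrid | None = None,
    actin_id: str | None = "actin",
) -> dict[ProfileKey, Profile]:
    """Average replicates, actin-normalize proteins, interpolate to the grid.

    Knot days are inferred per (molecule, kind, condition) from the data
    rather than hard-coded, so miRNA/mRNA/protein designs with different day
    grids are handled uniformly.  If ``actin_id`` names a recorded protein,
    every other protein replicate is divided by the actin value of the
    matching (condition, day, replicate) lane before averaging.
    """
    grid = grid or TimeGrid()
    recordings = list(recordings)
    actin: dict[tuple[Condition, float, int], float] = {}
    if actin_id is not None:
        for rec in recordings:
            if rec.kind is Kind.PROTEIN and rec.molecule_id == actin_id:
                actin[(rec.condition, rec.day, rec.replicate)] = rec.value

    groups: dict[ProfileKey, dict[float, list[float]]] = {}
    for rec in recordings:
        value = rec.value
        if rec.kind is Kind.PROTEIN:
            if rec.molecule_id == actin_id:
                continue
            if actin:
                lane = (rec.condition, rec.day, rec.replicate)
                if lane not in actin:
                    raise MissingDataError(f"no actin lane for {rec.molecule_id} at {lane}")
                value = normalize_by_actin(rec.value, actin[lane])
        key = (rec.molecule_id, rec.kind, rec.condition)
        groups.setdefault(key, {}).setdefault(rec.day, []).append(value)

    if not groups:
        raise MissingDataError("no recordings supplied")

    profiles: dict[ProfileKey, Profile] = {}
    for key, day_map in sorted(groups.items()):
        mid, kind, cond = key
        days = sorted(day_map)
        vals = [float(np.mean(day_map[d])) for d in days]
        # a knocked-out molecule recorded as identically zero needs no interpolant
        if all(v == 0 for v in vals):
            interp = np.zeros(len(grid))
        else:
            interp = interpolate_profile(days, vals, grid)
        profiles[key] = Profile(
            molecule_id=mid,
            kind=kind,
            condition=cond,
            values=tuple(float(v) for v in interp),
            knot_days=tuple(days),
        )
    return profiles


_COLUMNS = ["molecule_id", "kind", "condition", "day", "replicate", "value"]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_table(path: str | Path) -> list[RawRecording]:
    """Parse a delimited long-format expression table into raw recordings.

    Delimiter is inferred from the extension (.csv comma, otherwise tab).
    Malformed rows raise :class:`TableParseError` with the 1-based data line.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                RawRecording(
                    molecule_id=str(row.molecule_id),
                    kind=Kind(str(row.kind)),
                    condition=Condition(str(row.condition)),
                    day=float(row.day),
                    replicate=int(row.replicate),
                    value=float(row.value),
                )
            )
        except (ValueError, KeyError) as exc:
            raise TableParseError(str(exc), line=i) from exc
    return out


def write_expression_table(recordings: Iterable[RawRecording], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.molecule_id, r.kind.value, r.condition.value, r.day, r.replicate, r.value)
            for r in recordings
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_profiles(profiles: Mapping[ProfileKey, Profile], path: str | Path) -> None:
    """Write profiles as a wide table, one column per grid point (t0..t18)."""
    rows = []
    for (mid, kind, cond), prof in sorted(profiles.items()):
        row = {"molecule_id": mid, "kind": kind.value, "condition": cond.value}
        row.update({f"t{i}": v for i, v in enumerate(prof.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_profiles(path: str | Path) -> dict[ProfileKey, Profile]:
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = [f"t{i}" for i in range(19)]
    if any(c not in df.columns for c in cols):
        raise TableParseError("profile table must carry columns t0..t18")
    out = {}
    for row in df.itertuples(index=False):
        cond = Condition(str(row.condition))
        kind = Kind(str(row.kind))
        out[(str(row.molecule_id), kind, cond)] = Profile(
            molecule_id=str(row.molecule_id),
            kind=kind,
            condition=cond,
            values=tuple(float(getattr(row, c)) for c in cols),
        )
    return out


def require_aligned(a: Profile | Sequence[float], b: Profile | Sequence[float]) -> None:
    la = len(a.values) if isinstance(a, Profile) else len(a)
    lb = len(b.values) if isinstance(b, Profile) else len(b)
    if la != lb:
        raise AlignmentError(f"profiles of length {la} and {lb} are not aligned")
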
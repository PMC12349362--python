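"""Rugosity index (RI) computation on epidermal contour polylines.

The rugosity index quantifies how much longer the outer epidermal contour of a
fruit cross-section is than the straight section it was cut from:

    RI (%) = (epidermal length - section length) / section length * 100

A perfectly flat epidermis gives RI = 0; ridges and depressions inflate the
traced contour length and hence the index.  Fruits are graded into four
rugosity levels from the mean RI of (by default) four slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidContourError,
    InvalidParameterError,
    MeasurementWarning,
)

__all__ = [
    "Contour",
    "LevelScheme",
    "DEFAULT_LEVEL_SCHEME",
    "SliceMeasurement",
    "FruitRugosity",
    "polyline_length",
    "rugosity_index",
    "slice_ri",
    "fruit_ri",
    "classify_level",
]

#: relative tolerance below which epidermal < section is treated as numerical
#: noise rather than a tracing error worth warning about
_SHRINK_TOL = 1e-9


@dataclass(frozen=True)
class Contour:
    """An ordered open polyline of 2-D points in millimetres.

    Point order is preserved exactly as given; no sorting or deduplication is
    applied, mirroring a traced polyline.
    """

    xy: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.xy, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidContourError(
                f"contour must be an (n, 2) array of points, got shape {arr.shape}"
            )
        if arr.shape[0] < 2:
            raise InvalidContourError("contour needs at least two points")
        if not np.all(np.isfinite(arr)):
            raise InvalidContourError("contour contains non-finite coordinates")
        if np.all(arr == arr[0]):
            raise InvalidContourError("contour needs at least two distinct points")
        object.__setattr__(self, "xy", arr)

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def __len__(self) -> int:
        return self.xy.shape[0]

    @classmethod
    def from_points(cls, x: Iterable[float], y: Iterable[float]) -> "Contour":
        return cls(np.column_stack([np.asarray(x, float), np.asarray(y, float)]))

    @classmethod
    def from_csv(cls, path) -> "Contour":
        """Read a contour from a ``x_mm,y_mm`` CSV (one ordered point per row)."""
        df = pd.read_csv(path)
        if not {"x_mm", "y_mm"}.issubset(df.columns):
            raise InvalidContourError(
                f"contour CSV must have columns x_mm,y_mm; got {list(df.columns)}"
            )
        return cls.from_points(df["x_mm"].to_numpy(), df["y_mm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"x_mm": self.x, "y_mm": self.y}).to_csv(path, index=False)


@dataclass(frozen=True)
class LevelScheme:
    """Rugosity level boundaries in RI percent.

    Intervals are left-closed, right-open: ``[0, b1) -> 1, [b1, b2) -> 2,
    [b2, b3) -> 3, [b3, inf) -> 4`` under the default ``(1.5, 2.5, 3.5)``
    boundaries, so the top level is the only unbounded class and every RI
    value is classified exactly once.
    """

    boundaries_percent: tuple[float, ...] = (1.5, 2.5, 3.5)

    def __post_init__(self) -> None:
        b = tuple(float(v) for v in self.boundaries_percent)
        if len(b) == 0:
            raise InvalidParameterError("level scheme needs at least one boundary")
        if not all(np.isfinite(b)):
            raise InvalidParameterError("level boundaries must be finite")
        if any(v < 0 for v in b):
            raise InvalidParameterError("level boundaries must be non-negative")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise InvalidParameterError("level boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries_percent", b)

    @property
    def n_levels(self) -> int:
        return len(self.boundaries_percent) + 1


DEFAULT_LEVEL_SCHEME = LevelScheme()


@dataclass(frozen=True)
class SliceMeasurement:
    """Epidermal length, section length and RI for one slice."""

    epidermal_length_mm: float
    section_length_mm: float
    ri_percent: float


@dataclass(frozen=True)
class FruitRugosity:
    """Per-fruit aggregate: mean RI over slices and the assigned level."""

    fruit_id: str
    slice_measurements: tuple[SliceMeasurement, ...]
    mean_ri_percent: float
    level: int
    scheme: LevelScheme = field(default=DEFAULT_LEVEL_SCHEME)


def polyline_length(contour: Contour) -> float:
    """Total Euclidean length of the polyline in input order (mm).

    This is the digital analogue of summing segment lengths of a traced
    polyline; it is always at least the chord length between the endpoints.
    """
    seg = np.diff(contour.xy, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def chord_length(contour: Contour) -> float:
    """Straight-line distance between the contour endpoints (mm)."""
    return float(np.hypot(*(contour.xy[-1] - contour.xy[0])))


def rugosity_index(epidermal_length_mm: float, section_length_mm: float) -> float:
    """RI (%) = (epidermal length - section length) / section length * 100.

    A slightly negative value (epidermal shorter than section, possible from
    tracing noise) is returned as-is with a :class:`MeasurementWarning`.
    """
    e = float(epidermal_length_mm)
    s = float(section_length_mm)
    if not (np.isfinite(e) and np.isfinite(s)):
        raise InvalidParameterError("lengths must be finite")
    if s <= 0:
        raise InvalidParameterError(f"section length must be positive, got {s}")
    if e <= 0:
        raise InvalidParameterError(f"epidermal length must be positive, got {e}")
    if e < s * (1.0 - _SHRINK_TOL):
        warnings.warn(
            f"epidermal length {e:.6g} mm is shorter than section length "
            f"{s:.6g} mm; negative RI suggests a tracing error",
            MeasurementWarning,
            stacklevel=2,
        )
    return 100.0 * (e - s) / s


def slice_ri(
    contour: Contour,
    mode: str = "nominal",
    section_mm: float = 30.0,
) -> SliceMeasurement:
    """Measure one slice.

    Parameters
    ----------
    mode
        ``"nominal"`` uses the supplied excised section length (default 30 mm,
        i.e. the 3 cm protocol); ``"chord"`` uses the endpoint-to-endpoint
        distance of the traced contour itself.
    """
    epidermal = polyline_length(contour)
    if mode == "nominal":
        section = float(section_mm)
        if not np.isfinite(section) or section <= 0:
            raise InvalidParameterError("nominal section length must be positive")
    elif mode == "chord":
        section = chord_length(contour)
        if section == 0.0:
            raise InvalidContourError("closed contour has zero chord; cannot use chord mode")
    else:
        raise InvalidParameterError(f"unknown section mode {mode!r}")
    ri = rugosity_index(epidermal, section)
    return SliceMeasurement(epidermal, section, ri)


def classify_level(ri_percent: float, scheme: LevelScheme = DEFAULT_LEVEL_SCHEME) -> int:
    """Assign a rugosity level (1-based) to an RI value.

    Negative RI is clamped to zero with a warning before classification, so
    tracing noise never produces an unclassifiable fruit.
    """
    ri = float(ri_percent)
    if not np.isfinite(ri):
        raise InvalidParameterError(f"RI must be finite, got {ri}")
    if ri < 0:
        warnings.warn(
            f"negative RI {ri:.6g} clamped to 0 for classification",
            MeasurementWarning,
            stacklevel=2,
        )
        ri = 0.0
    # left-closed intervals: a boundary value belongs to the level above it
    return int(np.searchsorted(scheme.boundaries_percent, ri, side="right")) + 1


def fruit_ri(
    fruit_id: str,
    slices: Sequence[SliceMeasurement],
    scheme: LevelScheme = DEFAULT_LEVEL_SCHEME,
    expected_slices: int = 4,
) -> FruitRugosity:
    """Aggregate slice measurements into a per-fruit mean RI and level."""
    if len(slices) == 0:
        raise InvalidParameterError(f"fruit {fruit_id!r}: empty slice list")
    if len(slices) != expected_slices:
        warnings.warn(
            f"fruit {fruit_id!r}: {len(slices)} slice(s) measured, "
            f"{expected_slices} expected",
            MeasurementWarning,
            stacklevel=2,
        )
    mean_ri = float(np.mean([s.ri_percent for s in slices]))
    return FruitRugosity(
        fruit_id=str(fruit_id),
        slice_measurements=tuple(slices),
        mean_ri_percent=mean_ri,
        level=classify_level(mean_ri, scheme),
        scheme=scheme,
    )


def measure_batch(
    manifest: pd.DataFrame,
    mode: str = "nominal",
    section_mm: float = 30.0,
    scheme: LevelScheme = DEFAULT_LEVEL_SCHEME,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every contour listed in a ``fruit_id,slice_id,contour_path`` manifest.

    Returns ``(slice_table, fruit_table)`` with the documented CSV dialects:
    per-slice ``fruit_id,slice_id,epidermal_mm,section_mm,ri_percent`` and
    per-fruit ``fruit_id,mean_ri_percent,level,n_slices``.
    """
    required = {"fruit_id", "slice_id", "contour_path"}
    if not required.issubset(manifest.columns):
        raise InvalidParameterError(f"manifest needs columns {sorted(required)}")
    rows = []
    for rec in manifest.itertuples(index=False):
        contour = Contour.from_csv(rec.contour_path)
        m = slice_ri(contour, mode=mode, section_mm=section_mm)
        rows.append(
            {
                "fruit_id": rec.fruit_id,
                "slice_id": rec.slice_id,
                "epidermal_mm": m.epidermal_length_mm,
                "section_mm": m.section_length_mm,
                "ri_percent": m.ri_percent,
            }
        )
    slice_table = pd.DataFrame(rows)
    fruit_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MeasurementWarning)
        for fid, grp in slice_table.groupby("fruit_id", sort=False):
            slices = [
                SliceMeasurement(r.epidermal_mm, r.section_mm, r.ri_percent)
                for r in grp.itertuples(index=False)
            ]
            agg = fruit_ri(fid, slices, scheme)
            fruit_rows.append(
                {
                    "fruit_id": fid,
                    "mean_ri_percent": agg.mean_ri_percent,
                    "level": agg.level,
                    "n_slices": len(slices),
                }
            )
    return slice_table, pd.DataFrame(fruit_rows)
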
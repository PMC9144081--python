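"""Measurement core: frame validation, tare, aggregation, decomposition.

An eight-cell balance plate places two load cells (medial + lateral) under
each quadrant of the stance — left/right foot x fore/rear half.  This module
turns raw per-cell readings (kilogram-equivalents) into the section weights
and body-weight percentage map the screening layer consumes, and fits the
voltage-to-weight calibration line.

Conservation identities that hold for every validated frame:

    left + right                          = total
    toes + heel                           = total
    L.toe + L.heel + R.toe + R.heel       = total
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import CalibrationError, DataError, StructuralError, UsageError

logger = logging.getLogger("enp")

SCHEMA_VERSION = 1

#: Small negative readings (tare over-subtraction) are clipped to zero;
#: anything below this is treated as a sensor fault.
NEGATIVE_CLIP_KG = -0.05

#: Relative tolerance for the conservation identities.
IDENTITY_RTOL = 1e-9

FEET = ("left", "right")
REGIONS = ("fore", "rear")
SIDES = ("medial", "lateral")

#: The eight Table-style region ids, grid order: quadrants carry one scoring
#: point, aggregates (sums of two quadrants) carry two.
QUADRANT_REGIONS = ("L.toe", "R.toe", "L.heel", "R.heel")
AGGREGATE_REGIONS = ("toes", "left", "right", "heel")
ALL_REGIONS = ("L.toe", "toes", "R.toe", "left", "right", "L.heel", "heel", "R.heel")


@dataclass(frozen=True, order=True)
class CellPosition:
    """One physical load cell: (foot, region, side) is a unique key."""

    foot: str
    region: str
    side: str

    def __post_init__(self) -> None:
        if self.foot not in FEET or self.region not in REGIONS or self.side not in SIDES:
            raise UsageError(f"invalid cell position {(self.foot, self.region, self.side)}")

    @property
    def quadrant(self) -> str:
        """Region id of the quadrant this cell belongs to."""
        half = "toe" if self.region == "fore" else "heel"
        return f"{self.foot[0].upper()}.{half}"

    @property
    def code(self) -> str:
        """Short column code, e.g. ``L_fore_med``."""
        return f"{self.foot[0].upper()}_{self.region}_{self.side[:3]}"


#: All eight positions in a fixed canonical order.
CELL_POSITIONS: tuple[CellPosition, ...] = tuple(
    CellPosition(f, r, s) for f in FEET for r in REGIONS for s in SIDES
)

_CODE_TO_POSITION = {p.code: p for p in CELL_POSITIONS}


@dataclass
class LoadCellFrame:
    """One time-stamped vector of eight cell readings in kg."""

    timestamp: float
    readings: dict[CellPosition, float]

    def reading(self, foot: str, region: str, side: str) -> float:
        return self.readings[CellPosition(foot, region, side)]


@dataclass
class TareModel:
    """Per-cell zero offsets estimated from empty-plate frames."""

    offsets: dict[CellPosition, float]
    residual_noise_sd: float
    n_frames: int

    def apply(self, frame: LoadCellFrame) -> LoadCellFrame:
        """Subtract the offsets from a raw frame."""
        return LoadCellFrame(
            timestamp=frame.timestamp,
            readings={p: frame.readings[p] - self.offsets[p] for p in CELL_POSITIONS},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "kind": "tare_model",
                "offsets": {p.code: self.offsets[p] for p in CELL_POSITIONS},
                "residual_noise_sd": self.residual_noise_sd,
                "n_frames": self.n_frames,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TareModel":
        obj = json.loads(text)
        return cls(
            offsets={_CODE_TO_POSITION[c]: v for c, v in obj["offsets"].items()},
            residual_noise_sd=obj["residual_noise_sd"],
            n_frames=obj["n_frames"],
        )


@dataclass
class SectionWeights:
    """The decomposition of one frame: four quadrants, four aggregates, total."""

    quadrants: dict[str, float]
    left: float
    right: float
    toes: float
    heel: float
    total: float

    def region_weight(self, region: str) -> float:
        if region in self.quadrants:
            return self.quadrants[region]
        return getattr(self, region)


@dataclass
class RegionPercentages:
    """Body-weight share (percent of total) for each of the 8 regions."""

    values: dict[str, float]

    def __getitem__(self, region: str) -> float:
        return self.values[region]


@dataclass
class CalibrationFit:
    """OLS voltage-to-weight line and its coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, voltage: float) -> float:
        return self.slope * voltage + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "kind": "calibration_fit",
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "n_points": self.n_points,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationFit":
        obj = json.loads(text)
        return cls(obj["slope"], obj["intercept"], obj["r_squared"], obj["n_points"])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def validate_frame(frame: LoadCellFrame) -> LoadCellFrame:
    """Check structure and values of a frame; clip tiny negatives to zero.

    Raises
    ------
    StructuralError
        If any of the eight cell positions is missing.
    DataError
        If a reading is non-finite or more negative than the clip tolerance.
    """
    missing = [p for p in CELL_POSITIONS if p not in frame.readings]
    if missing:
        raise StructuralError(f"frame missing cell positions: {[p.code for p in missing]}")
    cleaned: dict[CellPosition, float] = {}
    for p in CELL_POSITIONS:
        v = float(frame.readings[p])
        if not math.isfinite(v):
            raise DataError(f"non-finite reading at {p.code}: {v!r}")
        if v < 0.0:
            if v < NEGATIVE_CLIP_KG:
                raise DataError(f"reading at {p.code} is {v:.3f} kg, below clip tolerance {NEGATIVE_CLIP_KG} kg")
            logger.warning("clipping slightly negative reading %.4f kg at %s to 0", v, p.code)
            v = 0.0
        cleaned[p] = v
    return LoadCellFrame(timestamp=frame.timestamp, readings=cleaned)


def tare_calibrate(empty_frames: Sequence[LoadCellFrame], tolerance: float = 0.1) -> TareModel:
    """Zero the plate from empty-plate frames captured at start-up.

    Offsets are the per-cell means; the residual noise is the pooled per-cell
    sample standard deviation.  Calibration fails when the residual noise
    exceeds ``tolerance`` (the plate is not stable).
    """
    if len(empty_frames) < 1:
        raise UsageError("tare_calibrate needs at least one empty-plate frame")
    mat = np.array(
        [[f.readings[p] for p in CELL_POSITIONS] for f in empty_frames], dtype=float
    )
    offsets = {p: float(m) for p, m in zip(CELL_POSITIONS, mat.mean(axis=0))}
    if mat.shape[0] >= 2:
        # pooled across cells: sqrt of the mean per-cell variance
        residual = float(np.sqrt(np.mean(mat.var(axis=0, ddof=1))))
    else:
        residual = 0.0
    if residual > tolerance:
        raise CalibrationError(
            f"plate not stable: residual noise SD {residual:.4f} kg exceeds tolerance {tolerance} kg"
        )
    return TareModel(offsets=offsets, residual_noise_sd=residual, n_frames=mat.shape[0])


def aggregate_measurement(
    frames: Sequence[LoadCellFrame], tare: TareModel | None = None
) -> LoadCellFrame:
    """Average a window of frames into one measurement frame.

    Frames are tare-corrected first (when a model is given), then averaged
    per cell.  The result carries the mean timestamp of the window.
    """
    if len(frames) == 0:
        raise UsageError("aggregate_measurement needs at least one frame")
    if tare is not None:
        frames = [tare.apply(f) for f in frames]
    mat = np.array([[f.readings[p] for p in CELL_POSITIONS] for f in frames], dtype=float)
    means = mat.mean(axis=0)
    ts = float(np.mean([f.timestamp for f in frames]))
    return LoadCellFrame(timestamp=ts, readings={p: float(m) for p, m in zip(CELL_POSITIONS, means)})


def compute_totals(frame: LoadCellFrame) -> SectionWeights:
    """Decompose a validated frame into quadrant/aggregate/total weights.

    Each quadrant is the sum of its medial and lateral cell; left/right are
    per-foot sums, toes/heel fore/rear sums, and the total is the sum of all
    eight cells.  The three conservation identities hold by construction.
    """
    q = {
        qr: sum(frame.readings[p] for p in CELL_POSITIONS if p.quadrant == qr)
        for qr in QUADRANT_REGIONS
    }
    left = q["L.toe"] + q["L.heel"]
    right = q["R.toe"] + q["R.heel"]
    toes = q["L.toe"] + q["R.toe"]
    heel = q["L.heel"] + q["R.heel"]
    total = left + right
    return SectionWeights(quadrants=q, left=left, right=right, toes=toes, heel=heel, total=total)


def compute_percentages(weights: SectionWeights) -> RegionPercentages:
    """Map every region to its share of total body weight, in percent."""
    if weights.total <= 0:
        raise DataError("no load detected: total weight is not positive")
    t = weights.total
    values = {r: 100.0 * weights.region_weight(r) / t for r in ALL_REGIONS}
    return RegionPercentages(values=values)


def fit_linear_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Ordinary least squares of known weight (kg) on sensor voltage.

    ``r_squared`` is 1 - SSres/SStot of the fitted line.
    """
    if len(pairs) < 2:
        raise UsageError("calibration needs at least two (voltage, weight) pairs")
    v = np.asarray([p[0] for p in pairs], dtype=float)
    w = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(v).all() and np.isfinite(w).all()):
        raise DataError("calibration pairs contain non-finite values")
    if np.ptp(v) == 0:
        raise DataError("degenerate calibration: all voltages identical")
    fit = stats.linregress(v, w)
    resid = w - (fit.slope * v + fit.intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((w - w.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2, n_points=len(pairs)
    )


# ---------------------------------------------------------------------------
# Frame CSV IO (long and wide dialects)
# ---------------------------------------------------------------------------

LONG_HEADER = ["timestamp", "foot", "region", "side", "kg"]
WIDE_HEADER = ["timestamp"] + [p.code for p in CELL_POSITIONS]


def write_frames_csv(frames: Iterable[LoadCellFrame], path, dialect: str = "wide") -> None:
    """Write frames as CSV in the ``long`` or ``wide`` dialect."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "wide":
            w.writerow(WIDE_HEADER)
            for f in frames:
                w.writerow([repr(f.timestamp)] + [repr(f.readings[p]) for p in CELL_POSITIONS])
        elif dialect == "long":
            w.writerow(LONG_HEADER)
            for f in frames:
                for p in CELL_POSITIONS:
                    w.writerow([repr(f.timestamp), p.foot, p.region, p.side, repr(f.readings[p])])
        else:
            raise UsageError(f"unknown CSV dialect {dialect!r}")


def read_frames_csv(path) -> list[LoadCellFrame]:
    """Read frames from CSV, auto-detecting the dialect by header."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StructuralError(f"empty frames CSV: {path}")
        header = [h.strip() for h in header]
        if header == LONG_HEADER:
            return _read_long(reader, path)
        if header == WIDE_HEADER:
            return _read_wide(reader, path)
        raise StructuralError(f"unrecognized frames CSV header in {path}: {header}")


def _read_wide(rows: Iterable[Sequence[str]], path) -> list[LoadCellFrame]:
    frames = []
    for row in rows:
        if not row:
            continue
        if len(row) != 9:
            raise StructuralError(f"wide frames row in {path} has {len(row)} columns, expected 9")
        ts = float(row[0])
        readings = {p: float(x) for p, x in zip(CELL_POSITIONS, row[1:])}
        frames.append(LoadCellFrame(timestamp=ts, readings=readings))
    return frames


def _read_long(rows: Iterable[Sequence[str]], path) -> list[LoadCellFrame]:
    by_ts: dict[float, dict[CellPosition, float]] = {}
    order: list[float] = []
    for row in rows:
        if not row:
            continue
        ts, foot, region, side, kg = row
        t = float(ts)
        if t not in by_ts:
            by_ts[t] = {}
            order.append(t)
        by_ts[t][CellPosition(foot, region, side)] = float(kg)
    frames = []
    for t in order:
        readings = by_ts[t]
        if len(readings) != 8:
            raise StructuralError(f"frame at t={t} in {path} has {len(readings)} cells, expected 8")
        frames.append(LoadCellFrame(timestamp=t, readings=readings))
    return frames
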
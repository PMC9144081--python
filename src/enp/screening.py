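"""Threshold screening: color codes, point scoring, and the overall level.

Each of the eight regions has a setpoint — the population-average share of
body weight it should carry — and a symmetric warning band around it:
±1.5 percentage points for the four quadrant regions (single pair of cells)
and ±3 percentage points for the four aggregate regions (two quadrants on
the same side).  A share at or above the upper bound codes red (overload),
at or below the lower bound codes blue (underload), strictly inside codes
green.  Red warnings score 1 point per quadrant and 2 per aggregate (blue
likewise), and the point totals set the overall level:

    red points >= 2          -> above-average
    else blue points > 2     -> below-average
    else                     -> average

The shipped default table is the printed population table; new tables can
be derived from any set of measured region averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .decomposition import (
    AGGREGATE_REGIONS,
    ALL_REGIONS,
    QUADRANT_REGIONS,
    SCHEMA_VERSION,
    LoadCellFrame,
    RegionPercentages,
    TareModel,
    aggregate_measurement,
    compute_percentages,
    compute_totals,
    validate_frame,
)
from .exceptions import StructuralError, UsageError

#: Default half-widths of the warning band, in percentage points.
DEFAULT_CELL_MARGIN = 1.5
DEFAULT_SIDE_MARGIN = 3.0

RED, GREEN, BLUE = "red", "green", "blue"
ABOVE, BELOW, AVERAGE = "above-average", "below-average", "average"


@dataclass(frozen=True)
class RegionSpec:
    """Scoring spec for one region: quadrants weigh 1 point, aggregates 2."""

    region: str
    kind: str  # "cell-quadrant" | "aggregate"
    point_weight: int


REGION_SPECS: dict[str, RegionSpec] = {
    **{r: RegionSpec(r, "cell-quadrant", 1) for r in QUADRANT_REGIONS},
    **{r: RegionSpec(r, "aggregate", 2) for r in AGGREGATE_REGIONS},
}

#: Maximum attainable points on one color: 4 quadrants + 4 aggregates.
MAX_POINTS = sum(s.point_weight for s in REGION_SPECS.values())

#: The printed population setpoints (percent of body weight per region).
PRINTED_SETPOINTS: dict[str, float] = {
    "L.toe": 6.4,
    "toes": 13.1,
    "R.toe": 6.4,
    "left": 16.8,
    "right": 16.5,
    "L.heel": 10.1,
    "heel": 20.2,
    "R.heel": 9.8,
}

#: The printed warning bounds (lower, upper) for each region.
PRINTED_BOUNDS: dict[str, tuple[float, float]] = {
    "L.toe": (4.9, 7.9),
    "toes": (10.1, 16.1),
    "R.toe": (4.9, 7.9),
    "left": (13.8, 19.8),
    "right": (13.5, 19.5),
    "L.heel": (8.6, 11.6),
    "heel": (17.2, 23.2),
    "R.heel": (8.3, 11.3),
}


@dataclass
class RegionThreshold:
    """Setpoint and inclusive warning bounds for one region, in percent."""

    region: str
    setpoint: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.setpoint < self.upper:
            raise UsageError(
                f"invalid threshold for {self.region}: "
                f"need lower < setpoint < upper, got {self.lower}/{self.setpoint}/{self.upper}"
            )


@dataclass
class ThresholdTable:
    """Per-region thresholds plus the margins and provenance that built them."""

    regions: dict[str, RegionThreshold]
    cell_margin: float = DEFAULT_CELL_MARGIN
    side_margin: float = DEFAULT_SIDE_MARGIN
    provenance: str = "derived-from-averages"

    def __post_init__(self) -> None:
        missing = [r for r in ALL_REGIONS if r not in self.regions]
        if missing:
            raise StructuralError(f"threshold table missing regions: {missing}")

    def __getitem__(self, region: str) -> RegionThreshold:
        return self.regions[region]

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "kind": "threshold_table",
                "provenance": self.provenance,
                "cell_margin": self.cell_margin,
                "side_margin": self.side_margin,
                "regions": {
                    r: {
                        "setpoint": t.setpoint,
                        "lower": t.lower,
                        "upper": t.upper,
                        "point_weight": REGION_SPECS[r].point_weight,
                    }
                    for r, t in self.regions.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdTable":
        obj = json.loads(text)
        regions = {
            r: RegionThreshold(r, d["setpoint"], d["lower"], d["upper"])
            for r, d in obj["regions"].items()
        }
        return cls(
            regions=regions,
            cell_margin=obj.get("cell_margin", DEFAULT_CELL_MARGIN),
            side_margin=obj.get("side_margin", DEFAULT_SIDE_MARGIN),
            provenance=obj.get("provenance", "derived-from-averages"),
        )


@dataclass
class ScreeningReport:
    """One screening outcome: shares, colors, points, level, warnings."""

    timestamp: float
    total_weight_kg: float
    percentages: dict[str, float]
    colors: dict[str, str]
    red_points: int
    blue_points: int
    level: str
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "kind": "screening_report",
                "timestamp": self.timestamp,
                "total_weight_kg": self.total_weight_kg,
                "percentages": self.percentages,
                "colors": self.colors,
                "red_points": self.red_points,
                "blue_points": self.blue_points,
                "level": self.level,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScreeningReport":
        obj = json.loads(text)
        return cls(
            timestamp=obj["timestamp"],
            total_weight_kg=obj["total_weight_kg"],
            percentages=obj["percentages"],
            colors=obj["colors"],
            red_points=obj["red_points"],
            blue_points=obj["blue_points"],
            level=obj["level"],
            warnings=obj["warnings"],
        )

    def to_text(self, ansi: bool = False) -> str:
        """Aligned human-readable rendering, optionally ANSI-colored."""
        tint = {RED: "\x1b[31m", BLUE: "\x1b[34m", GREEN: "\x1b[32m"}
        reset = "\x1b[0m"
        lines = [
            f"Total weight: {self.total_weight_kg:.1f} kg",
            f"{'region':<8} {'share %':>8}  color",
        ]
        for r in ALL_REGIONS:
            c = self.colors[r]
            label = f"{tint[c]}{c}{reset}" if ansi else c
            lines.append(f"{r:<8} {self.percentages[r]:>8.1f}  {label}")
        lines.append(f"Red points: {self.red_points}  Blue points: {self.blue_points}")
        lines.append(f"Level: {self.level}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def printed_default_thresholds() -> ThresholdTable:
    """The shipped population threshold table, verbatim as printed.

    The printed aggregate setpoints were averaged independently of the
    quadrant setpoints and rounded for display, so e.g. the toes setpoint
    (13.1) is not exactly the sum of the two toe quadrants (6.4 + 6.4);
    the table is shipped as printed rather than recomputed.
    """
    regions = {
        r: RegionThreshold(r, PRINTED_SETPOINTS[r], *PRINTED_BOUNDS[r]) for r in ALL_REGIONS
    }
    return ThresholdTable(regions=regions, provenance="printed-default")


def derive_thresholds(
    averages: Mapping[str, float],
    cell_margin: float = DEFAULT_CELL_MARGIN,
    side_margin: float = DEFAULT_SIDE_MARGIN,
) -> ThresholdTable:
    """Build a threshold table from measured region averages.

    The setpoint is the average; bounds are setpoint +/- cell_margin for
    quadrant regions and +/- side_margin for aggregate regions (margins are
    percentage points of body-weight share, not relative percents).
    """
    if cell_margin <= 0 or side_margin <= 0:
        raise UsageError("margins must be positive percentage points")
    missing = [r for r in ALL_REGIONS if r not in averages]
    if missing:
        raise StructuralError(f"averages missing regions: {missing}")
    regions = {}
    for r in ALL_REGIONS:
        m = cell_margin if REGION_SPECS[r].kind == "cell-quadrant" else side_margin
        a = float(averages[r])
        regions[r] = RegionThreshold(r, a, a - m, a + m)
    return ThresholdTable(
        regions=regions,
        cell_margin=cell_margin,
        side_margin=side_margin,
        provenance="derived-from-averages",
    )


def to_chart_scale(percentages: RegionPercentages | Mapping[str, float]) -> dict[str, float]:
    """Convert body-weight-percent shares to the display-chart scale.

    The screening chart and its threshold table normalize each of the eight
    displayed regions by the sum over all eight — three times body weight,
    since every cell contributes to one quadrant and two aggregates — so the
    grid's setpoints sum to ~100 as a whole.  On this scale a balanced
    stance reads e.g. heel ~20 rather than ~60 percent of body weight.
    """
    vals = percentages.values if isinstance(percentages, RegionPercentages) else dict(percentages)
    return {r: v / 3.0 for r, v in vals.items()}


def classify_region(percent: float, threshold: RegionThreshold) -> str:
    """Color one region's share: bounds are warning-inclusive."""
    if percent >= threshold.upper:
        return RED
    if percent <= threshold.lower:
        return BLUE
    return GREEN


def score_points(colors: Mapping[str, str]) -> tuple[int, int]:
    """Sum point weights of red and blue regions."""
    missing = [r for r in ALL_REGIONS if r not in colors]
    if missing:
        raise StructuralError(f"colors missing regions: {missing}")
    red = sum(REGION_SPECS[r].point_weight for r in ALL_REGIONS if colors[r] == RED)
    blue = sum(REGION_SPECS[r].point_weight for r in ALL_REGIONS if colors[r] == BLUE)
    return red, blue


def assign_level(red_points: int, blue_points: int) -> str:
    """Overall level from the point totals; above takes precedence over below."""
    if red_points < 0 or blue_points < 0:
        raise UsageError("point totals must be non-negative")
    if red_points >= 2:
        return ABOVE
    if blue_points > 2:
        return BELOW
    return AVERAGE


def build_report(
    percentages: RegionPercentages | Mapping[str, float],
    thresholds: ThresholdTable,
    total_weight_kg: float,
    timestamp: float = 0.0,
) -> ScreeningReport:
    """Compose classification, scoring and level into a screening report.

    ``percentages`` are compared against the table as given; callers must
    supply them on the same scale the table was built on (the printed table
    lives on the chart scale, see :func:`to_chart_scale`).
    """
    colors = {r: classify_region(percentages[r], thresholds[r]) for r in ALL_REGIONS}
    red, blue = score_points(colors)
    level = assign_level(red, blue)
    warnings = []
    for r in ALL_REGIONS:
        t = thresholds[r]
        if colors[r] == RED:
            warnings.append(
                f"{r} share {percentages[r]:.1f}% at or above upper bound {t.upper:.1f}% (overload)"
            )
        elif colors[r] == BLUE:
            warnings.append(
                f"{r} share {percentages[r]:.1f}% at or below lower bound {t.lower:.1f}% (underload)"
            )
    return ScreeningReport(
        timestamp=timestamp,
        total_weight_kg=total_weight_kg,
        percentages={r: percentages[r] for r in ALL_REGIONS},
        colors=colors,
        red_points=red,
        blue_points=blue,
        level=level,
        warnings=warnings,
    )


def screen_frames(
    frames: list[LoadCellFrame],
    thresholds: ThresholdTable | None = None,
    tare: TareModel | None = None,
) -> ScreeningReport:
    """Full measurement-to-report pipeline for a window of raw frames.

    Validates every frame, tare-corrects and averages the window, decomposes
    it, converts the shares to the chart scale and screens them against the
    given table (the printed population table by default).
    """
    frames = [validate_frame(f) for f in frames]
    measurement = aggregate_measurement(frames, tare=tare)
    weights = compute_totals(measurement)
    shares = to_chart_scale(compute_percentages(weights))
    table = thresholds if thresholds is not None else printed_default_thresholds()
    return build_report(shares, table, weights.total, timestamp=measurement.timestamp)
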
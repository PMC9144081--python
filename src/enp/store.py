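"""Session persistence and longitudinal monitoring.

Sessions are appended to a local line-delimited JSON (JSONL) store, one
record per line; the store is the offline replacement for a networked
backend.  Trends compare a subject's earliest and latest screening within a
window, per region, to surface slow drifts in load distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .decomposition import ALL_REGIONS, SCHEMA_VERSION
from .exceptions import DataError, UsageError
from .screening import GREEN, ScreeningReport

logger = logging.getLogger("enp")

__version__ = "0.1.0"


@dataclass
class SessionRecord:
    """One stored screening session for one subject."""

    session_id: str
    subject: str
    timestamp: float
    report: ScreeningReport
    thresholds_provenance: str = "printed-default"
    software_version: str = __version__

    def to_json_line(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "session_id": self.session_id,
                "subject": self.subject,
                "timestamp": self.timestamp,
                "report": json.loads(self.report.to_json()),
                "thresholds_provenance": self.thresholds_provenance,
                "software_version": self.software_version,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json_line(cls, line: str) -> "SessionRecord":
        obj = json.loads(line)
        return cls(
            session_id=obj["session_id"],
            subject=obj["subject"],
            timestamp=obj["timestamp"],
            report=ScreeningReport.from_json(json.dumps(obj["report"])),
            thresholds_provenance=obj["thresholds_provenance"],
            software_version=obj["software_version"],
        )


@dataclass
class TrendSummary:
    """First-to-last change per region over a subject's session window."""

    subject: str
    n_sessions: int
    first_timestamp: float
    last_timestamp: float
    region_first: dict[str, float]
    region_last: dict[str, float]
    region_delta_pp: dict[str, float]
    region_direction: dict[str, str]
    level_history: list[str]
    warning_sessions: int


def read_sessions(store_path) -> list[SessionRecord]:
    """Read all records from a JSONL store; corrupt lines are skipped."""
    path = Path(store_path)
    if not path.exists():
        return []
    records = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            records.append(SessionRecord.from_json_line(line))
        except (json.JSONDecodeError, KeyError) as exc:
            logger.warning("skipping corrupt session line %d in %s: %s", i, path, exc)
    return records


def append_session(store_path, record: SessionRecord) -> SessionRecord:
    """Append one session to the store, enforcing unique session ids."""
    path = Path(store_path)
    existing = read_sessions(path)
    if any(r.session_id == record.session_id for r in existing):
        raise DataError(f"duplicate session id {record.session_id!r} in {path}")
    with open(path, "a") as fh:
        fh.write(record.to_json_line() + "\n")
    return record


def trend(store_path, subject: str, window: tuple[float, float] | None = None) -> TrendSummary:
    """Per-region first-to-last deltas for one subject's sessions.

    ``window`` is an optional (start, end) timestamp filter, end-inclusive.
    """
    sessions = [r for r in read_sessions(store_path) if r.subject == subject]
    if window is not None:
        lo, hi = window
        sessions = [r for r in sessions if lo <= r.timestamp <= hi]
    sessions.sort(key=lambda r: r.timestamp)
    if len(sessions) < 2:
        raise UsageError(
            f"trend for {subject!r} needs at least 2 sessions in the window, found {len(sessions)}"
        )
    first, last = sessions[0], sessions[-1]
    region_first = {r: first.report.percentages[r] for r in ALL_REGIONS}
    region_last = {r: last.report.percentages[r] for r in ALL_REGIONS}
    delta = {r: region_last[r] - region_first[r] for r in ALL_REGIONS}

    def direction(d: float) -> str:
        if d > 0:
            return "rising"
        if d < 0:
            return "falling"
        return "stable"

    return TrendSummary(
        subject=subject,
        n_sessions=len(sessions),
        first_timestamp=first.timestamp,
        last_timestamp=last.timestamp,
        region_first=region_first,
        region_last=region_last,
        region_delta_pp=delta,
        region_direction={r: direction(delta[r]) for r in ALL_REGIONS},
        level_history=[r.report.level for r in sessions],
        warning_sessions=sum(
            1 for r in sessions if any(c != GREEN for c in r.report.colors.values())
        ),
    )
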
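"""Individual-level screening histories and look-back window classification.

A woman's participation in the last round of each programme is read off her
event history with a programme-specific look-back window anchored at her
reference date (the last date she was known to be alive): six years for
cervical, four for breast, three for bowel screening — the recommended
inter-screening interval plus one year for reasonable delays.  Windows are
half-open ``[anchor - L years, anchor)``: the day exactly L years before the
anchor counts as inside, the anchor day itself does not.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Programme",
    "EventType",
    "ScreeningEvent",
    "WomanRecord",
    "ParticipationPattern",
    "WindowSpec",
    "MAIN_WINDOWS",
    "PRE_AGE54_WINDOWS",
    "PATTERN_ORDER",
    "classify_last_round",
    "tabulate_patterns",
    "tabulate_two_programme",
    "pre_age54_patterns",
    "restrict_to_invited",
    "ever_participant_flags",
    "years_before",
    "add_years",
    "round_half_up",
    "read_events",
    "read_roster",
    "load_cohort",
    "write_cohort",
    "write_patterns",
    "read_patterns",
    "MalformedRowError",
]


class Programme(str, enum.Enum):
    BREAST = "breast"
    CERVICAL = "cervical"
    BOWEL = "bowel"


class EventType(str, enum.Enum):
    INVITATION = "invitation"
    SCREEN = "screen"


@dataclass(frozen=True)
class ScreeningEvent:
    """One invitation or completed screen in one programme."""

    woman_id: str
    programme: Programme
    event_type: EventType
    event_date: dt.date

    def __post_init__(self) -> None:
        if not isinstance(self.event_date, dt.date):
            raise TypeError("event_date must be a datetime.date")


@dataclass
class WomanRecord:
    """A woman's roster entry plus her ordered screening event history.

    ``reference_date`` is the last date the woman was known to be alive and
    anchors every look-back window.  ``hysterectomy`` is carried through but
    never used by the classifiers (eligibility loss after hysterectomy is
    handled by the pre-age-54 robustness analysis instead); it exists so that
    synthetic experiments can filter on it.
    """

    woman_id: str
    birth_date: dt.date
    reference_date: dt.date
    hysterectomy: bool | None = None
    events: list[ScreeningEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reference_date <= self.birth_date:
            raise ValueError(
                f"woman {self.woman_id}: reference_date {self.reference_date} "
                f"is not after birth_date {self.birth_date}"
            )


@dataclass(frozen=True)
class ParticipationPattern:
    """Per-woman last-round participation triple (breast, cervical, bowel)."""

    woman_id: str
    breast: bool
    cervical: bool
    bowel: bool

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.breast, self.cervical, self.bowel)

    @property
    def n_programmes(self) -> int:
        return int(self.breast) + int(self.cervical) + int(self.bowel)


@dataclass(frozen=True)
class WindowSpec:
    """Look-back window for one programme: ``[anchor - lookback_years, anchor)``."""

    programme: Programme
    lookback_years: int

    def __post_init__(self) -> None:
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")


#: Main analysis: recommended interval plus one year per programme.
MAIN_WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec(Programme.CERVICAL, 6),
    WindowSpec(Programme.BREAST, 4),
    WindowSpec(Programme.BOWEL, 3),
)

#: Robustness analysis anchored at the 54th birthday (two programmes only).
PRE_AGE54_WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec(Programme.CERVICAL, 6),
    WindowSpec(Programme.BREAST, 4),
)

#: Row order of the 8-pattern table: by number of programmes, then
#: breast > cervical > bowel precedence.
PATTERN_ORDER: tuple[tuple[bool, bool, bool], ...] = (
    (True, True, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (False, False, False),
)


def years_before(anchor: dt.date, years: int) -> dt.date:
    """Calendar date exactly ``years`` before ``anchor`` (Feb 29 -> Feb 28)."""
    try:
        return anchor.replace(year=anchor.year - years)
    except ValueError:  # Feb 29 in a non-leap target year
        return anchor.replace(year=anchor.year - years, month=2, day=28)


def add_years(anchor: dt.date, years: int) -> dt.date:
    """Calendar date exactly ``years`` after ``anchor`` (Feb 29 -> Feb 28)."""
    try:
        return anchor.replace(year=anchor.year + years)
    except ValueError:
        return anchor.replace(year=anchor.year + years, month=2, day=28)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, as in the published tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_last_round(
    woman: WomanRecord,
    windows: Sequence[WindowSpec] = MAIN_WINDOWS,
    anchor: dt.date | None = None,
) -> ParticipationPattern:
    """Classify last-round participation per programme.

    A programme's flag is True iff the woman has at least one *screen* event
    in that programme dated inside the half-open window
    ``[anchor - lookback, anchor)``.  Invitations never count towards
    participation.  Programmes without a window are flagged False.
    """
    if anchor is None:
        anchor = woman.reference_date
    if anchor <= woman.birth_date:
        raise ValueError(
            f"woman {woman.woman_id}: anchor {anchor} is not after birth date"
        )
    seen = [w.programme for w in windows]
    if len(seen) != len(set(seen)):
        raise ValueError("each programme may appear at most once in windows")

    flags = {p: False for p in Programme}
    for w in windows:
        start = years_before(anchor, w.lookback_years)
        flags[w.programme] = any(
            ev.event_type is EventType.SCREEN
            and ev.programme is w.programme
            and start <= ev.event_date < anchor
            for ev in woman.events
        )
    return ParticipationPattern(
        woman.woman_id,
        breast=flags[Programme.BREAST],
        cervical=flags[Programme.CERVICAL],
        bowel=flags[Programme.BOWEL],
    )


def tabulate_patterns(patterns: Iterable[ParticipationPattern]) -> pd.DataFrame:
    """Tabulate the 8 participation combinations.

    Returns a DataFrame with columns ``breast, cervical, bowel, count,
    percent`` in :data:`PATTERN_ORDER` (most programmes first).  Percents are
    of the total and rounded half away from zero to integers; an empty input
    yields a table of zeros.
    """
    counts = {combo: 0 for combo in PATTERN_ORDER}
    total = 0
    for p in patterns:
        counts[p.flags] += 1
        total += 1
    rows = []
    for combo in PATTERN_ORDER:
        c = counts[combo]
        pct = round_half_up(100.0 * c / total) if total else 0.0
        rows.append(
            {
                "breast": combo[0],
                "cervical": combo[1],
                "bowel": combo[2],
                "count": c,
                "percent": int(pct),
            }
        )
    return pd.DataFrame(rows)


def tabulate_two_programme(
    patterns: Iterable[ParticipationPattern],
) -> dict[str, int]:
    """Collapse breast/cervical patterns into both / one / neither counts."""
    out = {"both": 0, "one": 0, "neither": 0}
    for p in patterns:
        k = int(p.breast) + int(p.cervical)
        out["both" if k == 2 else "one" if k == 1 else "neither"] += 1
    return out


def pre_age54_patterns(
    women: Iterable[WomanRecord],
) -> list[ParticipationPattern]:
    """Breast/cervical participation in the windows preceding the 54th birthday.

    The anchor is each woman's 54th birthday and only the cervical (6 y) and
    breast (4 y) windows apply; the bowel flag is structurally False.  This is
    the hysterectomy-robustness analysis: before the mid-50s almost all women
    are still eligible for cervical screening.
    """
    out = []
    for w in women:
        anchor = add_years(w.birth_date, 54)
        out.append(classify_last_round(w, PRE_AGE54_WINDOWS, anchor=anchor))
    return out


def restrict_to_invited(
    women: Sequence[WomanRecord], min_lag_years: float = 1.0
) -> list[WomanRecord]:
    """Subset to women with a bowel invitation sent sufficiently long ago.

    Retains exactly the women having at least one bowel *invitation* event
    dated on or before ``reference_date - min_lag_years``.  This is the
    bowel roll-out robustness analysis (lag of one year in the published
    design).  Monotone in the lag and idempotent.
    """
    if min_lag_years < 0:
        raise ValueError("min_lag_years must be non-negative")
    kept = []
    for w in women:
        if float(min_lag_years).is_integer():
            cutoff = years_before(w.reference_date, int(min_lag_years))
        else:
            cutoff = w.reference_date - dt.timedelta(
                days=round(min_lag_years * 365.2425)
            )
        if any(
            ev.programme is Programme.BOWEL
            and ev.event_type is EventType.INVITATION
            and ev.event_date <= cutoff
            for ev in w.events
        ):
            kept.append(w)
    return kept


def ever_participant_flags(women: Iterable[WomanRecord]) -> dict[str, bool]:
    """True for women with >= 1 screen event ever, in any programme."""
    return {
        w.woman_id: any(ev.event_type is EventType.SCREEN for ev in w.events)
        for w in women
    }


# ---------------------------------------------------------------------------
# CSV input/output


class MalformedRowError(ValueError):
    """Raised when input rows cannot be parsed; carries 1-based line numbers."""

    def __init__(self, path: str | Path, lines: list[tuple[int, str]]):
        self.lines = lines
        msg = "; ".join(f"line {n}: {reason}" for n, reason in lines[:10])
        extra = "" if len(lines) <= 10 else f" (+{len(lines) - 10} more)"
        super().__init__(f"{path}: {len(lines)} malformed row(s): {msg}{extra}")


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def _require_columns(path: str | Path, header: Sequence[str], required: Sequence[str]) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_events(path: str | Path) -> list[ScreeningEvent]:
    """Read an events CSV (woman_id, programme, event_type, event_date).

    Dates must be ISO-8601.  Rows with an unknown programme or event type are
    skipped with a warning; rows with unparseable dates abort the read with a
    :class:`MalformedRowError` listing their line numbers.
    """
    events: list[ScreeningEvent] = []
    bad: list[tuple[int, str]] = []
    n_unknown = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(path, reader.fieldnames or [], ["woman_id", "programme", "event_type", "event_date"])
        for lineno, row in enumerate(reader, start=2):
            try:
                programme = Programme(row["programme"].strip().lower())
                event_type = EventType(row["event_type"].strip().lower())
            except ValueError:
                n_unknown += 1
                continue
            try:
                date = _parse_date(row["event_date"])
            except ValueError:
                bad.append((lineno, f"unparseable date {row['event_date']!r}"))
                continue
            events.append(ScreeningEvent(row["woman_id"].strip(), programme, event_type, date))
    if bad:
        raise MalformedRowError(path, bad)
    if n_unknown:
        warnings.warn(
            f"{path}: skipped {n_unknown} row(s) with unknown programme/event type",
            stacklevel=2,
        )
    return events


def read_roster(path: str | Path) -> dict[str, WomanRecord]:
    """Read a roster CSV (woman_id, birth_date, reference_date, hysterectomy)."""
    women: dict[str, WomanRecord] = {}
    bad: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(path, reader.fieldnames or [], ["woman_id", "birth_date", "reference_date"])
        for lineno, row in enumerate(reader, start=2):
            try:
                birth = _parse_date(row["birth_date"])
                ref = _parse_date(row["reference_date"])
            except ValueError:
                bad.append((lineno, "unparseable date"))
                continue
            hyst_raw = (row.get("hysterectomy") or "").strip()
            hyst = None if hyst_raw == "" else bool(int(hyst_raw))
            wid = row["woman_id"].strip()
            women[wid] = WomanRecord(wid, birth, ref, hyst)
    if bad:
        raise MalformedRowError(path, bad)
    return women


def load_cohort(events_path: str | Path, roster_path: str | Path) -> list[WomanRecord]:
    """Join roster and events into WomanRecords (events sorted by date)."""
    women = read_roster(roster_path)
    orphans = 0
    for ev in read_events(events_path):
        if ev.woman_id in women:
            women[ev.woman_id].events.append(ev)
        else:
            orphans += 1
    if orphans:
        warnings.warn(f"{events_path}: {orphans} event(s) for women absent from roster", stacklevel=2)
    for w in women.values():
        w.events.sort(key=lambda e: (e.event_date, e.programme.value, e.event_type.value))
    return sorted(women.values(), key=lambda w: w.woman_id)


def write_cohort(
    women: Sequence[WomanRecord], events_path: str | Path, roster_path: str | Path
) -> None:
    """Write the events.csv / roster.csv pair for a cohort."""
    with open(roster_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["woman_id", "birth_date", "reference_date", "hysterectomy"])
        for w in women:
            hyst = "" if w.hysterectomy is None else int(w.hysterectomy)
            wr.writerow([w.woman_id, w.birth_date.isoformat(), w.reference_date.isoformat(), hyst])
    with open(events_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["woman_id", "programme", "event_type", "event_date"])
        for w in women:
            for ev in w.events:
                wr.writerow([ev.woman_id, ev.programme.value, ev.event_type.value, ev.event_date.isoformat()])


def write_patterns(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_patterns(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("breast", "cervical", "bowel"):
        df[col] = df[col].astype(bool)
    return df
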
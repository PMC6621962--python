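"""Season calendars mapping calendar dates to ecological seasons.

The default calendar is the three-season split used throughout the
analysis: spring (den emergence to June 14), summer (June 15 to
August 9), fall (August 10 to den entry).  Denning is handled outside
the calendar: dates before a bear's den emergence or after den entry
are excluded upstream, so spring effectively begins at emergence and
fall ends at entry.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

SEASONS = ("spring", "summer", "fall")


@dataclass(frozen=True)
class SeasonCalendar:
    """Ordered within-year season start dates.

    ``starts`` maps season name -> (month, day) of its first day; the
    season runs until the next start (wrapping at new year).
    """

    starts: tuple[tuple[str, tuple[int, int]], ...] = (
        ("spring", (1, 1)),
        ("summer", (6, 15)),
        ("fall", (8, 10)),
    )

    def season_of(self, date: dt.date) -> str:
        md = (date.month, date.day)
        name = self.starts[-1][0]  # last season wraps past new year
        for season, start in self.starts:
            if md >= start:
                name = season
        return name

    def to_file(self, path: str | Path) -> None:
        lines = [f"{name} {m:02d}-{d:02d}" for name, (m, d) in self.starts]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SeasonCalendar":
        starts = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, md = line.split()
            m, d = md.split("-")
            starts.append((name, (int(m), int(d))))
        return cls(starts=tuple(starts))


DEFAULT_CALENDAR = SeasonCalendar()
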
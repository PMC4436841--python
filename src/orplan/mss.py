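"""Master Surgical Schedule: the cyclic weekly grid of OR blocks.

Each block is one half-day session (default 360 min) of one operating room,
reserved for exactly one surgical specialty — block booking: a block cannot
be shared between specialties. The MSS is tactical input here, never a
decision variable.
"""
from __future__ import annotations

from datetime import date, time, timedelta
from enum import Enum
from functools import lru_cache
from importlib import resources

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pathway import ConfigurationError


class Session(str, Enum):
    MORNING = "morning"
    AFTERNOON = "afternoon"


WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday")


class ORBlock(BaseModel):
    model_config = ConfigDict(frozen=True)

    room: str
    date: date
    session: Session
    start_time: time
    duration_min: float = Field(default=360, gt=0)
    specialty: str

    @property
    def key(self) -> tuple[str, date, Session]:
        return (self.room, self.date, self.session)

    def label(self) -> str:
        return f"{self.room} {self.date.isoformat()} {self.session.value}"


class MSSTemplate(BaseModel):
    """Weekly grid keyed room -> weekday -> session -> specialty."""

    model_config = ConfigDict(frozen=True)

    rooms: dict[str, dict[str, dict[Session, str]]]
    session_duration_min: float = Field(default=360, gt=0)
    session_start: dict[Session, time] = {
        Session.MORNING: time(8, 0),
        Session.AFTERNOON: time(14, 0),
    }

    @model_validator(mode="after")
    def _check_days(self) -> "MSSTemplate":
        for room, days in self.rooms.items():
            bad = set(days) - set(WEEKDAYS)
            if bad:
                raise ValueError(f"room {room}: not Monday-Friday weekdays: {sorted(bad)}")
        return self

    @property
    def specialties(self) -> list[str]:
        seen: dict[str, None] = {}
        for days in self.rooms.values():
            for sessions in days.values():
                for spec in sessions.values():
                    seen.setdefault(spec)
        return list(seen)

    @classmethod
    def from_yaml(cls, path) -> "MSSTemplate":
        with open(path) as fh:
            return cls._from_raw(yaml.safe_load(fh))

    @classmethod
    def _from_raw(cls, raw: dict) -> "MSSTemplate":
        starts = {
            Session(k): time.fromisoformat(v) if isinstance(v, str) else v
            for k, v in raw.get(
                "session_start", {"morning": "08:00", "afternoon": "14:00"}
            ).items()
        }
        return cls(
            rooms={
                room: {
                    day: {Session(s): spec for s, spec in sessions.items()}
                    for day, sessions in days.items()
                }
                for room, days in raw["rooms"].items()
            },
            session_duration_min=raw.get("session_duration_min", 360),
            session_start=starts,
        )


class MasterSchedule(BaseModel):
    blocks: list[ORBlock]
    specialty_list: list[str]

    @model_validator(mode="after")
    def _check(self) -> "MasterSchedule":
        keys = [b.key for b in self.blocks]
        if len(set(keys)) != len(keys):
            raise ValueError("two blocks share the same (room, date, session)")
        unknown = {b.specialty for b in self.blocks} - set(self.specialty_list)
        if unknown:
            raise ValueError(f"blocks labeled with unknown specialties: {sorted(unknown)}")
        return self

    def blocks_in_week(self, week_start: date) -> list[ORBlock]:
        monday = monday_of(week_start)
        end = monday + timedelta(days=7)
        return sorted(
            (b for b in self.blocks if monday <= b.date < end),
            key=lambda b: (b.date, b.session is Session.AFTERNOON, b.room),
        )


@lru_cache(maxsize=1)
def default_template() -> MSSTemplate:
    raw = yaml.safe_load(
        resources.files("orplan.data").joinpath("mss_default.yaml").read_text()
    )
    return MSSTemplate._from_raw(raw)


def monday_of(d: date) -> date:
    return d - timedelta(days=d.weekday())


def expand_template(
    template: MSSTemplate, start_date: date, n_weeks: int
) -> MasterSchedule:
    """Repeat the weekly template over ``n_weeks`` Monday-Friday weeks,
    starting from the Monday of ``start_date``'s week."""
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    monday = monday_of(start_date)
    blocks: list[ORBlock] = []
    for week in range(n_weeks):
        for room, days in template.rooms.items():
            for day, sessions in days.items():
                d = monday + timedelta(weeks=week, days=WEEKDAYS.index(day))
                for session, specialty in sessions.items():
                    blocks.append(
                        ORBlock(
                            room=room,
                            date=d,
                            session=session,
                            start_time=template.session_start[session],
                            duration_min=template.session_duration_min,
                            specialty=specialty,
                        )
                    )
    return MasterSchedule(blocks=blocks, specialty_list=template.specialties)


def specialty_capacity(
    mss: MasterSchedule, specialty: str, week_start: date
) -> float:
    """Total block minutes assigned a priori to a specialty in one week."""
    if specialty not in mss.specialty_list:
        raise ConfigurationError(f"unknown specialty {specialty!r}")
    return sum(
        b.duration_min for b in mss.blocks_in_week(week_start) if b.specialty == specialty
    )
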
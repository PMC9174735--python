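"""Coalition events: roles, configuration classification, feasibility.

A coalition is simultaneous aggression by at least two participants against at
least one target. Configuration encodes the rank relation between target and
participants on the event day:

* ``all-up`` — every participant rated strictly below the target;
* ``all-down`` — no participant rated below the target;
* ``bridging`` — at least one participant below and at least one not below.

Feasibility is the sum of the participants' standardized ratings minus the
target's, with ratings standardized among *all* males present in the group on
the event day (highest 1, lowest 0). Positive feasibility means the
participants jointly outrank the target; by construction every all-down and
bridging event has positive feasibility, and only all-up events can be
infeasible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .elo import EloTrajectories

logger = logging.getLogger(__name__)

CONFIGURATIONS = ("all-down", "bridging", "all-up")
ROLE_PARTICIPANT = "participant"
ROLE_TARGET = "target"


@dataclass(frozen=True)
class CoalitionEvent:
    """One coalition event: >=2 participants against >=1 target."""

    event_id: str
    date: pd.Timestamp
    group: str
    participants: tuple[str, ...]
    targets: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        object.__setattr__(self, "participants", tuple(self.participants))
        object.__setattr__(self, "targets", tuple(self.targets))

    @property
    def males(self) -> tuple[str, ...]:
        return self.participants + self.targets


def events_from_roles(roles: pd.DataFrame) -> list[CoalitionEvent]:
    """Build events from a long role table (event_id, date, group, role, male)."""
    events = []
    for eid, sub in roles.groupby("event_id", sort=True):
        parts = tuple(sub.loc[sub["role"] == ROLE_PARTICIPANT, "male"])
        targs = tuple(sub.loc[sub["role"] == ROLE_TARGET, "male"])
        events.append(CoalitionEvent(
            event_id=str(eid), date=pd.Timestamp(sub["date"].iloc[0]),
            group=str(sub["group"].iloc[0]), participants=parts, targets=targs))
    return events


def assign_roles(event: CoalitionEvent,
                 presence: pd.DataFrame | None = None) -> dict[str, str]:
    """Validate an event and return the male -> role map.

    Raises :class:`DataError` (naming the event id) when the participant and
    target sets overlap, are too small, or a member is absent on the event day.
    """
    overlap = set(event.participants) & set(event.targets)
    if overlap:
        raise DataError(
            f"event {event.event_id}: males {sorted(overlap)} listed as both "
            "participant and target")
    if len(event.participants) < 2:
        raise DataError(f"event {event.event_id}: needs >= 2 participants")
    if len(event.targets) < 1:
        raise DataError(f"event {event.event_id}: needs >= 1 target")
    if len(set(event.males)) != len(event.males):
        raise DataError(f"event {event.event_id}: duplicated male in role lists")
    if presence is not None:
        pres = presence.set_index("male") if "male" in presence.columns else presence
        for m in event.males:
            if m not in pres.index:
                raise DataError(f"event {event.event_id}: unknown male {m!r}")
            row = pres.loc[m]
            if not (pd.Timestamp(row["entry"]) <= event.date <= pd.Timestamp(row["exit"])):
                raise DataError(
                    f"event {event.event_id}: {m!r} not present on {event.date.date()}")
    roles = {m: ROLE_PARTICIPANT for m in event.participants}
    roles.update({m: ROLE_TARGET for m in event.targets})
    return roles


def _reference_target(event: CoalitionEvent, ratings) -> str:
    """Single-target events use their target; multi-target events are measured
    against the highest-rated target (flagged by callers)."""
    return max(event.targets, key=lambda m: ratings[m])


def classify_configuration(event: CoalitionEvent, ratings) -> str:
    """Classify an event from day-0 ratings (any monotone scale).

    A participant rated exactly equal to the target counts as "not lower":
    ties never produce all-up. Tie cases are logged at WARNING level because
    with continuous ratings they indicate suspect inputs.
    """
    target = _reference_target(event, ratings)
    try:
        rt = ratings[target]
        rel = [(ratings[p] < rt, ratings[p] == rt) for p in event.participants]
    except KeyError as exc:
        raise DataError(
            f"event {event.event_id}: missing rating for male {exc.args[0]!r}") from None
    if any(tie for _, tie in rel):
        logger.warning("event %s: participant rating tied with target; "
                       "tie counts as 'not lower'", event.event_id)
    below = [b for b, _ in rel]
    if all(below):
        return "all-up"
    if not any(below):
        return "all-down"
    return "bridging"


def compute_feasibility(event: CoalitionEvent, standardized) -> float:
    """Feasibility f = sum of participants' standardized ratings - target's.

    ``standardized`` must be the min-max standardized ratings of all males
    present in the group on the event day, not only the event members.
    """
    target = _reference_target(event, standardized)
    try:
        return float(sum(standardized[p] for p in event.participants)
                     - standardized[target])
    except KeyError as exc:
        raise DataError(
            f"event {event.event_id}: missing standardized rating for "
            f"{exc.args[0]!r}") from None


def event_metrics(events: list[CoalitionEvent],
                  trajectories: EloTrajectories,
                  presence: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-event metrics table: configuration, feasibility, size, day-0 ratings.

    Events whose day-0 standardization fails (degenerate rating range, <2
    males) are excluded, with the reason logged.
    """
    rows = []
    for ev in events:
        assign_roles(ev, presence)
        try:
            ratings = trajectories.ratings_on(ev.group, ev.date)
            standardized = trajectories.standardized_on(ev.group, ev.date)
        except Exception as exc:  # noqa: BLE001 - logged and excluded by contract
            logger.warning("event %s excluded: %s", ev.event_id, exc)
            continue
        config = classify_configuration(ev, ratings)
        f = compute_feasibility(ev, standardized)
        rows.append({
            "event_id": ev.event_id,
            "date": ev.date,
            "group": ev.group,
            "configuration": config,
            "feasibility": f,
            "n_participants": len(ev.participants),
            "n_targets": len(ev.targets),
            "multi_target": len(ev.targets) > 1,
            "target": _reference_target(ev, ratings),
        })
    cols = ["event_id", "date", "group", "configuration", "feasibility",
            "n_participants", "n_targets", "multi_target", "target"]
    return pd.DataFrame(rows, columns=cols)


def events_to_contests(events: list[CoalitionEvent]) -> pd.DataFrame:
    """Express coalition events as decided dyadic contests (each participant
    beats each target on the event date).

    For sensitivity analyses only: feeding these rows into the rating engine
    alongside the dyadic agonism lets coalitionary aggression move ratings.
    The default analysis excludes them to avoid circularity between the
    response (future rating) and the events whose effects are estimated.
    """
    rows = []
    for ev in events:
        for p in ev.participants:
            for t in ev.targets:
                rows.append((ev.date, ev.group, p, t))
    return pd.DataFrame(rows, columns=["date", "group", "winner", "loser"])


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (12.5 -> 13)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def configuration_share_table(configurations) -> pd.DataFrame:
    """Descriptive share table: counts and integer percentages per configuration.

    Accepts either a sequence of labels or a mapping label -> count.
    Percentages are rounded half-away-from-zero.
    """
    if isinstance(configurations, dict):
        counts = pd.Series(configurations, dtype=int)
    else:
        counts = pd.Series(configurations).value_counts()
    counts = counts.reindex([c for c in CONFIGURATIONS if c in counts.index])
    total = int(counts.sum())
    pct = [round_half_away(100.0 * c / total) for c in counts]
    return pd.DataFrame({
        "configuration": counts.index,
        "count": counts.values,
        "percent": pct,
    })
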
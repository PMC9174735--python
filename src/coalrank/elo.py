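"""Sequential Elo-rating dominance trajectories.

Decided dyadic contests are processed chronologically. After each contest the
winner gains ``k * (1 - E(R_w - R_l))`` rating points and the loser loses the
same amount, where ``E`` maps the pre-contest rating difference to the winner's
expected score. Two expected-score functions are supported:

``logistic-400``
    ``E(d) = 1 / (1 + 10**(-d/400))`` — the chess convention.
``normal-cdf``
    ``E(d) = Phi(d / (200*sqrt(2)))`` — the classical Gaussian form, common in
    the animal-dominance literature.

Both satisfy ``E(0) = 0.5`` and ``E(d) + E(-d) = 1``, so every update conserves
the two contestants' rating total (zero-sum).

Ratings are step functions: ``rating_at`` carries the last update forward, and
a male's rating before his first contest is the start value. On the day of an
update the post-update value is returned.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._exceptions import ConfigError, DataError, RatingLookupError, StandardizationError
from .config import EloParams

_EPOCH = pd.Timestamp("1970-01-01")


def expected_score(diff, kind: str = "logistic-400"):
    """Expected score of the focal contestant given rating difference ``diff``."""
    d = np.asarray(diff, dtype=float)
    if kind == "logistic-400":
        return 1.0 / (1.0 + 10.0 ** (-d / 400.0))
    if kind == "normal-cdf":
        return ndtr(d / (200.0 * np.sqrt(2.0)))
    raise ConfigError(f"expected_score: unknown kind {kind!r}")


def _day(date) -> int:
    return (pd.Timestamp(date) - _EPOCH).days


def _check_presence_frame(presence: pd.DataFrame) -> pd.DataFrame:
    required = {"male", "group", "entry", "exit"}
    missing = required - set(presence.columns)
    if missing:
        raise DataError(f"presence table lacks columns {sorted(missing)}")
    out = presence.copy()
    for col in ("entry", "exit"):
        out[col] = pd.to_datetime(out[col])
    if "birth_date" in out.columns:
        out["birth_date"] = pd.to_datetime(out["birth_date"])
    if out["male"].duplicated().any():
        dupes = out.loc[out["male"].duplicated(), "male"].tolist()
        raise DataError(f"presence table has duplicate male ids: {dupes}")
    return out.set_index("male", drop=False)


class EloTrajectories:
    """Per-male date-indexed rating series produced by :func:`compute_trajectories`.

    Presence intervals are inclusive on both ends. Queries outside a male's
    presence raise :class:`RatingLookupError`.
    """

    def __init__(self, params: EloParams, presence: pd.DataFrame,
                 updates: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.params = params
        self.presence = presence  # indexed by male
        self._updates = updates
        self._bounds = {
            m: (_day(e), _day(x))
            for m, e, x in zip(presence.index, presence["entry"],
                               presence["exit"])
        }

    @property
    def males(self) -> list[str]:
        return list(self.presence.index)

    def _presence_days(self, male: str) -> tuple[int, int]:
        try:
            return self._bounds[male]
        except KeyError:
            raise RatingLookupError(f"unknown male {male!r}") from None

    def rating_at(self, male: str, date) -> float:
        """Rating of ``male`` on ``date`` (carry-forward; post-update on update days)."""
        d = _day(date)
        entry, exit_ = self._presence_days(male)
        if not (entry <= d <= exit_):
            raise RatingLookupError(
                f"date {pd.Timestamp(date).date()} outside presence of {male!r} "
                f"({self.presence.loc[male, 'entry'].date()}.."
                f"{self.presence.loc[male, 'exit'].date()})")
        days, ratings = self._updates.get(male, (np.empty(0, int), np.empty(0)))
        i = np.searchsorted(days, d, side="right")
        if i == 0:
            return float(self.params.start_value)
        return float(ratings[i - 1])

    def males_present(self, group: str, date) -> list[str]:
        d = _day(date)
        p = self.presence
        mask = ((p["group"] == group)
                & (p["entry"].values.astype("datetime64[D]").astype(int) <= d)
                & (p["exit"].values.astype("datetime64[D]").astype(int) >= d))
        return list(p.index[mask])

    def ratings_on(self, group: str, date) -> pd.Series:
        """Ratings of all males co-resident in ``group`` on ``date``."""
        males = self.males_present(group, date)
        return pd.Series({m: self.rating_at(m, date) for m in males}, dtype=float)

    def ratings_frame(self, group: str, dates) -> pd.DataFrame:
        """Ratings of the group's males over a date range (vectorized).

        Returns a DataFrame indexed by date with one column per male who is
        present on at least one of the dates; entries are NaN outside a
        male's presence interval.
        """
        dates = pd.DatetimeIndex(dates)
        days = ((dates - _EPOCH) // pd.Timedelta(days=1)).to_numpy()
        p = self.presence[self.presence["group"] == group]
        out = {}
        for male in p.index:
            entry, exit_ = self._presence_days(male)
            if days[-1] < entry or days[0] > exit_:
                continue
            upd_days, upd_ratings = self._updates.get(
                male, (np.empty(0, int), np.empty(0)))
            idx = np.searchsorted(upd_days, days, side="right")
            vals = np.where(idx == 0, self.params.start_value,
                            np.concatenate(([np.nan], upd_ratings))[idx])
            vals = np.where((days >= entry) & (days <= exit_), vals, np.nan)
            out[male] = vals
        return pd.DataFrame(out, index=dates)

    def standardized_on(self, group: str, date) -> pd.Series:
        """Min-max standardized ratings of co-resident males (highest 1, lowest 0)."""
        return standardize(self.ratings_on(group, date))

    def future_ratings(self, male: str, event_date, step: int = 10,
                       horizon: int = 120) -> pd.DataFrame:
        """Ratings at offsets 0, step, ..., horizon days after ``event_date``.

        Offsets after the male leaves the group carry a missing rating and
        ``present=False``; they are never imputed.
        """
        if step <= 0 or horizon < step:
            raise ConfigError("future_ratings: need step > 0 and horizon >= step")
        d0 = _day(event_date)
        entry, exit_ = self._presence_days(male)
        if not (entry <= d0 <= exit_):
            raise RatingLookupError(
                f"event date {pd.Timestamp(event_date).date()} outside presence of {male!r}")
        offsets = np.arange(0, horizon + 1, step)
        rows = []
        for off in offsets:
            d = d0 + int(off)
            if entry <= d <= exit_:
                rows.append((int(off), self.rating_at(male, _EPOCH + pd.Timedelta(days=d)),
                             True))
            else:
                rows.append((int(off), np.nan, False))
        return pd.DataFrame(rows, columns=["offset", "rating", "present"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (male, date, rating) table of every recorded update."""
        parts = []
        for male in self.males:
            days, ratings = self._updates.get(male, (np.empty(0, int), np.empty(0)))
            entry, _ = self._presence_days(male)
            # include the initialization point at entry
            all_days = np.concatenate(([entry], days))
            all_ratings = np.concatenate(([self.params.start_value], ratings))
            parts.append(pd.DataFrame({
                "male": male,
                "date": _EPOCH + pd.to_timedelta(all_days, unit="D"),
                "rating": all_ratings,
            }))
        if not parts:
            return pd.DataFrame(columns=["male", "date", "rating"])
        return pd.concat(parts, ignore_index=True)


def compute_trajectories(interactions: pd.DataFrame, presence: pd.DataFrame,
                         params: EloParams | None = None) -> EloTrajectories:
    """Run the sequential Elo system over a decided-contest table.

    ``interactions`` needs columns ``date``, ``winner``, ``loser`` (``group`` is
    carried through if present). Rows are processed in date order; within a
    day, input order is preserved (stable sort). Every male in the presence
    table starts at ``params.start_value`` upon entry.
    """
    params = params or EloParams()
    pres = _check_presence_frame(presence)
    updates: dict[str, list[tuple[int, float]]] = {m: [] for m in pres.index}
    current: dict[str, float] = {m: params.start_value for m in pres.index}

    if len(interactions):
        inter = interactions.copy()
        inter["date"] = pd.to_datetime(inter["date"])
        inter = inter.sort_values("date", kind="stable").reset_index()
        entry_day = {m: _day(pres.loc[m, "entry"]) for m in pres.index}
        exit_day = {m: _day(pres.loc[m, "exit"]) for m in pres.index}
        for row in inter.itertuples(index=False):
            w, l = row.winner, row.loser
            if w == l:
                raise DataError(f"interaction row {row.index}: winner == loser ({w!r})")
            d = _day(row.date)
            for m in (w, l):
                if m not in current:
                    raise DataError(f"interaction row {row.index}: unknown male {m!r}")
                if not (entry_day[m] <= d <= exit_day[m]):
                    raise DataError(
                        f"interaction row {row.index}: {m!r} not present on "
                        f"{row.date.date()}")
            e = float(expected_score(current[w] - current[l], params.expected_score))
            delta = params.k * (1.0 - e)
            current[w] += delta
            current[l] -= delta
            updates[w].append((d, current[w]))
            updates[l].append((d, current[l]))

    packed = {
        m: (np.array([d for d, _ in ups], dtype=int),
            np.array([r for _, r in ups], dtype=float))
        for m, ups in updates.items() if ups
    }
    return EloTrajectories(params, pres, packed)


def standardize(ratings: pd.Series) -> pd.Series:
    """Min-max standardize ratings among co-resident males: highest 1, lowest 0.

    Requires at least two males and a non-degenerate range; order-preserving
    and idempotent on inputs already spanning [0, 1].
    """
    if len(ratings) < 2:
        raise StandardizationError(
            f"standardization needs >= 2 co-resident males, got {len(ratings)}")
    lo, hi = float(ratings.min()), float(ratings.max())
    if hi == lo:
        raise StandardizationError("all ratings equal: standardized rating undefined")
    return (ratings - lo) / (hi - lo)
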
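"""Control variables: hierarchy stability, male competition, aggression rate, age.

The stability index is an inversion-count measure on ordinal ranks: over a
trailing window it averages, across consecutive day-pairs, the fraction of
male pairs whose rank order flips between the two days, and returns one minus
that mean. S = 1 means the ordinal hierarchy never changed within the window;
S = 0 means every pair flipped every day. Because it uses ordinal ranks only,
S is invariant under any strictly monotone transform of the ratings.

The competition index defaults to the adult-male headcount on the date — the
simplest reading of male competition; a callable can be supplied for variants
(e.g. males per fertile female) when the data support them.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._exceptions import CovariateError
from .elo import EloTrajectories

DAY = pd.Timedelta(days=1)


def stability_index(trajectories: EloTrajectories, group: str, date,
                    window: int = 30) -> float:
    """Hierarchy stability S in [0, 1] over the ``window`` days ending at ``date``.

    For each of the ``window - 1`` consecutive day-pairs, the males present on
    both days are ranked by rating and the fraction of discordant male pairs
    (out of n*(n-1)/2) is counted; S is one minus the mean fraction. If the
    window extends before the first presence date it is truncated with a
    warning.
    """
    date = pd.Timestamp(date)
    first = trajectories.presence["entry"].min()
    start = date - (window - 1) * DAY
    if start < first:
        warnings.warn(
            f"stability window truncated at first data date {first.date()}",
            stacklevel=2)
        start = first
    days = pd.date_range(start, date, freq="D")
    if len(days) < 2:
        raise CovariateError("stability window too short after truncation")

    R = trajectories.ratings_frame(group, days).to_numpy()
    fractions = []
    for t in range(len(days) - 1):
        both = np.isfinite(R[t]) & np.isfinite(R[t + 1])
        n = int(both.sum())
        if n < 2:
            raise CovariateError(
                f"stability index needs >= 2 co-resident males throughout; "
                f"only {n} present on both {days[t].date()} and "
                f"{days[t + 1].date()}")
        a = R[t, both]
        b = R[t + 1, both]
        s0 = np.sign(a[:, None] - a[None, :])
        s1 = np.sign(b[:, None] - b[None, :])
        inversions = int(np.sum((s0 * s1) < 0)) // 2
        fractions.append(inversions / (n * (n - 1) / 2))
    return float(1.0 - np.mean(fractions))


def competition_index(presence: pd.DataFrame, group: str, date,
                      variant=None) -> float:
    """Male competition index: co-resident adult-male headcount by default.

    ``variant`` accepts a callable ``(presence, group, date) -> float`` for
    alternative definitions (e.g. males per fertile female) when the data
    support them; the default headcount is the simplest reading.
    """
    date = pd.Timestamp(date)
    sub = presence[presence["group"] == group]
    mask = (pd.to_datetime(sub["entry"]) <= date) & (pd.to_datetime(sub["exit"]) >= date)
    n = int(mask.sum())
    if n < 1:
        raise CovariateError(f"no adult males present in {group} on {date.date()}")
    if variant is not None:
        return float(variant(presence, group, date))
    return n


def aggression_rate(focal: pd.DataFrame, male: str, date,
                    window: int = 30) -> float:
    """Aggressive events per focal hour over the ``window`` days ending at ``date``.

    Zero observation effort yields a missing value (NaN), never zero: an
    unobserved male has an unknown rate, not a rate of zero.
    """
    date = pd.Timestamp(date)
    start = date - (window - 1) * DAY
    dates = (focal["date"]
             if pd.api.types.is_datetime64_any_dtype(focal["date"])
             else pd.to_datetime(focal["date"]))
    sub = focal[(focal["male"] == male) & (dates >= start) & (dates <= date)]
    hours = float(sub["duration_min"].sum()) / 60.0
    if hours <= 0:
        warnings.warn(f"no focal effort on {male} in window ending {date.date()}; "
                      "aggression rate missing", stacklevel=2)
        return float("nan")
    return float(sub["n_aggressive_events"].sum()) / hours


def age_at(presence: pd.DataFrame, male: str, date) -> float:
    """Age in years: (date - birth_date) / 365.25; NaN when birth date unknown."""
    pres = presence.set_index("male") if "male" in presence.columns else presence
    if male not in pres.index:
        raise CovariateError(f"unknown male {male!r}")
    birth = pres.loc[male].get("birth_date", pd.NaT)
    if pd.isna(birth):
        warnings.warn(f"birth date missing for {male}; age missing", stacklevel=2)
        return float("nan")
    return (pd.Timestamp(date) - pd.Timestamp(birth)).days / 365.25
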
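"""Assembly of the long-format analysis tables.

The rank table links each coalition event to multiple future time points:
every male involved in an event contributes one row per 10-day offset from 10
to 120 days after the event, for as long as he remains resident (rows for
offsets after emigration are dropped, never imputed). The response is the raw
Elo rating at the future date; the day-0 rating enters only as the
"current rank" control. Numeric predictors are z-scored on the assembled
table (the raw columns are retained alongside).

The paternity table holds one row per candidate male x infant, candidates
being the males present on at least one day of the 11-day window centred on
the estimated conception date; the rating is the mean of the daily
standardized ratings over the days present.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DataError
from .coalition import CoalitionEvent, assign_roles
from .covariates import age_at, aggression_rate, competition_index, stability_index
from .elo import EloTrajectories

logger = logging.getLogger(__name__)

DAY = pd.Timedelta(days=1)

#: numeric predictors that get z-scored copies (suffix ``_z``)
ZSCORE_COLUMNS = {
    "feasibility": "feas_z",
    "days_since": "days_z",
    "day0_rating": "day0_z",
    "age": "age_z",
    "aggr_rate": "aggr_z",
    "stability": "stab_z",
    "competition": "comp_z",
}

RANK_TABLE_COLUMNS = [
    "event_id", "male", "role", "configuration", "feasibility", "days_since",
    "future_rating", "group", "day0_rating", "age", "aggr_rate", "stability",
    "competition", "autocorr",
] + list(ZSCORE_COLUMNS.values())


def zscore(x: pd.Series, name: str = "") -> pd.Series:
    """(x - mean) / SD with ddof 0; a zero-variance column maps to zeros with
    a logged warning rather than NaN (a constant carries no information)."""
    x = pd.to_numeric(x, errors="coerce")
    mu = x.mean()
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        logger.warning("z-score: column %s has zero variance; set to 0", name)
        return pd.Series(np.zeros(len(x)), index=x.index)
    return (x - mu) / sd


def build_rank_dataset(events: list[CoalitionEvent],
                       metrics: pd.DataFrame,
                       trajectories: EloTrajectories,
                       presence: pd.DataFrame,
                       focal: pd.DataFrame | None = None,
                       step: int = 10, horizon: int = 120,
                       stability_window: int = 30,
                       aggression_window: int = 30,
                       standardize_response: bool = False) -> pd.DataFrame:
    """Assemble the event x male x future-offset table.

    ``metrics`` is the per-event table from :func:`coalition.event_metrics`;
    events missing from it (excluded there) are skipped with a logged reason.
    The response is the raw future Elo rating; ``standardize_response``
    switches it to the within-group standardized rating at the future date
    (undefined days become missing).
    """
    if step <= 0 or horizon < step:
        raise ConfigError("build_rank_dataset: need step > 0 and horizon >= step")
    met = metrics.set_index("event_id")
    if focal is not None and len(focal):
        focal = focal.assign(date=pd.to_datetime(focal["date"]))
        focal_by_male = {m: sub for m, sub in focal.groupby("male")}
    else:
        focal_by_male = {}
    empty_focal = pd.DataFrame(columns=["male", "date", "duration_min",
                                        "n_aggressive_events"])
    stab_cache: dict[tuple[str, pd.Timestamp], float] = {}
    comp_cache: dict[tuple[str, pd.Timestamp], int] = {}
    rows = []
    for ev in events:
        if ev.event_id not in met.index:
            logger.warning("event %s absent from metrics table; skipped", ev.event_id)
            continue
        roles = assign_roles(ev, presence)
        m = met.loc[ev.event_id]
        key = (ev.group, ev.date)
        if key not in stab_cache:
            stab_cache[key] = stability_index(trajectories, ev.group, ev.date,
                                              window=stability_window)
            comp_cache[key] = competition_index(presence, ev.group, ev.date)
        for male, role in roles.items():
            day0 = trajectories.rating_at(male, ev.date)
            age = age_at(presence, male, ev.date)
            if focal is not None and len(focal):
                sub = focal_by_male.get(male, empty_focal)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    aggr = aggression_rate(sub, male, ev.date,
                                           window=aggression_window)
            else:
                aggr = np.nan
            future = trajectories.future_ratings(male, ev.date, step=step,
                                                 horizon=horizon)
            for rec in future.itertuples(index=False):
                if rec.offset == 0 or not rec.present:
                    continue
                response = rec.rating
                if standardize_response:
                    fut_date = ev.date + pd.Timedelta(days=int(rec.offset))
                    try:
                        response = float(
                            trajectories.standardized_on(ev.group,
                                                         fut_date)[male])
                    except Exception:  # degenerate standardization
                        response = np.nan
                rows.append({
                    "event_id": ev.event_id, "male": male, "role": role,
                    "configuration": m["configuration"],
                    "feasibility": m["feasibility"],
                    "days_since": int(rec.offset),
                    "future_rating": response,
                    "group": ev.group, "day0_rating": day0, "age": age,
                    "aggr_rate": aggr, "stability": stab_cache[key],
                    "competition": comp_cache[key], "autocorr": 0.0,
                })
    df = pd.DataFrame(rows, columns=[c for c in RANK_TABLE_COLUMNS
                                     if not c.endswith("_z")])
    return _attach_zscores(df)


def _attach_zscores(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for raw, z in ZSCORE_COLUMNS.items():
        if raw in df.columns:
            df[z] = zscore(df[raw], raw) if len(df) else pd.Series(dtype=float)
    return df


def build_paternity_dataset(conceptions: pd.DataFrame,
                            trajectories: EloTrajectories,
                            presence: pd.DataFrame,
                            window: int = 11,
                            stability_window: int = 30) -> pd.DataFrame:
    """Assemble the candidate-male x infant paternity table.

    ``conceptions`` is either the long per-candidate table (with a ``sired``
    column) produced by the generator or the condensed one-row-per-infant form
    whose ``sire`` field names the sire(s), ';'-separated, blank when unknown.
    """
    if window % 2 == 0:
        raise ConfigError("conception window length must be odd")
    half = window // 2
    if "sired" in conceptions.columns:
        infants = conceptions[["infant", "group", "conception_date"]].drop_duplicates()
        sire_sets = {
            inf: set(sub.loc[sub["sired"] == 1, "male"])
            for inf, sub in conceptions.groupby("infant")
        }
    else:
        infants = conceptions[["infant", "group", "conception_date"]]
        sire_sets = {
            rec.infant: set(str(rec.sire).split(";")) if isinstance(rec.sire, str)
            and rec.sire else set()
            for rec in conceptions.itertuples(index=False)
        }
    pres = presence.set_index("male", drop=False)
    for c in ("entry", "exit"):
        pres[c] = pd.to_datetime(pres[c])
    rows = []
    for rec in infants.itertuples(index=False):
        date = pd.Timestamp(rec.conception_date)
        window_days = [date + off * DAY for off in range(-half, half + 1)]
        candidates = sorted({m for d in window_days
                             for m in trajectories.males_present(rec.group, d)})
        if not candidates:
            raise DataError(
                f"no candidate males for infant {rec.infant} in the window "
                f"around {date.date()}")
        stab = stability_index(trajectories, rec.group, date,
                               window=stability_window)
        comp = competition_index(presence, rec.group, date)
        daily = []
        for d in window_days:
            try:
                daily.append(trajectories.standardized_on(rec.group, d))
            except Exception:
                continue
        for male in candidates:
            vals = [s[male] for s in daily if male in s.index]
            rating = float(np.mean(vals)) if vals else np.nan
            mid_date = min(max(date, pres.loc[male, "entry"]), pres.loc[male, "exit"])
            rows.append({
                "infant": rec.infant, "male": male, "rating": rating,
                "sired": int(male in sire_sets.get(rec.infant, set())),
                "group": rec.group, "conception_date": date,
                "age": age_at(presence, male, mid_date),
                "stability": stab, "competition": comp,
            })
    df = pd.DataFrame(rows)
    if len(df):
        for raw, z in (("rating", "rating_z"), ("age", "age_z"),
                       ("stability", "stab_z"), ("competition", "comp_z")):
            df[z] = zscore(df[raw], raw)
    return df


def add_autocorrelation_term(rank_table: pd.DataFrame,
                             residuals: np.ndarray | pd.Series) -> pd.DataFrame:
    """Fill the ``autocorr`` column from first-pass residuals.

    For each row, the term is the weighted mean of the same male's residuals
    at the *other* offsets of the same event, with weights
    1 / (1 + |offset difference| / 10). Rows with no neighbours get 0.
    """
    res = np.asarray(residuals, dtype=float)
    if len(res) != len(rank_table):
        raise DataError("residual vector length does not match the rank table")
    out = rank_table.copy()
    term = np.zeros(len(out))
    dt = out["days_since"].to_numpy(dtype=float)
    for _, idx in out.groupby(["event_id", "male"], sort=False).indices.items():
        if len(idx) < 2:
            continue
        d = dt[idx]
        r = res[idx]
        ok = np.isfinite(r)
        for pos, i in enumerate(idx):
            w = 1.0 / (1.0 + np.abs(d - d[pos]) / 10.0)
            w[pos] = 0.0
            w[~ok] = 0.0
            total = w.sum()
            term[i] = float(np.dot(w[ok], r[ok]) / total) if total > 0 else 0.0
    out["autocorr"] = term
    return out
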
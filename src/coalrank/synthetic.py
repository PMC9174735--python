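"""Synthetic study-population generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two groups of adult males (headcount held inside a 7-18 band) with
ongoing migration, latent strength following a per-male baseline plus slow
AR(1) drift, decided dyadic contests whose winner is logistic in the strength
difference, rare coalition events drawn from an all-down/bridging/all-up
mixture whose participants and target are picked by current rating order, and
conceptions whose per-candidate siring probability is logit-linear in
window-mean standardized rating.

Coalition events inject *transient* strength effects: the target loses
``target_effect * g(feasibility)`` strength units, each participant gains
``participant_effect``, and both perturbations decay linearly to zero over the
decay horizon. Latent strength is the generative truth; Elo ratings computed
downstream are estimates of it, so recovery tests compare against the injected
effects, never against latent strength directly.

The outcome re-draw trick: contest schedules depend only on presence and the
encounter rate, so re-running :func:`simulate_agonism` with the same seed on
the perturbed population yields the *same* contest schedule with outcomes
flipped exactly where the injected effects tip the scales. With zero injected
effects the regenerated table is identical to the baseline table.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._exceptions import ConfigError, GenerationError
from .coalition import CoalitionEvent, compute_feasibility
from .config import (AgonismConfig, CoalitionSimConfig, EloParams, FocalSimConfig,
                     PaternitySimConfig, PopulationConfig, config_to_dict)
from .elo import compute_trajectories, standardize

logger = logging.getLogger(__name__)

DAY = pd.Timedelta(days=1)


@dataclass
class Population:
    """A simulated population: presence intervals plus latent strength series.

    ``strength`` is a (study_days, n_males) array, NaN outside presence;
    column order matches ``males``.
    """

    config: PopulationConfig
    presence: pd.DataFrame  # male, group, entry, exit, birth_date (Timestamps)
    males: list[str]
    strength: np.ndarray
    start_date: pd.Timestamp

    _col: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._col = {m: i for i, m in enumerate(self.males)}
        self._entry = {}
        self._exit = {}
        for row in self.presence.itertuples(index=False):
            self._entry[row.male] = self.day_index(row.entry)
            self._exit[row.male] = self.day_index(row.exit)

    @property
    def study_days(self) -> int:
        return self.strength.shape[0]

    def day_index(self, date) -> int:
        return (pd.Timestamp(date) - self.start_date).days

    def date_of(self, day: int) -> pd.Timestamp:
        return self.start_date + day * DAY

    def present_on(self, male: str, day: int) -> bool:
        return self._entry[male] <= day <= self._exit[male]

    def males_present(self, group: str, day: int) -> list[str]:
        sub = self.presence[self.presence["group"] == group]
        return [m for m in sub["male"] if self.present_on(m, day)]

    def strength_of(self, male: str) -> np.ndarray:
        return self.strength[:, self._col[male]]

    def with_strength(self, strength: np.ndarray) -> "Population":
        return Population(self.config, self.presence, self.males, strength,
                          self.start_date)

    def strength_frame(self) -> pd.DataFrame:
        idx = pd.date_range(self.start_date, periods=self.study_days, freq="D")
        return pd.DataFrame(self.strength, index=idx, columns=self.males)


def generate_population(cfg: PopulationConfig) -> Population:
    """Simulate demography and latent strength; deterministic given cfg.seed.

    Migration is exit plus entry of a brand-new identity. Exits are blocked at
    the lower band edge and entries at the upper one, so the adult-male
    headcount per group-day stays inside ``cfg.male_band``.
    """
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_date)
    D = cfg.study_days
    lo, hi = cfg.male_band

    records = []  # (male, group, entry_day, exit_day, birth_day, baseline)
    rec_index: dict[str, list] = {}
    counters: dict[str, int] = {}

    def new_male(group: str, entry_day: int):
        counters[group] = counters.get(group, 0) + 1
        male = f"{group}M{counters[group]:03d}"
        age = rng.uniform(*cfg.entry_age_range)
        birth_day = entry_day - int(round(age * 365.25))
        baseline = rng.normal(0.0, 1.0)
        rec = [male, group, entry_day, D - 1, birth_day, baseline]
        records.append(rec)
        rec_index[male] = rec
        return male

    present: dict[str, list[str]] = {}
    for g in range(cfg.n_groups):
        group = f"G{g + 1}"
        present[group] = [new_male(group, 0) for _ in range(cfg.adult_males_per_group)]
    for day in range(1, D):
        for group in sorted(present):
            roster = present[group]
            # exits (blocked at the lower band edge)
            exit_draws = rng.random(len(roster))
            for male, u in zip(list(roster), exit_draws):
                if u < cfg.migration_rate and len(roster) > lo:
                    rec_index[male][3] = day - 1
                    roster.remove(male)
            # entries (blocked at the upper band edge)
            n_arrive = rng.poisson(cfg.migration_rate * len(roster))
            for _ in range(n_arrive):
                if len(roster) < hi:
                    roster.append(new_male(group, day))

    males = [r[0] for r in records]
    strength = np.full((D, len(males)), np.nan)
    for j, (male, group, entry, exit_, birth, baseline) in enumerate(records):
        span = exit_ - entry + 1
        z = np.empty(span)
        if cfg.strength_sd == 0:
            z[:] = 0.0
        else:
            z[0] = rng.normal(0.0, cfg.strength_sd)
            innov_sd = cfg.strength_sd * np.sqrt(1.0 - cfg.strength_ar1 ** 2)
            eps = rng.normal(0.0, 1.0, size=span - 1) * innov_sd if span > 1 else []
            for t in range(1, span):
                z[t] = cfg.strength_ar1 * z[t - 1] + eps[t - 1]
        strength[entry:exit_ + 1, j] = baseline + z

    presence = pd.DataFrame({
        "male": males,
        "group": [r[1] for r in records],
        "entry": [start + r[2] * DAY for r in records],
        "exit": [start + r[3] * DAY for r in records],
        "birth_date": [start + r[4] * DAY for r in records],
    })
    return Population(cfg, presence, males, strength, start)


def simulate_agonism(pop: Population, cfg: AgonismConfig = AgonismConfig(),
                     seed: int = 0) -> pd.DataFrame:
    """Draw decided dyadic contests.

    Per co-resident dyad-day an encounter occurs with probability
    ``encounter_rate``; the higher-indexed male's win probability is logistic
    in the strength difference over ``tau``. The random-number stream depends
    only on presence and the encounter rate, never on strength, so the same
    seed on a perturbed copy of the population reproduces the same schedule.
    """
    rng = np.random.default_rng(seed)
    rows = []
    groups = sorted(pop.presence["group"].unique())
    for day in range(pop.study_days):
        date = pop.date_of(day)
        for group in groups:
            males = sorted(pop.males_present(group, day))
            if len(males) < 2:
                continue
            dyads = list(itertools.combinations(males, 2))
            u_enc = rng.random(len(dyads))
            u_win = rng.random(len(dyads))
            for (a, b), ue, uw in zip(dyads, u_enc, u_win):
                if ue >= cfg.encounter_rate:
                    continue
                sa = pop.strength_of(a)[day]
                sb = pop.strength_of(b)[day]
                p_a = expit((sa - sb) / cfg.tau)
                winner, loser = (a, b) if uw < p_a else (b, a)
                rows.append((date, group, winner, loser))
    return pd.DataFrame(rows, columns=["date", "group", "winner", "loser"])


def _truncated_geometric_pmf(mean: float, max_size: int) -> np.ndarray:
    """Participant-count distribution on {2..max_size} with the given mean."""
    ks = np.arange(2, max_size + 1)

    def mean_at(p):
        w = (1 - p) ** (ks - 2) * p
        return float((ks * w).sum() / w.sum())

    p = brentq(lambda p: mean_at(p) - mean, 1e-9, 1 - 1e-9)
    w = (1 - p) ** (ks - 2) * p
    return w / w.sum()


def simulate_coalitions(pop: Population, interactions: pd.DataFrame,
                        cfg: CoalitionSimConfig = CoalitionSimConfig(),
                        seed: int = 0,
                        elo_params: EloParams | None = None):
    """Draw coalition events and inject their transient strength effects.

    Events occur per group-day with probability ``event_rate`` (after a
    burn-in of ``min_day`` days so ratings carry information). Participants
    and target are chosen by current Elo-rating order, computed from the
    supplied interaction table, to realize the configuration drawn from
    ``cfg.mix``; when the drawn configuration is impossible on that day (e.g.
    bridging with the target at an extreme rank) the configuration is
    redrawn from the feasible set.

    Returns ``(events, roles, perturbed_population, truth_records)``.
    """
    rng = np.random.default_rng(seed)
    traj = compute_trajectories(interactions, pop.presence, elo_params)
    groups = sorted(pop.presence["group"].unique())
    max_present = max(
        (len(pop.males_present(g, d)) for g in groups for d in range(pop.study_days)),
        default=0)
    if max_present < 3:
        raise GenerationError(
            "coalition generation needs >= 3 co-resident males on some day; "
            f"max observed was {max_present}")

    size_pmf = _truncated_geometric_pmf(cfg.mean_size, cfg.max_size)
    size_values = np.arange(2, cfg.max_size + 1)
    config_names = np.array(["all-down", "bridging", "all-up"])

    perturbation = np.zeros_like(pop.strength)
    events: list[CoalitionEvent] = []
    truth: list[dict] = []
    H = cfg.decay_horizon
    eid = 0

    for day in range(cfg.min_day, pop.study_days):
        for group in groups:
            if rng.random() >= cfg.event_rate:
                continue
            males = sorted(pop.males_present(group, day))
            n = len(males)
            if n < 3:
                continue
            date = pop.date_of(day)
            ratings = {m: traj.rating_at(m, date) for m in males}
            # strict rating order, ties broken by id: index 0 = lowest rated
            order = sorted(males, key=lambda m: (ratings[m], m))
            size = int(rng.choice(size_values, p=size_pmf))
            size = min(size, n - 1)
            if cfg.select_by_rating:
                config = str(rng.choice(config_names, p=np.asarray(cfg.mix)))
                if config == "bridging" and not (n >= 3 and size >= 2):
                    config = str(rng.choice(["all-down", "all-up"]))
                if config == "all-down":
                    t_idx = int(rng.integers(0, n - size))
                    above = order[t_idx + 1:]
                    participants = list(rng.choice(above, size=size, replace=False))
                elif config == "all-up":
                    t_idx = int(rng.integers(size, n))
                    below = order[:t_idx]
                    participants = list(rng.choice(below, size=size, replace=False))
                else:  # bridging: >= 1 participant on each side of the target
                    t_idx = int(rng.integers(1, n - 1))
                    n_below, n_above = t_idx, n - 1 - t_idx
                    size = min(size, n_below + n_above)
                    k_lo = max(1, size - n_above)
                    k_hi = min(size - 1, n_below)
                    k_below = int(rng.integers(k_lo, k_hi + 1))
                    participants = (list(rng.choice(order[:t_idx], size=k_below,
                                                    replace=False))
                                    + list(rng.choice(order[t_idx + 1:],
                                                      size=size - k_below,
                                                      replace=False)))
                target = order[t_idx]
            else:
                # neutral world: members and roles uniformly at random; the
                # configuration is whatever the rating order classifies
                members = list(rng.choice(males, size=size + 1, replace=False))
                target = members[int(rng.integers(size + 1))]
                participants = [m for m in members if m != target]
                t_rank = order.index(target)
                p_ranks = [order.index(p) for p in participants]
                if all(r < t_rank for r in p_ranks):
                    config = "all-up"
                elif all(r > t_rank for r in p_ranks):
                    config = "all-down"
                else:
                    config = "bridging"

            eid += 1
            event = CoalitionEvent(event_id=f"E{eid:04d}", date=date, group=group,
                                   participants=tuple(sorted(participants)),
                                   targets=(target,))
            events.append(event)

            s = standardize(pd.Series(ratings))
            f = compute_feasibility(event, s)
            if config == "all-up":
                g_mod = max(0.1, 1.0 + cfg.feasibility_modulation * f)
            else:
                g_mod = 1.0
            decay = np.maximum(0.0, 1.0 - np.arange(pop.study_days - day) / H)
            tcol = pop._col[target]
            perturbation[day:, tcol] -= cfg.target_effect * g_mod * decay
            for p_male in participants:
                perturbation[day:, pop._col[p_male]] += cfg.participant_effect * decay
            truth.append({
                "event_id": event.event_id, "date": str(date.date()), "group": group,
                "configuration": config, "feasibility": f, "g_modulation": g_mod,
                "target": target, "participants": list(event.participants),
                "participant_effect": cfg.participant_effect,
                "target_effect": cfg.target_effect * g_mod,
            })

    perturbed = pop.with_strength(pop.strength + perturbation)
    roles = _roles_frame(events)
    return events, roles, perturbed, truth


def _roles_frame(events: list[CoalitionEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        for m in ev.participants:
            rows.append((ev.event_id, ev.date, ev.group, "participant", m))
        for m in ev.targets:
            rows.append((ev.event_id, ev.date, ev.group, "target", m))
    return pd.DataFrame(rows, columns=["event_id", "date", "group", "role", "male"])


def simulate_focal(pop: Population, cfg: FocalSimConfig = FocalSimConfig(),
                   seed: int = 0) -> pd.DataFrame:
    """Focal-observation protocols: per male-day, a 20-60 min protocol with
    probability ``focal_prob``; aggressive-event counts are Poisson in the
    male's latent aggressiveness times observed hours."""
    rng = np.random.default_rng(seed)
    rate = {m: cfg.base_rate * rng.lognormal(0.0, cfg.rate_log_sd)
            for m in sorted(pop.males)}
    rows = []
    for day in range(pop.study_days):
        for male in pop.males:
            if not pop.present_on(male, day):
                continue
            if rng.random() < cfg.focal_prob:
                dur = rng.uniform(*cfg.duration_range)
                n_events = rng.poisson(rate[male] * dur / 60.0)
                rows.append((male, pop.date_of(day), round(dur, 1), int(n_events)))
    return pd.DataFrame(rows, columns=["male", "date", "duration_min",
                                       "n_aggressive_events"])


def simulate_conceptions(pop: Population, trajectories,
                         cfg: PaternitySimConfig = PaternitySimConfig(),
                         seed: int = 0, window: int = 11) -> pd.DataFrame:
    """Draw conception events and per-candidate sire indicators.

    Candidates are the males present on the conception date; each candidate's
    window-mean standardized rating enters a Bernoulli sire indicator with
    logit = intercept + slope * rating + male random intercept. Returns a long
    table (infant, group, conception_date, male, rating, sired).
    """
    rng = np.random.default_rng(seed)
    half = window // 2
    u_male = {m: rng.normal(0.0, cfg.male_re_sd) for m in sorted(pop.males)}
    groups = sorted(pop.presence["group"].unique())
    lo_day, hi_day = 60, pop.study_days - half - 1
    if hi_day <= lo_day:
        raise GenerationError("study too short for conception windows")
    days = np.sort(rng.integers(lo_day, hi_day + 1, size=cfg.n_conceptions))
    rows = []
    for i, day in enumerate(days, start=1):
        group = groups[int(rng.integers(len(groups)))]
        date = pop.date_of(int(day))
        candidates = sorted(pop.males_present(group, int(day)))
        if not candidates:
            raise GenerationError(
                f"no candidate males in {group} for conception window around "
                f"{date.date()}")
        ratings = _window_mean_standardized(trajectories, group, date, window,
                                            candidates)
        for male in candidates:
            s = ratings[male]
            p = expit(cfg.intercept + cfg.slope * s + u_male[male])
            rows.append((f"I{i:02d}", group, date, male, s,
                         int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["infant", "group", "conception_date",
                                       "male", "rating", "sired"])


def _window_mean_standardized(trajectories, group, date, window, candidates):
    """Mean of daily standardized ratings over the days a male is present in
    the window centred on ``date``."""
    half = window // 2
    sums = {m: 0.0 for m in candidates}
    counts = {m: 0 for m in candidates}
    for off in range(-half, half + 1):
        d = pd.Timestamp(date) + off * DAY
        try:
            s = trajectories.standardized_on(group, d)
        except Exception:  # <2 males or degenerate range that day
            continue
        for m in candidates:
            if m in s.index:
                sums[m] += s[m]
                counts[m] += 1
    return {m: (sums[m] / counts[m]) if counts[m] else np.nan for m in candidates}


def simulate_paternity_cohort(cfg: PaternitySimConfig = PaternitySimConfig(),
                              seed: int = 0) -> pd.DataFrame:
    """Stand-alone conception cohorts mirroring the paternity model's structure.

    A fixed pool of candidate males shares the cohort; each conception draws
    fresh ratings (uniform, then min-max standardized within the conception)
    and independent Bernoulli sire indicators. Used for parameter-recovery
    experiments where the full population simulation is unnecessary.
    """
    rng = np.random.default_rng(seed)
    males = [f"M{i:02d}" for i in range(1, cfg.candidates_per_conception + 1)]
    u = rng.normal(0.0, cfg.male_re_sd, size=len(males))
    rows = []
    for j in range(1, cfg.n_conceptions + 1):
        raw = rng.uniform(size=len(males))
        s = (raw - raw.min()) / (raw.max() - raw.min())
        p = expit(cfg.intercept + cfg.slope * s + u)
        sired = rng.random(len(males)) < p
        for male, si, yi in zip(males, s, sired):
            rows.append((f"I{j:02d}", male, float(si), int(yi)))
    return pd.DataFrame(rows, columns=["infant", "male", "rating", "sired"])


@dataclass
class SyntheticDataset:
    """Bundle of all generated tables plus ground truth."""

    population: Population
    interactions: pd.DataFrame
    events: list[CoalitionEvent]
    roles: pd.DataFrame
    focal: pd.DataFrame
    conceptions: pd.DataFrame  # long form, one row per candidate x infant
    truth: dict

    def conception_summary(self) -> pd.DataFrame:
        """One row per infant; sires joined with ';' (empty when none)."""
        def _sires(sub):
            return ";".join(sub.loc[sub["sired"] == 1, "male"])
        g = self.conceptions.groupby(["infant", "group", "conception_date"],
                                     sort=True)
        out = g.apply(_sires, include_groups=False).reset_index(name="sire")
        return out

    def write_tables(self, outdir) -> dict:
        """Write the five standard CSVs plus a truth.json sidecar; returns paths."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        presence = self.population.presence.copy()
        for c in ("entry", "exit", "birth_date"):
            presence[c] = presence[c].dt.strftime("%Y-%m-%d")
        tables = {
            "interactions.csv": self.interactions.assign(
                date=pd.to_datetime(self.interactions["date"]).dt.strftime("%Y-%m-%d"))
            [["date", "group", "winner", "loser"]],
            "coalitions.csv": self.roles.assign(
                date=pd.to_datetime(self.roles["date"]).dt.strftime("%Y-%m-%d"))
            [["event_id", "date", "group", "role", "male"]],
            "presence.csv": presence[["male", "group", "entry", "exit", "birth_date"]],
            "focal.csv": self.focal.assign(
                date=pd.to_datetime(self.focal["date"]).dt.strftime("%Y-%m-%d"))
            [["male", "date", "duration_min", "n_aggressive_events"]],
            "conceptions.csv": self.conception_summary().assign(
                conception_date=lambda d: pd.to_datetime(
                    d["conception_date"]).dt.strftime("%Y-%m-%d"))
            [["infant", "group", "conception_date", "sire"]],
        }
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, index=False)
            paths[name] = path
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=2, default=str))
        paths["truth.json"] = truth_path
        return paths


def generate_all(pop_cfg: PopulationConfig = PopulationConfig(),
                 agonism_cfg: AgonismConfig = AgonismConfig(),
                 coalition_cfg: CoalitionSimConfig = CoalitionSimConfig(),
                 paternity_cfg: PaternitySimConfig = PaternitySimConfig(),
                 focal_cfg: FocalSimConfig = FocalSimConfig(),
                 elo_params: EloParams | None = None,
                 seed: int | None = None) -> SyntheticDataset:
    """Generate all five input tables end to end with a single master seed.

    Stage seeds are derived deterministically from ``seed`` (default:
    ``pop_cfg.seed``). The agonism stage is run twice with the same stage
    seed: once on the baseline population (to pick coalition members by
    rating order) and once on the coalition-perturbed population, which
    re-draws the same contest schedule under the injected effects.
    """
    master = pop_cfg.seed if seed is None else seed
    sub = np.random.default_rng(master).integers(0, 2 ** 31 - 1, size=4)
    pop = generate_population(pop_cfg if seed is None else
                              _replace_seed(pop_cfg, int(sub[0])))
    baseline_inter = simulate_agonism(pop, agonism_cfg, seed=int(sub[1]))
    events, roles, perturbed, truth_events = simulate_coalitions(
        pop, baseline_inter, coalition_cfg, seed=int(sub[2]), elo_params=elo_params)
    interactions = simulate_agonism(perturbed, agonism_cfg, seed=int(sub[1]))
    focal = simulate_focal(pop, focal_cfg, seed=int(sub[3]))
    trajectories = compute_trajectories(interactions, pop.presence, elo_params)
    conceptions = simulate_conceptions(perturbed, trajectories, paternity_cfg,
                                       seed=int(sub[3]) ^ 0x5A5A)
    truth = {
        "seed": master,
        "population": config_to_dict(pop_cfg),
        "agonism": config_to_dict(agonism_cfg),
        "coalitions": config_to_dict(coalition_cfg),
        "paternity": config_to_dict(paternity_cfg),
        "events": truth_events,
    }
    return SyntheticDataset(perturbed, interactions, events, roles, focal,
                            conceptions, truth)


def _replace_seed(cfg: PopulationConfig, seed: int) -> PopulationConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)
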
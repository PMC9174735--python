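"""Configuration dataclasses for the generator, the rating engine and the pipeline.

All stochastic components take explicit seeds; a configuration plus a seed fully
determines every generated table.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ._exceptions import ConfigError

#: Plausibility band for the number of adult males per group on any day.
DEFAULT_MALE_BAND = (7, 18)


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PopulationConfig:
    """Demography and latent-strength dynamics of the simulated study population.

    Latent strength is baseline (one draw per male, SD 1 — this defines the
    strength unit) plus a slowly drifting AR(1) component with stationary
    standard deviation ``strength_sd`` and day-to-day autocorrelation
    ``strength_ar1``. Migration is modelled as exit plus entry of a new
    identity; no male returns.
    """

    n_groups: int = 2
    adult_males_per_group: int = 12
    study_days: int = 800
    migration_rate: float = 0.002  # exit events per male per day
    strength_sd: float = 0.3
    strength_ar1: float = 0.98
    seed: int = 0
    male_band: tuple[int, int] = DEFAULT_MALE_BAND
    entry_age_range: tuple[float, float] = (9.0, 20.0)  # years at entry
    start_date: str = "2020-01-01"

    def __post_init__(self) -> None:
        lo, hi = self.male_band
        _require(self.n_groups >= 1, "n_groups", "must be >= 1")
        _require(lo <= self.adult_males_per_group <= hi, "adult_males_per_group",
                 f"must lie within the plausibility band {self.male_band}")
        _require(self.study_days >= 150, "study_days",
                 "must be >= 150 so that 120-day horizons fit")
        _require(self.migration_rate >= 0, "migration_rate", "must be >= 0")
        _require(self.strength_sd >= 0, "strength_sd", "must be >= 0")
        _require(0 <= self.strength_ar1 < 1, "strength_ar1", "must be in [0, 1)")
        _require(self.entry_age_range[0] < self.entry_age_range[1],
                 "entry_age_range", "must be an increasing (lo, hi) pair")


@dataclass(frozen=True)
class AgonismConfig:
    """Dyadic contest process: encounters per co-resident dyad-day and the
    logistic scale ``tau`` mapping strength differences to win probabilities."""

    encounter_rate: float = 0.05  # decided contests per dyad-day
    tau: float = 1.0  # strength units

    def __post_init__(self) -> None:
        _require(self.encounter_rate >= 0, "encounter_rate", "must be >= 0")
        _require(self.tau > 0, "tau", "must be > 0")


@dataclass(frozen=True)
class CoalitionSimConfig:
    """Coalition event process and the transient strength effects it injects.

    ``mix`` gives the probabilities of drawing an all-down, bridging or all-up
    event (in that order). From the event day, the target's latent strength is
    reduced by ``target_effect * g(feasibility)`` and each participant's is
    raised by ``participant_effect``; both perturbations decay linearly to zero
    over ``decay_horizon`` days. For all-up events
    ``g(f) = max(0.1, 1 + feasibility_modulation * f)`` (increasing in
    feasibility); for the other configurations ``g = 1``.
    """

    event_rate: float = 0.08  # events per group per day
    # all-down, bridging, all-up — exact fractions behind the rounded 69/19/13%
    mix: tuple[float, float, float] = (88 / 128, 24 / 128, 16 / 128)
    participant_effect: float = 0.3  # strength units
    target_effect: float = 0.6  # strength units
    decay_horizon: int = 120  # days
    feasibility_modulation: float = 0.5
    mean_size: float = 2.2  # mean number of participants
    max_size: int = 6
    min_day: int = 30  # burn-in before the first event may occur
    #: choose participants/target by current rating order to realize the
    #: configuration mix (the study's structure). With False, event members
    #: and roles are drawn uniformly at random — the neutral world for null
    #: calibration, where role carries no information by construction.
    select_by_rating: bool = True

    def __post_init__(self) -> None:
        _require(abs(sum(self.mix) - 1.0) <= 1e-12, "mix", "must sum to 1")
        _require(all(p >= 0 for p in self.mix), "mix", "entries must be >= 0")
        _require(self.decay_horizon > 0, "decay_horizon", "must be > 0")
        _require(self.participant_effect >= 0, "participant_effect", "must be >= 0")
        _require(self.target_effect >= 0, "target_effect", "must be >= 0")
        _require(self.event_rate >= 0, "event_rate", "must be >= 0")
        _require(2 <= self.max_size, "max_size", "must be >= 2")
        _require(2.0 < self.mean_size < self.max_size, "mean_size",
                 f"must lie in (2, max_size={self.max_size})")


@dataclass(frozen=True)
class PaternitySimConfig:
    """Conception process: per-candidate sire indicators are Bernoulli with
    logit = intercept + slope * (window-mean standardized rating) + male
    random intercept. Indicators are independent across candidates; exactly
    one sire per conception is deliberately *not* enforced, so the generator's
    likelihood is the one the paternity model maximises.
    """

    n_conceptions: int = 19
    candidates_per_conception: int = 12
    slope: float = 1.43  # log-odds per unit standardized rating
    intercept: float = -3.1  # log-odds; ~1 expected sire per conception at default size
    male_re_sd: float = 0.2

    def __post_init__(self) -> None:
        _require(self.n_conceptions >= 1, "n_conceptions", "must be >= 1")
        _require(self.candidates_per_conception >= 2, "candidates_per_conception",
                 "must be >= 2")
        _require(self.male_re_sd >= 0, "male_re_sd", "must be >= 0")


@dataclass(frozen=True)
class FocalSimConfig:
    """Focal-observation effort: protocols of 20-60 min, with aggressive-event
    counts Poisson in each male's latent aggressiveness."""

    focal_prob: float = 0.1  # probability a male is focal-sampled on a day
    duration_range: tuple[float, float] = (20.0, 60.0)  # minutes
    base_rate: float = 0.5  # aggressive events per focal hour (geometric mean)
    rate_log_sd: float = 0.5

    def __post_init__(self) -> None:
        _require(0 <= self.focal_prob <= 1, "focal_prob", "must be in [0, 1]")
        _require(self.duration_range[0] > 0, "duration_range", "must be positive")
        _require(self.base_rate >= 0, "base_rate", "must be >= 0")


@dataclass(frozen=True)
class EloParams:
    """Sequential Elo-rating parameters.

    ``expected_score`` selects the map from rating difference to expected win
    probability: ``logistic-400`` (base-10 logistic with scale 400) or
    ``normal-cdf`` (Gaussian CDF with SD 200*sqrt(2), the classical variant).
    """

    start_value: float = 1000.0
    k: float = 100.0
    expected_score: str = "logistic-400"

    def __post_init__(self) -> None:
        _require(self.k > 0, "k", "must be > 0")
        _require(self.expected_score in ("logistic-400", "normal-cdf"),
                 "expected_score", "must be 'logistic-400' or 'normal-cdf'")


def config_to_dict(cfg) -> dict:
    """Serialize any of the configuration dataclasses to plain JSON-able data."""
    return asdict(cfg)
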
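"""Linear mixed model for future dominance status after coalition events.

The model regresses the future Elo rating on the coalition predictors — role
(participant/target), configuration (all-down/bridging/all-up), feasibility
and time distance — with the three-way role x configuration x feasibility
interaction (all lower-order terms included) and the role x time interaction,
plus control terms. The random structure crosses male identity and coalition
event identity (random intercepts) with random slopes for time distance (by
male and by event) and feasibility (by male), implemented as independent
variance components.

Fits use maximum likelihood (not REML) whenever the result feeds a
likelihood-ratio test, so full and null log-likelihoods are comparable. When
a random-slope structure fails to converge, slopes are dropped one at a time
in a documented order and the reduction is recorded on the results object.

Estimation is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`
with crossed effects expressed as variance components within a single trivial
grouping.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

from ._exceptions import FittingError, UsageError

#: order in which random slopes are dropped when a fit fails to converge
DEFAULT_REDUCTION_ORDER = ("male_feas", "event_days", "male_days", "series_days")

#: crossed random intercepts (male, event) plus the documented slope set
DEFAULT_RANDOM_STRUCTURE = {
    "male": "0 + C(male)",
    "event": "0 + C(event_id)",
    "male_days": "0 + C(male):days_z",
    "event_days": "0 + C(event_id):days_z",
    "male_feas": "0 + C(male):feas_z",
}

#: variant adding event x male series components. Role, configuration and
#: feasibility are constant within each event x male series; with strongly
#: autocorrelated responses (e.g. Elo trajectories) the series components
#: keep those predictors from absorbing series-level noise, at a substantial
#: cost in power and fitting time. See docs/methods.md.
SERIES_RANDOM_STRUCTURE = {
    **DEFAULT_RANDOM_STRUCTURE,
    "series": "0 + C(event_male)",
    "series_days": "0 + C(event_male):days_z",
}

INTERCEPTS_ONLY = {k: v for k, v in DEFAULT_RANDOM_STRUCTURE.items()
                   if k in ("male", "event")}


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Fixed-effects layout of the rank model.

    The null specification drops every term containing a main predictor
    (role, configuration, feasibility, time distance) and keeps the controls;
    the random structure is shared between full and null.
    """

    response: str = "future_rating"
    main: str = "C(role) * C(configuration) * feas_z + days_z + C(role):days_z"
    controls: tuple[str, ...] = ("C(group)", "day0_z", "age_z", "aggr_z",
                                 "stab_z", "comp_z")
    include_autocorr: bool = False

    def _control_rhs(self) -> str:
        terms = list(self.controls)
        if self.include_autocorr:
            terms.append("autocorr")
        return " + ".join(terms) if terms else "1"

    def full_formula(self) -> str:
        return f"{self.response} ~ {self.main} + {self._control_rhs()}"

    def null_formula(self) -> str:
        return f"{self.response} ~ {self._control_rhs()}"


@dataclass
class LRTResult:
    """Full-vs-null likelihood-ratio test."""

    statistic: float
    df: int
    pvalue: float

    def summary(self) -> str:
        return (f"LRT: chi2({self.df}) = {self.statistic:.2f}, "
                f"p = {self.pvalue:.4g}")


class RankTrajectoryResults:
    """Results of a rank-trajectory model fit.

    Exposes fixed-effect estimates (``params``), standard errors (``bse``),
    z statistics and p-values, the log-likelihood, variance components
    (``vcomp``), the residual variance (``scale``), and the list of random
    slopes dropped to reach convergence (``reduction``).
    """

    def __init__(self, model: "RankTrajectoryModel", smresults, structure: dict,
                 reduction: list[str], reml: bool):
        self.model = model
        self._sm = smresults
        self.structure = dict(structure)
        self.reduction = list(reduction)
        self.method = "REML" if reml else "ML"
        k = len(smresults.model.exog_names)
        self.fixed_names = list(smresults.model.exog_names)
        self.params = pd.Series(np.asarray(smresults.params)[:k],
                                index=self.fixed_names)
        self.bse = pd.Series(np.asarray(smresults.bse)[:k], index=self.fixed_names)
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(2 * stats.norm.sf(np.abs(self.tvalues)),
                                 index=self.fixed_names)
        self.llf = float(smresults.llf)
        self.scale = float(smresults.scale)
        self.vcomp = dict(zip(smresults.model.exog_vc.names,
                              np.asarray(smresults.vcomp)))
        self.converged = bool(getattr(smresults, "converged", True))
        self.nobs = int(smresults.model.nobs)
        self.df_fixed = k

    def predict(self, new_data: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (random effects at zero) on new data."""
        (X,) = patsy.build_design_matrices([self.model.design_info], new_data)
        return np.asarray(X) @ self.params.to_numpy()

    def summary(self):
        """statsmodels-style coefficient table."""
        tab = pd.DataFrame({
            "coef": self.params, "se": self.bse, "z": self.tvalues,
            "p": self.pvalues,
        })
        header = (f"Rank trajectory LMM ({self.method}), n = {self.nobs}, "
                  f"llf = {self.llf:.2f}\n"
                  f"variance components: "
                  + ", ".join(f"{k} = {v:.3g}" for k, v in self.vcomp.items())
                  + f", residual = {self.scale:.3g}\n")
        if self.reduction:
            header += f"random slopes dropped for convergence: {self.reduction}\n"
        return header + tab.to_string(float_format=lambda v: f"{v:.4f}")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "llf": self.llf,
            "scale": self.scale,
            "vcomp": self.vcomp,
            "converged": self.converged,
            "method": self.method,
            "reduction": self.reduction,
            "nobs": self.nobs,
        }


class RankTrajectoryModel:
    """Gaussian LMM for future Elo ratings after coalition events.

    Parameters
    ----------
    data : DataFrame
        The long rank table from :func:`datasets.build_rank_dataset`.
    spec : FixedEffectsSpec
        Fixed-effects layout; ``spec.full_formula()`` is fitted unless
        ``null=True``.
    random_structure : dict, optional
        Variance-component formulas (name -> patsy formula); defaults to
        crossed intercepts plus the documented random-slope set.
    null : bool
        Fit the null specification (controls and random structure only).
    """

    def __init__(self, data: pd.DataFrame, spec: FixedEffectsSpec | None = None,
                 random_structure: dict | None = None, null: bool = False):
        if len(data) < 2:
            raise UsageError("rank model needs a non-degenerate table")
        if data["event_id"].nunique() < 2 or data["male"].nunique() < 2:
            raise UsageError("rank model needs >= 2 events and >= 2 males")
        self.spec = spec or FixedEffectsSpec()
        needed = [self.spec.response, "role", "configuration", "group",
                  "feas_z", "days_z", "day0_z", "age_z", "aggr_z", "stab_z",
                  "comp_z"]
        if self.spec.include_autocorr:
            needed.append("autocorr")
        needed = [c for c in needed if c in data.columns]
        complete = data.dropna(subset=needed)
        if len(complete) < len(data):
            import logging

            logging.getLogger(__name__).warning(
                "rank model: dropped %d/%d rows with missing covariates",
                len(data) - len(complete), len(data))
        complete = complete.copy()
        complete["event_male"] = (complete["event_id"].astype(str) + ":"
                                  + complete["male"].astype(str))
        self.data = complete  # original index kept so residuals can be aligned
        self.random_structure = dict(random_structure
                                     if random_structure is not None
                                     else DEFAULT_RANDOM_STRUCTURE)
        self.null = null
        self.formula = (self.spec.null_formula() if null
                        else self.spec.full_formula())
        resp = self.data[self.spec.response].to_numpy(dtype=float)
        if np.nanstd(resp) == 0:
            raise FittingError("response is constant: residual variance would "
                               "be 0 and the model is degenerate")
        self.design_info = None  # set on fit

    def fit(self, reml: bool = False, maxiter: int = 500,
            polish: bool = True) -> RankTrajectoryResults:
        """Maximize the (restricted) likelihood.

        ``polish`` runs a second BFGS stage warm-started from the L-BFGS
        solution and keeps whichever log-likelihood is higher; the refinement
        matters when log-likelihood *differences* feed an LRT, where
        incomplete convergence of either fit biases the statistic.
        """
        structure = dict(self.random_structure)
        dropped: list[str] = []
        last_exc: Exception | None = None
        order = [k for k in DEFAULT_REDUCTION_ORDER if k in structure]
        for _ in range(len(order) + 1):
            try:
                res = self._fit_once(structure, reml, maxiter, polish)
                return RankTrajectoryResults(self, res, structure, dropped, reml)
            except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
                last_exc = exc
                slope_keys = [k for k in order if k in structure]
                if not slope_keys:
                    break
                drop = slope_keys[0]
                structure.pop(drop)
                dropped.append(drop)
        raise FittingError(
            f"rank model failed to converge even with reduced random structure "
            f"(dropped {dropped}): {last_exc}")

    def _fit_once(self, structure: dict, reml: bool, maxiter: int,
                  polish: bool = True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                self.formula, data=self.data,
                groups=np.ones(len(self.data)),
                vc_formula=structure, re_formula="0")
            self.design_info = model.data.design_info
            res = model.fit(reml=reml, method="lbfgs", maxiter=maxiter)
            if polish:
                res = polish_mixedlm_fit(model, res, reml=reml)
        if not np.isfinite(res.llf):
            raise RuntimeError("non-finite log-likelihood")
        return res


def polish_mixedlm_fit(model, res, reml: bool = False):
    """Second-stage BFGS refinement of a MixedLM fit, warm-started from the
    first solution; returns whichever result has the higher log-likelihood."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = model.fit(reml=reml, method="bfgs",
                             start_params=res.params_object)
        if np.isfinite(res2.llf) and res2.llf > res.llf:
            return res2
    except (np.linalg.LinAlgError, ValueError):
        pass
    return res


def likelihood_ratio_test(full, null) -> LRTResult:
    """Full-vs-null LRT: chi2 = 2 * (llf_full - llf_null), floored at 0.

    Degrees of freedom equal the difference in fixed-effect design-matrix
    columns. Both fits must be maximum likelihood on the same data with the
    null's fixed terms nested in the full's.
    """
    for r in (full, null):
        if getattr(r, "method", "ML") != "ML":
            raise UsageError("LRT requires ML fits, not REML")
    if full.nobs != null.nobs:
        raise UsageError("LRT requires both models fitted to the same data")
    if not set(null.fixed_names) <= set(full.fixed_names):
        raise UsageError(
            "models are not nested: null has terms absent from the full model: "
            f"{sorted(set(null.fixed_names) - set(full.fixed_names))}")
    df = full.df_fixed - null.df_fixed
    if df < 0:
        raise UsageError("the 'full' model has fewer parameters than the null")
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    if df == 0:
        # identical specifications: nothing to test
        return LRTResult(statistic=0.0, df=0, pvalue=1.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, pvalue=p)


def make_prediction_grid(data: pd.DataFrame,
                         role=("participant", "target"),
                         configuration=None,
                         feas_z=(0.0,),
                         days_z=(0.0,),
                         spec: FixedEffectsSpec | None = None) -> pd.DataFrame:
    """Cartesian prediction grid with numeric covariates at 0 (their mean on
    the z-scale) and categorical controls at their reference level.

    Feasibility values should span only the range observed per configuration;
    the caller restricts them (see :func:`observed_feasibility_range`).
    """
    spec = spec or FixedEffectsSpec()
    if configuration is None:
        configuration = sorted(data["configuration"].unique())
    grid = pd.DataFrame(
        [(r, c, f, d) for r in role for c in configuration
         for f in np.atleast_1d(feas_z) for d in np.atleast_1d(days_z)],
        columns=["role", "configuration", "feas_z", "days_z"])
    grid["group"] = sorted(data["group"].unique())[0]
    for ctl in ("day0_z", "age_z", "aggr_z", "stab_z", "comp_z", "autocorr"):
        grid[ctl] = 0.0
    return grid


def observed_feasibility_range(data: pd.DataFrame, configuration: str,
                               n: int = 25) -> np.ndarray:
    """Evenly spaced z-scaled feasibility values inside the observed range of
    the given configuration."""
    sub = data.loc[data["configuration"] == configuration, "feas_z"]
    if sub.empty:
        return np.array([0.0])
    return np.linspace(sub.min(), sub.max(), n)
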
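"""Parametric bootstrap prediction bands for the fitted models.

Responses are simulated from the fitted model (fixed effects plus fresh
random-effect and residual draws), the model is refitted to each simulated
response, and predictions are evaluated on a user grid with numeric
covariates at their mean (0 on the z-scale) and categorical predictors at
their reference levels. The result is a (B, n_grid) array of prediction
curves; percentile bands across the B curves form the plotted envelope.

Refits that fail are logged and excluded; if more than 20% fail the band is
considered unreliable and a :class:`BootstrapError` is raised.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from ._exceptions import BootstrapError
from .glmm import PaternityGLMM, PaternityGLMMResults
from .lmm import RankTrajectoryResults

logger = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.20


def bootstrap_predictions(results, grid: pd.DataFrame, B: int = 1000,
                          seed: int = 0) -> np.ndarray:
    """Dispatch on the results type; returns a (B_ok, n_grid) array."""
    if isinstance(results, RankTrajectoryResults):
        return _bootstrap_lmm(results, grid, B, seed)
    if isinstance(results, PaternityGLMMResults):
        return _bootstrap_glmm(results, grid, B, seed)
    raise TypeError(f"no bootstrap scheme for {type(results).__name__}")


def _bootstrap_lmm(results: RankTrajectoryResults, grid: pd.DataFrame,
                   B: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    smres = results._sm
    model = smres.model
    X = model.exog
    fe = np.asarray(smres.params)[:X.shape[1]]
    mean = X @ fe
    # variance-component design matrices (single trivial group)
    vc_mats = [np.asarray(model.exog_vc.mats[j][0])
               for j in range(len(model.exog_vc.names))]
    vc_var = np.asarray(smres.vcomp)
    sigma2 = float(smres.scale)
    (Xg,) = patsy.build_design_matrices([results.model.design_info], grid)
    Xg = np.asarray(Xg)

    curves, failures = [], 0
    for _ in range(B):
        y = mean.copy()
        for Z, v in zip(vc_mats, vc_var):
            if v > 0:
                y = y + Z @ rng.normal(0.0, np.sqrt(v), size=Z.shape[1])
        y = y + rng.normal(0.0, np.sqrt(sigma2), size=len(y))
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit_model = sm.MixedLM(y, X, groups=model.groups,
                                         exog_vc=model.exog_vc)
                refit = refit_model.fit(reml=False, method="lbfgs")
            if not np.isfinite(refit.llf):
                raise RuntimeError("non-finite log-likelihood")
            curves.append(Xg @ np.asarray(refit.params)[:X.shape[1]])
        except Exception as exc:  # noqa: BLE001 - excluded by contract
            failures += 1
            logger.debug("bootstrap refit failed: %s", exc)
    return _check_failures(curves, failures, B)


def _bootstrap_glmm(results: PaternityGLMMResults, grid: pd.DataFrame | np.ndarray,
                    B: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    model = results.model
    beta = results.params.to_numpy()[:-1]
    sd = results.re_sd
    eta0 = model.exog @ beta
    if isinstance(grid, pd.DataFrame) and model.design_info is not None:
        (Xg,) = patsy.build_design_matrices([model.design_info], grid)
        Xg = np.asarray(Xg)
    else:
        Xg = np.asarray(grid, dtype=float)

    curves, failures = [], 0
    for _ in range(B):
        u = rng.normal(0.0, sd, size=model.n_groups)
        eta = eta0 + u[model.group_codes]
        y = (rng.random(len(eta)) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        try:
            refit = PaternityGLMM(y, model.exog, model.group_codes,
                                  exog_names=model.exog_names,
                                  n_nodes=model.n_nodes).fit()
            eta_g = Xg @ refit.params.to_numpy()[:-1]
            curves.append(1.0 / (1.0 + np.exp(-eta_g)))
        except Exception as exc:  # noqa: BLE001 - excluded by contract
            failures += 1
            logger.debug("bootstrap refit failed: %s", exc)
    return _check_failures(curves, failures, B)


def _check_failures(curves: list, failures: int, B: int) -> np.ndarray:
    if failures > MAX_FAILURE_FRACTION * B:
        raise BootstrapError(
            f"{failures}/{B} bootstrap refits failed (> "
            f"{MAX_FAILURE_FRACTION:.0%}); prediction band unreliable")
    if failures:
        logger.warning("%d/%d bootstrap refits failed and were excluded",
                       failures, B)
    return np.vstack(curves)


def percentile_band(curves: np.ndarray, level: float = 0.95):
    """(lower, upper) percentile envelope of the bootstrap curves."""
    alpha = (1.0 - level) / 2.0
    return (np.quantile(curves, alpha, axis=0),
            np.quantile(curves, 1.0 - alpha, axis=0))
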
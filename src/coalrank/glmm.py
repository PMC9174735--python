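"""Binomial random-intercept GLMM for paternity success.

Models the probability that a candidate male sired a given infant as logistic
in his window-mean standardized rating (plus optional controls), with a
random intercept per male:

    logit P(sired_ij = 1) = x_ij' beta + u_i,   u_i ~ N(0, sigma^2)

The marginal likelihood integrates the random intercept out per male with
adaptive Gauss-Hermite quadrature: each male's integrand is re-centred at its
mode (found by a safeguarded Newton search) and re-scaled by the curvature
there before applying the Hermite rule, so a modest number of nodes (default
15) matches direct numerical integration to high accuracy. Parameters are the
fixed effects plus log(sigma); maximisation uses L-BFGS-B, standard errors
come from the numerically differentiated observed information, and the
standard error of sigma is delta-method transformed from the log scale.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import log_expit, logsumexp
from statsmodels.tools.numdiff import approx_hess

from ._exceptions import FittingError, UsageError

_LOG_SD_BOUNDS = (-7.0, 3.0)


class PaternityGLMMResults:
    """ML estimates of the paternity GLMM.

    ``params`` holds the fixed effects followed by ``re_sd`` (the
    random-intercept SD); ``bse``, ``zvalues`` and ``pvalues`` align with it
    (z and p are reported for fixed effects only).
    """

    def __init__(self, model: "PaternityGLMM", beta: np.ndarray, log_sd: float,
                 llf: float, cov: np.ndarray | None, converged: bool,
                 n_nodes: int):
        self.model = model
        names = list(model.exog_names) + ["re_sd"]
        sd = float(np.exp(log_sd))
        self.params = pd.Series(np.concatenate([beta, [sd]]), index=names)
        self.llf = float(llf)
        self.converged = converged
        self.n_nodes = n_nodes
        self.fixed_names = list(model.exog_names)
        self.df_fixed = len(beta)
        self.nobs = model.nobs
        if cov is not None:
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            se_sd = se[-1] * sd  # delta method: d(sigma)/d(log sigma) = sigma
            self.bse = pd.Series(np.concatenate([se[:-1], [se_sd]]), index=names)
        else:
            self.bse = pd.Series(np.full(len(names), np.nan), index=names)
        z = self.params[:-1] / self.bse[:-1]
        self.zvalues = z
        self.pvalues = pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)

    @property
    def re_sd(self) -> float:
        return float(self.params["re_sd"])

    def predict(self, new_data: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Population-level siring probability (random intercept at zero)."""
        if isinstance(new_data, pd.DataFrame) and self.model.design_info is not None:
            (X,) = patsy.build_design_matrices([self.model.design_info], new_data)
            X = np.asarray(X)
        else:
            X = np.asarray(new_data, dtype=float)
        eta = X @ self.params.to_numpy()[:-1]
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        tab = pd.DataFrame({"coef": self.params, "se": self.bse})
        tab["z"] = tab["coef"] / tab["se"]
        tab.loc["re_sd", "z"] = np.nan
        tab["p"] = 2 * stats.norm.sf(np.abs(tab["z"]))
        return (f"Paternity GLMM (binomial, adaptive GHQ {self.n_nodes} nodes, "
                f"ML), n = {self.nobs}, groups = {self.model.n_groups}, "
                f"llf = {self.llf:.2f}\n"
                + tab.to_string(float_format=lambda v: f"{v:.4f}"))

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "bse": self.bse.to_dict(),
                "llf": self.llf, "converged": self.converged, "nobs": self.nobs}


class PaternityGLMM:
    """Logistic mixed model with one random intercept per grouping unit.

    Parameters
    ----------
    endog : array of 0/1
    exog : (n, k) design matrix including the intercept column
    groups : length-n labels (male identity)
    """

    def __init__(self, endog, exog, groups, exog_names=None, n_nodes: int = 15):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 1 or self.exog.ndim != 2:
            raise UsageError("endog must be 1-D and exog 2-D")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise UsageError("response must be binary 0/1")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.exog.shape[1])])
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        self.nobs = len(self.endog)
        self.n_nodes = n_nodes
        self._nodes, self._weights = hermgauss(n_nodes)
        self._group_rows = [np.flatnonzero(codes == g) for g in range(self.n_groups)]
        self.design_info = None

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str = "male",
                     n_nodes: int = 15) -> "PaternityGLMM":
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        model = cls(np.asarray(y).ravel(), np.asarray(X), data[groups].to_numpy(),
                    exog_names=list(X.columns), n_nodes=n_nodes)
        model.design_info = X.design_info
        return model

    # -- marginal log-likelihood ------------------------------------------

    def _group_logintegrand(self, rows, eta0, b, sigma2):
        """h(b) = Bernoulli log-lik of the group at intercept b + log N(b;0,s2)."""
        eta = eta0[:, None] + b[None, :]
        y = self.endog[rows][:, None]
        ll = y * log_expit(eta) + (1 - y) * log_expit(-eta)
        return (ll.sum(axis=0)
                - 0.5 * b ** 2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2))

    def _group_mode(self, rows, eta0, sigma2):
        """Safeguarded Newton search for the mode of the group integrand."""
        y = self.endog[rows]
        b = 0.0
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
            grad = float(np.sum(y - p)) - b / sigma2
            hess = -float(np.sum(p * (1 - p))) - 1.0 / sigma2
            step = grad / hess
            b_new = b - step
            if not np.isfinite(b_new):
                break
            b = b_new
            if abs(step) < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
        curv = float(np.sum(p * (1 - p))) + 1.0 / sigma2
        return b, curv

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at (beta, log_sd) via adaptive GHQ."""
        beta = np.asarray(params[:-1], dtype=float)
        log_sd = float(np.clip(params[-1], *_LOG_SD_BOUNDS))
        sigma2 = np.exp(2.0 * log_sd)
        eta_all = self.exog @ beta
        total = 0.0
        x, w = self._nodes, self._weights
        logw = np.log(w)
        for rows in self._group_rows:
            eta0 = eta_all[rows]
            bhat, curv = self._group_mode(rows, eta0, sigma2)
            s = 1.0 / np.sqrt(curv)
            b = bhat + np.sqrt(2.0) * s * x
            h = self._group_logintegrand(rows, eta0, b, sigma2)
            total += (0.5 * np.log(2.0) + np.log(s)
                      + logsumexp(logw + x ** 2 + h))
        return float(total)

    # -- fitting -----------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glm = sm.GLM(self.endog, self.exog,
                             family=sm.families.Binomial()).fit(maxiter=50)
                beta0 = np.asarray(glm.params)
            except Exception:
                beta0 = np.zeros(self.exog.shape[1])
        return np.concatenate([beta0, [np.log(0.5)]])

    def fit(self, start_params=None, maxiter: int = 200) -> PaternityGLMMResults:
        start = (np.asarray(start_params, dtype=float) if start_params is not None
                 else self._start_params())
        k = self.exog.shape[1]
        bounds = [(None, None)] * k + [_LOG_SD_BOUNDS]

        def nll(p):
            return -self.loglike(p)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": maxiter})
        beta = opt.x[:k]
        if np.max(np.abs(beta)) > 15:
            raise FittingError(
                "paternity model: a coefficient diverged (|beta| > 15); the "
                "data are likely completely separated on that predictor")
        cov = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess(opt.x, nll)
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            pass
        return PaternityGLMMResults(self, beta, float(opt.x[-1]), -opt.fun,
                                    cov, bool(opt.success), self.n_nodes)


def fit_paternity_model(data: pd.DataFrame,
                        formula: str | None = None,
                        groups: str = "male",
                        n_nodes: int = 15) -> PaternityGLMMResults:
    """Fit the paternity GLMM to a paternity table.

    The default formula uses the window-mean standardized rating plus the
    control terms when their columns are present.
    """
    if data["infant"].nunique() < 2:
        raise UsageError("paternity model needs >= 2 infants")
    if formula is None:
        controls = [c for c in ("age_z", "stab_z", "comp_z") if c in data.columns
                    and data[c].notna().all()]
        formula = "sired ~ rating" + ("".join(" + " + c for c in controls))
    model = PaternityGLMM.from_formula(formula, data, groups=groups,
                                       n_nodes=n_nodes)
    return model.fit()
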
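"""Generalized linear models for the community responses, fitted by IRLS.

Three structurally identical models are fitted to the plot x era table:

* occupancy     — Bernoulli response (any shorebird on the plot), logit link;
* richness      — species count per plot, NB2 negative binomial, log link;
* density       — total birds per plot, NB2 negative binomial, log link,
                  with a log(plot area in km2) exposure offset so
                  coefficients are on a per-km2 scale.

All share additive treatment-coded effects of era, region and habitat with
reference categories (early era, Foxe Basin, lowland) absorbed into the
intercept.  The NB2 family has variance mu + mu^2/theta; theta is estimated
by profile maximum likelihood.  Inference is by Wald z-tests, coefficient
over its Fisher-information standard error against a standard normal.

The fitters are written from first principles (iteratively reweighted least
squares with step-halving); no external GLM library is used at run time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import EmptyInputError, RankDeficiencyError, ValidationError
from .survey import ERAS, HABITATS, REGIONS, PlotSurvey

RESPONSES = ("occupancy", "richness", "density_count")

_FACTORS = (("era", ERAS), ("region", REGIONS), ("habitat", HABITATS))

#: Design column labels, in published-table order.
DESIGN_LABELS = ("Intercept", "Time Period (2019)", "Region (Rasmussen)", "Habitat (Upland)")


@dataclass
class DesignMatrix:
    """Response vector + treatment-coded predictor matrix for one model."""

    response: np.ndarray
    X: np.ndarray
    labels: tuple[str, ...]
    row_ids: list[str]
    offset: np.ndarray | None = None
    kind: str = "occupancy"

    def __post_init__(self):
        if self.X.shape[0] != self.response.shape[0]:
            raise ValidationError("response and design row counts differ")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RankDeficiencyError("design")


def build_design(surveys: Iterable[PlotSurvey], response: str) -> DesignMatrix:
    """One row per plot x era; columns Intercept, era=late, region=Rasmussen, habitat=upland."""
    if response not in RESPONSES:
        raise ValidationError(f"response must be one of {RESPONSES}, got {response!r}")
    surveys = sorted(surveys, key=lambda s: (s.era, s.region, s.plot_id))
    if not surveys:
        raise EmptyInputError("no survey records")
    for name, levels in _FACTORS:
        seen = {getattr(s, name) for s in surveys}
        if len(seen) < 2:
            raise RankDeficiencyError(name)

    n = len(surveys)
    X = np.ones((n, 4))
    X[:, 1] = [s.era == "late" for s in surveys]
    X[:, 2] = [s.region == "Rasmussen" for s in surveys]
    X[:, 3] = [s.habitat == "upland" for s in surveys]

    if response == "occupancy":
        y = np.array([1.0 if s.total_birds >= 1 else 0.0 for s in surveys])
        offset = None
    elif response == "richness":
        y = np.array([float(s.richness) for s in surveys])
        offset = None
    else:  # density_count: counts with a log-area (km2) exposure offset
        y = np.array([float(s.total_birds) for s in surveys])
        offset = np.log(np.array([s.area_ha / 100.0 for s in surveys]))
    row_ids = [f"{s.plot_id}:{s.era}" for s in surveys]
    return DesignMatrix(response=y, X=X, labels=DESIGN_LABELS, row_ids=row_ids, offset=offset, kind=response)


@dataclass
class GLMResults:
    """Fitted-model bundle: estimates, Wald inference, and fit diagnostics."""

    family: str
    labels: tuple[str, ...]
    params: np.ndarray
    cov_params: np.ndarray
    deviance: float
    deviance_path: list[float]
    n_iter: int
    converged: bool
    nobs: int
    theta: float | None = None
    poisson_limit: bool = False
    diagnostic: str = ""

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def wald_table(self) -> pd.DataFrame:
        return wald_table(self, list(self.labels))

    def summary(self) -> str:
        lines = [
            f"Family: {self.family}   nobs: {self.nobs}   deviance: {self.deviance:.4f}",
            f"converged: {self.converged} in {self.n_iter} iterations"
            + (f"   theta: {self.theta:.4g}" + (" (Poisson limit)" if self.poisson_limit else "") if self.theta is not None else ""),
        ]
        if self.diagnostic:
            lines.append(f"note: {self.diagnostic}")
        tab = self.wald_table()
        lines.append(tab.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def wald_table(fit: GLMResults, labels: Sequence[str]) -> pd.DataFrame:
    """Coefficient table (label, estimate, SE, z, two-sided p) in design order."""
    if len(labels) != len(fit.params):
        raise ValidationError(f"{len(labels)} labels for {len(fit.params)} coefficients")
    return pd.DataFrame(
        {
            "coefficient": list(labels),
            "estimate": fit.params,
            "se": fit.bse,
            "z": fit.zvalues,
            "p": fit.pvalues,
        }
    )


# ---------------------------------------------------------------------------
# Binomial (Bernoulli) logit


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


class BinomialLogitGLM:
    """Bernoulli-logit model fitted by IRLS with step-halving.

    Step-halving accepts an IRLS step only if it does not increase the
    deviance, so the deviance path is non-increasing by construction.
    """

    def __init__(self, design: DesignMatrix):
        y = np.asarray(design.response, dtype=float)
        if not np.all((y == 0) | (y == 1)):
            raise ValidationError("binomial response must be 0/1")
        self.design = design

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> GLMResults:
        X, y = self.design.X, self.design.response
        offset = self.design.offset if self.design.offset is not None else 0.0
        beta = np.zeros(X.shape[1])
        eta = X @ beta + offset
        mu = special.expit(eta)
        dev = _binomial_deviance(y, mu)
        path = [dev]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta - offset + (y - mu) / w
            beta_new = _weighted_solve(X, w, z)
            # step-halve toward the current iterate until deviance does not rise
            step = 1.0
            for _ in range(30):
                cand = beta + step * (beta_new - beta)
                mu_c = special.expit(X @ cand + offset)
                dev_c = _binomial_deviance(y, mu_c)
                if dev_c <= dev + 1e-12:
                    break
                step /= 2.0
            beta = beta + step * (beta_new - beta)
            eta = X @ beta + offset
            mu = special.expit(eta)
            dev_new = _binomial_deviance(y, mu)
            path.append(dev_new)
            if abs(dev - dev_new) / (abs(dev) + 0.1) < tol:
                converged = True
                dev = dev_new
                break
            dev = dev_new

        diagnostic = ""
        if np.max(np.abs(X @ beta)) > 15:
            diagnostic = "possible complete separation: fitted probabilities at 0/1, estimates may be unbounded"
            converged = False
        w = np.clip(mu * (1 - mu), 1e-10, None)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        return GLMResults(
            family="binomial-logit",
            labels=self.design.labels,
            params=beta,
            cov_params=cov,
            deviance=dev,
            deviance_path=path,
            n_iter=it,
            converged=converged,
            nobs=len(y),
            diagnostic=diagnostic,
        )


def _weighted_solve(X: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
    WX = X * w[:, None]
    return np.linalg.solve(X.T @ WX, WX.T @ z)


# ---------------------------------------------------------------------------
# NB2 negative binomial, log link


def _nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.clip(mu, 1e-10, None)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _nb2_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.clip(mu, 1e-10, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


#: Profile-likelihood search window and ceiling for the dispersion parameter.
THETA_BOUNDS = (1e-2, 1e4)


class NegativeBinomialGLM:
    """NB2 log-link count model: IRLS for the mean, profile ML for theta.

    Alternates (a) IRLS for the regression coefficients at fixed theta with
    (b) a bounded 1-D maximization of the NB2 log-likelihood over log(theta),
    until the joint relative change falls below ``tol``.  Data with no
    detectable overdispersion push theta to the declared ceiling; the fit is
    then flagged ``poisson_limit`` and still reported as converged.
    """

    def __init__(self, design: DesignMatrix):
        y = np.asarray(design.response, dtype=float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValidationError("negative binomial response must be non-negative integers")
        self.design = design

    def _irls(self, beta: np.ndarray, theta: float, tol: float, max_iter: int) -> tuple[np.ndarray, int]:
        X, y = self.design.X, self.design.response
        offset = self.design.offset if self.design.offset is not None else 0.0
        dev = _nb2_deviance(y, np.exp(X @ beta + offset), theta)
        for it in range(1, max_iter + 1):
            eta = X @ beta + offset
            mu = np.clip(np.exp(eta), 1e-10, None)
            w = mu / (1.0 + mu / theta)  # Fisher weights for log link, NB2 variance
            z = eta - offset + (y - mu) / mu
            beta_new = _weighted_solve(X, w, z)
            step = 1.0
            for _ in range(30):
                cand = beta + step * (beta_new - beta)
                dev_c = _nb2_deviance(y, np.exp(X @ cand + offset), theta)
                if dev_c <= dev + 1e-12:
                    break
                step /= 2.0
            beta = beta + step * (beta_new - beta)
            dev_new = _nb2_deviance(y, np.exp(X @ beta + offset), theta)
            if abs(dev - dev_new) / (abs(dev) + 0.1) < tol:
                return beta, it
            dev = dev_new
        return beta, max_iter

    def _profile_theta(self, mu: np.ndarray) -> float:
        y = self.design.response
        lo, hi = np.log(THETA_BOUNDS[0]), np.log(THETA_BOUNDS[1])
        res = optimize.minimize_scalar(
            lambda lt: -_nb2_loglik(y, mu, np.exp(lt)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(np.exp(res.x))

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> GLMResults:
        X, y = self.design.X, self.design.response
        offset = self.design.offset if self.design.offset is not None else 0.0
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(np.mean(y), 0.1)) - np.mean(np.atleast_1d(offset))
        theta = 1.0
        ll = _nb2_loglik(y, np.exp(X @ beta + offset), theta)
        converged = False
        total_inner = 0
        for _ in range(max_iter):
            beta, inner = self._irls(beta, theta, tol, max_iter)
            total_inner += inner
            mu = np.exp(X @ beta + offset)
            theta = self._profile_theta(mu)
            ll_new = _nb2_loglik(y, mu, theta)
            if abs(ll_new - ll) / (abs(ll) + 0.1) < tol:
                converged = True
                ll = ll_new
                break
            ll = ll_new

        # refresh coefficients at the final dispersion estimate
        beta, _ = self._irls(beta, theta, tol, max_iter)
        poisson_limit = theta >= 0.99 * THETA_BOUNDS[1]
        if poisson_limit:
            converged = True
        mu = np.clip(np.exp(X @ beta + offset), 1e-10, None)
        w = mu / (1.0 + mu / theta)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        dev = _nb2_deviance(y, mu, theta)
        return GLMResults(
            family="negbin-log",
            labels=self.design.labels,
            params=beta,
            cov_params=cov,
            deviance=dev,
            deviance_path=[dev],
            n_iter=total_inner,
            converged=converged,
            nobs=len(y),
            theta=theta,
            poisson_limit=poisson_limit,
            diagnostic="theta at ceiling; counts are equidispersed (Poisson-like)" if poisson_limit else "",
        )


def fit_binomial(design: DesignMatrix, tol: float = 1e-8, max_iter: int = 100) -> GLMResults:
    """Functional wrapper over :class:`BinomialLogitGLM`."""
    return BinomialLogitGLM(design).fit(tol=tol, max_iter=max_iter)


def fit_negbin(design: DesignMatrix, tol: float = 1e-8, max_iter: int = 100) -> GLMResults:
    """Functional wrapper over :class:`NegativeBinomialGLM`."""
    return NegativeBinomialGLM(design).fit(tol=tol, max_iter=max_iter)


def fit_community_models(surveys: Iterable[PlotSurvey]) -> dict[str, GLMResults]:
    """Fit the three community models (occupancy, richness, density) to a survey set."""
    surveys = list(surveys)
    out: dict[str, GLMResults] = {}
    out["occupancy"] = fit_binomial(build_design(surveys, "occupancy"))
    out["richness"] = fit_negbin(build_design(surveys, "richness"))
    out["density"] = fit_negbin(build_design(surveys, "density_count"))
    return out


def community_model_table(fits: dict[str, GLMResults]) -> pd.DataFrame:
    """Stack the three Wald tables into one published-style coefficient table."""
    frames = []
    for model, fit in fits.items():
        tab = fit.wald_table()
        tab.insert(0, "model", model)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
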
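"""Maximum-likelihood logistic regression via Newton-Raphson (IRLS).

This is the package's own fitting engine for the dose-response pipeline:
binary outcome y, linear predictor eta = X beta, P(y=1) = expit(eta).
Newton steps solve (X' W X) delta = X'(y - mu) with W = diag(mu(1-mu));
step-halving guards against overshooting. Wald standard errors come from
the inverse observed information (X' W X at the optimum, which for the
logistic likelihood equals the expected information).

Complete or quasi-complete separation drives coefficients to infinity with
a monotonically improving likelihood; it is detected (|coef| beyond a
divergence bound, or a singular information matrix) and raised as
:class:`SeparationError` rather than returned as a spurious fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = ["LogisticModel", "LogisticResults", "SeparationError"]

# coefficient magnitude beyond which the fit is treated as separated
_DIVERGENCE_BOUND = 15.0


class SeparationError(RuntimeError):
    """Raised when the outcome is (quasi-)completely separated by a covariate."""


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log L = sum(y*eta - log(1+exp(eta)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogisticResults:
    """Fitted logistic model: estimates, uncertainty, and diagnostics."""

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_iter: int
    converged: bool
    exog_names: list[str]
    nobs: int
    model: "LogisticModel" = field(repr=False, default=None)

    @property
    def tvalues(self) -> np.ndarray:
        """Wald z statistics."""
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(k, 2) array of Wald confidence limits for the coefficients."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-unit odds ratios with Wald confidence limits."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "odds_ratio": np.exp(self.params),
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
                "p_value": self.pvalues,
            },
            index=self.exog_names,
        )

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Predicted event probabilities for a design matrix (default: training)."""
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return expit(X @ self.params)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Logistic regression (maximum likelihood, Newton-Raphson)",
            f"  n obs: {self.nobs}    log-likelihood: {self.llf:.4f}"
            f"    iterations: {self.n_iter}    converged: {self.converged}",
            "-" * 78,
            f"{'':<16}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>9}"
            f"{'[0.025':>11}{'0.975]':>10}",
            "-" * 78,
        ]
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"{name:<16}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.tvalues[i]:>8.2f}{self.pvalues[i]:>9.3f}"
                f"{ci[i, 0]:>11.4f}{ci[i, 1]:>10.4f}"
            )
        lines.append("-" * 78)
        return "\n".join(lines)


class LogisticModel:
    """Binary-outcome logistic model for a design matrix or DataFrame columns.

    Parameters
    ----------
    endog : 1-D binary array (0/1 outcomes)
    exog : 2-D covariate matrix, one row per observation (without intercept
        unless ``add_intercept=False``)
    exog_names : covariate names; generated if omitted
    add_intercept : prepend a constant column (default True)
    """

    def __init__(self, endog, exog=None, exog_names=None, add_intercept=True):
        y = np.asarray(endog, dtype=float).ravel()
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present")
        if exog is None:
            X = np.empty((y.size, 0))
            names: list[str] = []
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            if X.shape[0] != y.size:
                X = X.T
            if X.shape[0] != y.size:
                raise ValueError("endog and exog lengths differ")
            names = list(exog_names) if exog_names is not None else [
                f"x{i + 1}" for i in range(X.shape[1])
            ]
            if X.shape[1] and np.any(X.std(axis=0) == 0):
                bad = [names[i] for i in np.where(X.std(axis=0) == 0)[0]]
                raise ValueError(f"zero-variance covariate(s): {bad}")
        if add_intercept:
            X = np.column_stack([np.ones(y.size), X])
            names = ["intercept"] + names
        self.endog = y
        self.exog = X
        self.exog_names = names

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, factors: list[str],
                       add_intercept: bool = True) -> "LogisticModel":
        """Build a model from named columns of a cohort table."""
        missing = [c for c in [outcome, *factors] if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in cohort table: {missing}")
        return cls(
            data[outcome].to_numpy(),
            data[list(factors)].to_numpy(dtype=float),
            exog_names=list(factors),
            add_intercept=add_intercept,
        )

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> LogisticResults:
        """Newton-Raphson MLE; converged when |delta log L| < ``tol``."""
        y, X = self.endog, self.exog
        k = X.shape[1]
        beta = np.zeros(k)
        eta = X @ beta
        ll = _log_likelihood(y, eta)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            mu = expit(eta)
            w = mu * (1.0 - mu)
            info = (X * w[:, None]).T @ X
            grad = X.T @ (y - mu)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as err:
                raise SeparationError(
                    "information matrix singular (separation or collinearity)"
                ) from err
            # step-halving so the likelihood never decreases
            new_beta, new_eta, new_ll = beta + step, None, -np.inf
            for _ in range(30):
                new_eta = X @ new_beta
                new_ll = _log_likelihood(y, new_eta)
                if new_ll >= ll - 1e-12:
                    break
                new_beta = beta + (new_beta - beta) / 2.0
            if np.max(np.abs(new_beta)) > _DIVERGENCE_BOUND:
                raise SeparationError(
                    "coefficients diverging: outcome separated by a covariate"
                )
            delta_ll = new_ll - ll
            beta, eta, ll = new_beta, new_eta, new_ll
            if abs(delta_ll) < tol:
                converged = True
                break
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as err:
            raise SeparationError("information matrix singular at optimum") from err
        return LogisticResults(
            params=beta,
            bse=np.sqrt(np.diag(cov)),
            cov_params=cov,
            llf=ll,
            n_iter=n_iter,
            converged=converged,
            exog_names=self.exog_names,
            nobs=y.size,
            model=self,
        )
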
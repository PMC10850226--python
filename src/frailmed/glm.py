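"""Structural model fits and regression diagnostics.

Two models underpin the mediation analysis:

* a linear regression of the frailty index M on age A and covariates C
  (path a is the age coefficient), and
* a logistic regression of a binary 90-day outcome Y on age, the frailty
  index, optionally their product, and the same covariates (path c is the
  age coefficient, path b the frailty coefficient).

Fits are maximum likelihood (OLS; Newton-scoring logistic) via statsmodels,
wrapped into containers that carry exactly what the mediation formulas
need: named coefficients, the coefficient covariance, the residual
variance of the mediator model and the maximised log-likelihood of the
outcome model.  Complete or quasi-complete separation of the logistic
model is an error, not a silent fallback — no penalisation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SeparationError",
    "MediatorFit",
    "OutcomeFit",
    "fit_ols",
    "fit_logistic",
    "vif",
    "wald_test",
    "lr_test",
    "VIF_WARN_THRESHOLD",
]

#: multicollinearity screen: warn when any VIF exceeds this
VIF_WARN_THRESHOLD = 3.0


class SeparationError(RuntimeError):
    """Logistic MLE does not exist (complete/quasi-complete separation)."""


@dataclass
class MediatorFit:
    """Linear mediator model M = beta0 + beta1*A + beta2'C + eps."""

    beta0: float
    beta1: float
    beta2: np.ndarray
    sigma2: float
    vcov: np.ndarray
    n: int
    column_names: tuple[str, ...]

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.beta0, self.beta1], self.beta2])

    def se(self, index: int) -> float:
        return float(np.sqrt(self.vcov[index, index]))


@dataclass
class OutcomeFit:
    """Logistic outcome model
    logit P(Y=1) = theta0 + theta1*A + theta2*M [+ theta3*A*M] + theta4'C.

    ``theta3`` is 0 with zero variance when the model was fitted without
    the exposure-mediator interaction (``interaction=False``).
    """

    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    interaction: bool
    n: int
    column_names: tuple[str, ...]
    raw_params: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        if self.raw_params is not None:
            return self.raw_params
        base = [self.theta0, self.theta1, self.theta2]
        if self.interaction:
            base.append(self.theta3)
        return np.concatenate([base, self.theta4])

    @property
    def n_params(self) -> int:
        return len(self.column_names)

    def se(self, index: int) -> float:
        return float(np.sqrt(self.vcov[index, index]))


def _check_full_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(len(names)) if j < diag.size and diag[j] <= tol]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns near: {bad or 'unidentified'}"
        )


def fit_ols(X: np.ndarray, y: np.ndarray, column_names=None) -> MediatorFit:
    """Least-squares fit of the mediator model.

    ``X`` must contain an intercept column first and the exposure second;
    remaining columns are covariates.  ``sigma2`` is RSS/(n-p) and the
    coefficient covariance is ``sigma2 * (X'X)^-1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > p observations for the mediator model")
    names = tuple(column_names) if column_names else tuple(
        ["const", "exposure"] + [f"c{j}" for j in range(X.shape[1] - 2)]
    )
    _check_full_rank(X, names)
    res = sm.OLS(y, X).fit()
    params = np.asarray(res.params, dtype=float)
    sigma2 = float(res.ssr / res.df_resid)
    vcov = np.asarray(res.cov_params(), dtype=float)
    return MediatorFit(
        beta0=float(params[0]),
        beta1=float(params[1]) if X.shape[1] > 1 else 0.0,
        beta2=params[2:],
        sigma2=sigma2,
        vcov=vcov,
        n=int(res.nobs),
        column_names=names,
    )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    column_names=None,
    interaction: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> OutcomeFit:
    """Maximum-likelihood logistic fit of the outcome model.

    Column convention: intercept, exposure, mediator, [exposure*mediator
    when ``interaction``], covariates.  The covariance is the inverse
    observed information.  Raises :class:`SeparationError` when fitted
    probabilities are pinned at 0/1 (MLE on the boundary) and a plain
    error when Newton scoring fails to converge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic model undefined")
    k_base = 4 if interaction else 3
    names = tuple(column_names) if column_names else tuple(
        ["const", "exposure", "mediator"]
        + (["exposure:mediator"] if interaction else [])
        + [f"c{j}" for j in range(X.shape[1] - k_base)]
    )
    _check_full_rank(X, names)
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
        except np.linalg.LinAlgError as exc:
            # design is full rank (pre-checked), so a singular information
            # matrix during Newton means probabilities pinned at 0/1
            raise SeparationError(
                f"separation detected: information matrix singular during fit ({exc})"
            ) from exc
        except Exception as exc:  # statsmodels raises several types
            if "erfect" in str(type(exc).__name__) + str(exc):  # PerfectSeparation*
                raise SeparationError(f"separation detected during fit: {exc}") from exc
            raise
    params = np.asarray(res.params, dtype=float)
    fitted = np.asarray(res.predict(X), dtype=float)
    pinned = np.minimum(fitted, 1 - fitted) < 1e-6
    # scale-aware divergence check: a coefficient spanning > ~30 logits per
    # SD of its column only arises when the MLE is escaping to the boundary
    col_sd = X.std(axis=0)
    col_sd[col_sd == 0] = 1.0  # intercept
    if pinned.any() and np.abs(params * col_sd).max() > 30:
        raise SeparationError(
            "complete or quasi-complete separation: fitted probabilities pinned "
            f"at 0/1 for {int(pinned.sum())} observations with diverging coefficients"
        )
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(last iterations: {res.mle_retvals})"
        )
    def coef(j: int) -> float:
        # small designs (intercept-only, single-predictor) lack the later slots
        return float(params[j]) if j < params.size else 0.0

    return OutcomeFit(
        theta0=coef(0),
        theta1=coef(1),
        theta2=coef(2),
        theta3=coef(3) if interaction else 0.0,
        theta4=params[k_base:] if params.size > k_base else np.empty(0),
        raw_params=params,
        vcov=np.asarray(res.cov_params(), dtype=float),
        loglik=float(res.llf),
        converged=True,
        interaction=interaction,
        n=int(res.nobs),
        column_names=names,
    )


def vif(X: np.ndarray, column_names=None, has_intercept: bool = True) -> dict[str, float]:
    """Variance inflation factors, 1/(1 - R^2_j), per non-intercept column.

    ``R^2_j`` comes from regressing column j on every other column
    (intercept included as a regressor but excluded from the output).
    Exactly collinear columns get ``inf`` with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("VIF needs at least an intercept and two predictors")
    names = tuple(column_names) if column_names else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    start = 1 if has_intercept else 0
    out = {}
    for j in range(start, X.shape[1]):
        others = np.delete(X, j, axis=1)
        xj = X[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        ss_res = float(resid @ resid)
        if ss_tot == 0 or ss_res <= ss_tot * 1e-12:
            warnings.warn(
                f"column {names[j]!r} is (near-)exactly collinear; VIF infinite",
                UserWarning,
                stacklevel=2,
            )
            out[names[j]] = float("inf")
        else:
            out[names[j]] = ss_tot / ss_res
    high = {k: v for k, v in out.items() if v > VIF_WARN_THRESHOLD}
    if high:
        warnings.warn(
            f"VIF above {VIF_WARN_THRESHOLD}: {high} — check multicollinearity",
            UserWarning,
            stacklevel=2,
        )
    return out


def wald_test(fit: MediatorFit | OutcomeFit, index: int) -> tuple[float, float]:
    """Wald z-test of one coefficient: z = coef/SE, two-sided normal p."""
    coef = float(fit.params[index])
    se = fit.se(index)
    if se == 0:
        raise ZeroDivisionError("coefficient has zero standard error")
    z = coef / se
    return z, float(2 * stats.norm.sf(abs(z)))


def lr_test(full: OutcomeFit, reduced: OutcomeFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic models.

    Returns ``(deviance difference, df, p)`` with the chi-square reference.
    """
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise RuntimeError(
            f"full-model log-likelihood below reduced ({full.loglik} < {reduced.loglik}); "
            "fitting bug"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p
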
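"""Regression-based causal mediation: natural effects on the odds-ratio scale.

Given the linear mediator model and the logistic outcome model, the
natural direct effect (NDE: change the exposure A from a* to a while the
mediator keeps the distribution it would have at a*), natural indirect
effect (NIE: hold the exposure at a while the mediator shifts from its
a* to its a distribution) and total effect (TE) have closed forms under
the rare-outcome approximation.  With mediator model
``M = b0 + b1*A + b2'C + eps``, ``eps ~ N(0, s2)``, and outcome model
``logit P(Y=1) = t0 + t1*A + t2*M + t3*A*M + t4'C``:

    log OR_NDE = [t1 + t3*(b0 + b1*a* + b2'c + t2*s2)]*(a - a*)
                 + 0.5*t3^2*s2*(a^2 - a*^2)
    log OR_NIE = (t2*b1 + t3*b1*a)*(a - a*)
    log OR_TE  = log OR_NDE + log OR_NIE          (an exact identity here)

Without interaction (t3 = 0) these reduce to ``t1*(a-a*)`` and
``t2*b1*(a-a*)`` and no longer depend on the covariate conditioning
values ``c``.  Standard errors propagate the two coefficient covariance
blocks (treated as independent) through the analytic gradients of the
log-OR expressions; the proportion mediated is computed on the OR scale,

    PM = OR_NDE*(OR_NIE - 1) / (OR_NDE*OR_NIE - 1),

with its own delta-method interval from the joint (log NDE, log NIE)
covariance.  A participant-level bootstrap is available as an internal
cross-check on all intervals.  The approximation treats odds ratios as
risk ratios and degrades as the outcome becomes common; a warning is
emitted above 10% prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import CodedDesign, COVARIATE_COLUMNS
from .glm import (
    MediatorFit,
    OutcomeFit,
    SeparationError,
    fit_logistic,
    fit_ols,
    lr_test,
    vif,
    wald_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MediationSpec",
    "MediationEstimates",
    "InteractionReport",
    "NaturalEffectsMediator",
    "natural_effects",
    "delta_method_se",
    "proportion_mediated",
    "pm_inference",
    "bootstrap_mediation",
    "test_interaction",
    "mediator_design",
    "outcome_design",
    "PREVALENCE_WARN",
]

#: outcome prevalence above which the rare-outcome OR approximation is flagged
PREVALENCE_WARN = 0.10


@dataclass
class MediationSpec:
    """Exposure contrast and conditioning for the natural-effect estimands.

    ``a_star`` is the reference exposure (years of age), ``a`` the
    comparison level; ``c_cond`` holds the covariates fixed (only relevant
    when ``interaction`` is on).  ``alpha`` sets the CI level (0.05 gives
    95% intervals).
    """

    a: float
    a_star: float
    interaction: bool = False
    c_cond: np.ndarray | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.a == self.a_star:
            raise ValueError("exposure contrast requires a != a_star")
        if self.c_cond is not None:
            self.c_cond = np.asarray(self.c_cond, dtype=float)


@dataclass
class MediationEstimates:
    """Point estimates, delta-method SEs, CIs and p-values for TE/NDE/NIE
    and the proportion mediated (the machine-readable analogue of a
    mediation results table)."""

    log_te: float
    log_nde: float
    log_nie: float
    se_log_te: float
    se_log_nde: float
    se_log_nie: float
    cov_nde_nie: float
    or_te: float
    or_nde: float
    or_nie: float
    ci_te: tuple[float, float]
    ci_nde: tuple[float, float]
    ci_nie: tuple[float, float]
    p_te: float
    p_nde: float
    p_nie: float
    pm: float
    se_pm: float
    ci_pm_raw: tuple[float, float]
    ci_pm: tuple[float, float]
    p_pm: float
    spec: MediationSpec | None = None
    outcome_name: str = ""
    n: int = 0

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "log_te", "log_nde", "log_nie",
                "se_log_te", "se_log_nde", "se_log_nie", "cov_nde_nie",
                "or_te", "or_nde", "or_nie",
                "p_te", "p_nde", "p_nie",
                "pm", "se_pm", "p_pm", "outcome_name", "n",
            )
        }
        for k in ("ci_te", "ci_nde", "ci_nie", "ci_pm", "ci_pm_raw"):
            d[k] = list(getattr(self, k))
        if self.spec is not None:
            d["contrast"] = {
                "a": self.spec.a,
                "a_star": self.spec.a_star,
                "interaction": self.spec.interaction,
                "c_cond": None if self.spec.c_cond is None else list(self.spec.c_cond),
                "alpha": self.spec.alpha,
            }
        return d


def mediator_design(design: CodedDesign) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Design matrix and response for the mediator model (FI on age + covariates)."""
    X = np.column_stack([np.ones(design.n), design.exposure, design.covariates])
    names = ("const", "age") + tuple(design.column_names)
    return X, design.mediator, names


def outcome_design(
    design: CodedDesign, interaction: bool
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Design matrix and response for the logistic outcome model."""
    cols = [np.ones(design.n), design.exposure, design.mediator]
    names = ["const", "age", "frailty_index"]
    if interaction:
        cols.append(design.exposure * design.mediator)
        names.append("age:frailty_index")
    cols.append(design.covariates)
    X = np.column_stack(cols)
    return X, design.outcome, tuple(names) + tuple(design.column_names)


def _resolve_c(med: MediatorFit, spec: MediationSpec) -> np.ndarray:
    k = med.beta2.size
    if spec.c_cond is None:
        return np.zeros(k)
    if spec.c_cond.size != k:
        raise ValueError(
            f"c_cond has length {spec.c_cond.size}, model has {k} covariates"
        )
    return spec.c_cond


def natural_effects(
    med: MediatorFit, out: OutcomeFit, spec: MediationSpec
) -> tuple[float, float, float]:
    """Point estimates ``(log OR_TE, log OR_NDE, log OR_NIE)``.

    When ``spec.interaction`` is false the formulas reduce to forms that do
    not involve ``c_cond``; requesting an interaction contrast on a fit
    without the interaction term is an error.
    """
    if spec.interaction and not out.interaction:
        raise ValueError(
            "spec requests the exposure-mediator interaction but the outcome "
            "model was fitted without it"
        )
    a, a_star = spec.a, spec.a_star
    delta = a - a_star
    t1, t2, t3 = out.theta1, out.theta2, out.theta3 if spec.interaction else 0.0
    c = _resolve_c(med, spec)
    kappa = med.beta0 + med.beta1 * a_star + float(med.beta2 @ c) + t2 * med.sigma2
    log_nde = (t1 + t3 * kappa) * delta + 0.5 * t3**2 * med.sigma2 * (a**2 - a_star**2)
    log_nie = (t2 * med.beta1 + t3 * med.beta1 * a) * delta
    return log_nde + log_nie, log_nde, log_nie


def _gradients(
    med: MediatorFit, out: OutcomeFit, spec: MediationSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of (log NDE, log NIE) in the stacked parameter
    vector (mediator block then outcome block), plus the block-diagonal V."""
    a, a_star = spec.a, spec.a_star
    delta = a - a_star
    t2 = out.theta2
    t3 = out.theta3 if spec.interaction else 0.0
    c = _resolve_c(med, spec)
    kappa = med.beta0 + med.beta1 * a_star + float(med.beta2 @ c) + t2 * med.sigma2

    pm_len = len(med.column_names)
    po_len = len(out.column_names)
    g_nde = np.zeros(pm_len + po_len)
    g_nie = np.zeros(pm_len + po_len)

    # mediator block: [beta0, beta1, beta2...]
    g_nde[0] = t3 * delta
    g_nde[1] = t3 * a_star * delta
    g_nde[2:pm_len] = t3 * c * delta
    g_nie[1] = (t2 + t3 * a) * delta

    # outcome block: [theta0, theta1, theta2, (theta3), theta4...]
    o = pm_len
    g_nde[o + 1] = delta
    g_nde[o + 2] = t3 * med.sigma2 * delta
    g_nie[o + 2] = med.beta1 * delta
    if out.interaction:
        g_nde[o + 3] = kappa * delta + t3 * med.sigma2 * (a**2 - a_star**2)
        g_nie[o + 3] = med.beta1 * a * delta

    V = np.zeros((pm_len + po_len, pm_len + po_len))
    V[:pm_len, :pm_len] = med.vcov
    V[pm_len:, pm_len:] = out.vcov
    return g_nde, g_nie, V


def delta_method_se(
    med: MediatorFit, out: OutcomeFit, spec: MediationSpec
) -> tuple[float, float, float, np.ndarray]:
    """Delta-method SEs ``(se_te, se_nde, se_nie)`` and the joint 2x2
    covariance of (log NDE, log NIE).

    The two models' coefficient blocks are treated as independent and the
    mediator residual variance as fixed.
    """
    g_nde, g_nie, V = _gradients(med, out, spec)
    eig = np.linalg.eigvalsh((V + V.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise np.linalg.LinAlgError("joint coefficient covariance is not PSD")
    cov = np.empty((2, 2))
    cov[0, 0] = g_nde @ V @ g_nde
    cov[1, 1] = g_nie @ V @ g_nie
    cov[0, 1] = cov[1, 0] = g_nde @ V @ g_nie
    var_te = cov.sum()
    return (
        float(np.sqrt(max(var_te, 0.0))),
        float(np.sqrt(max(cov[0, 0], 0.0))),
        float(np.sqrt(max(cov[1, 1], 0.0))),
        cov,
    )


def proportion_mediated(or_nde: float, or_nie: float) -> float:
    """Proportion of the total effect transmitted through the mediator, on
    the OR scale: ``OR_NDE*(OR_NIE - 1) / (OR_NDE*OR_NIE - 1)``."""
    total = or_nde * or_nie
    if abs(total - 1.0) < 1e-12:
        raise ZeroDivisionError("total-effect OR is 1; proportion mediated undefined")
    return or_nde * (or_nie - 1.0) / (total - 1.0)


def _pm_gradient(log_nde: float, log_nie: float) -> np.ndarray:
    A, B = np.exp(log_nde), np.exp(log_nie)
    T = A * B
    d = (T - 1.0) ** 2
    return np.array([-A * (B - 1.0) / d, T * (A - 1.0) / d])


def pm_inference(
    log_nde: float,
    log_nie: float,
    cov: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float, tuple[float, float], tuple[float, float], float]:
    """Delta-method inference for the proportion mediated.

    Returns ``(pm, se, raw_ci, truncated_ci, p)``; the truncated interval
    is clipped to [0, 1] for reporting while the raw interval is kept for
    machine output.  ``p`` tests PM = 0.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("need the joint 2x2 covariance of (log NDE, log NIE)")
    if not np.all(np.isfinite(cov)):
        raise ValueError("degenerate joint covariance")
    pm = proportion_mediated(float(np.exp(log_nde)), float(np.exp(log_nie)))
    g = _pm_gradient(log_nde, log_nie)
    var = float(g @ cov @ g)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = pm - z * se, pm + z * se
    p = _p_from(pm, se)
    return pm, se, (lo, hi), (max(lo, 0.0), min(hi, 1.0)), p


def _p_from(point: float, se: float) -> float:
    if se == 0:
        return 1.0 if point == 0 else 0.0
    return float(2 * stats.norm.sf(abs(point) / se))


def estimate(
    med: MediatorFit,
    out: OutcomeFit,
    spec: MediationSpec,
    outcome_name: str = "",
) -> MediationEstimates:
    """Full mediation estimates: points, SEs, CIs, p-values and PM."""
    log_te, log_nde, log_nie = natural_effects(med, out, spec)
    se_te, se_nde, se_nie, cov = delta_method_se(med, out, spec)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    ci = lambda pt, se: (float(np.exp(pt - z * se)), float(np.exp(pt + z * se)))
    pm, se_pm, ci_raw, ci_trunc, p_pm = pm_inference(log_nde, log_nie, cov, spec.alpha)
    return MediationEstimates(
        log_te=log_te,
        log_nde=log_nde,
        log_nie=log_nie,
        se_log_te=se_te,
        se_log_nde=se_nde,
        se_log_nie=se_nie,
        cov_nde_nie=float(cov[0, 1]),
        or_te=float(np.exp(log_te)),
        or_nde=float(np.exp(log_nde)),
        or_nie=float(np.exp(log_nie)),
        ci_te=ci(log_te, se_te),
        ci_nde=ci(log_nde, se_nde),
        ci_nie=ci(log_nie, se_nie),
        p_te=_p_from(log_te, se_te),
        p_nde=_p_from(log_nde, se_nde),
        p_nie=_p_from(log_nie, se_nie),
        pm=pm,
        se_pm=se_pm,
        ci_pm_raw=ci_raw,
        ci_pm=ci_trunc,
        p_pm=p_pm,
        spec=spec,
        outcome_name=outcome_name,
        n=out.n,
    )


class NaturalEffectsMediator(BaseEstimator):
    """Estimator for natural direct/indirect effects of a continuous
    exposure on a binary outcome through a continuous mediator.

    Fit on a :class:`~frailmed.cohort.CodedDesign` (or a DataFrame with
    coded columns).  Parameters mirror :class:`MediationSpec`; ``a_star``
    and ``a`` default to the sample mean exposure and mean + 1 year, and
    ``c_cond`` to the covariate sample means (only consequential when the
    exposure-mediator interaction is on).

    Attributes set by :meth:`fit` (trailing underscore): ``mediator_fit_``,
    ``outcome_fit_``, ``spec_``, ``estimates_``, ``vif_``, ``n_``.
    """

    def __init__(
        self,
        a: float | None = None,
        a_star: float | None = None,
        interaction: bool = False,
        c_cond=None,
        alpha: float = 0.05,
        exposure: str = "age_years",
        mediator: str = "frailty_index",
        outcome: str = "composite",
        covariates: tuple[str, ...] = COVARIATE_COLUMNS,
    ) -> None:
        self.a = a
        self.a_star = a_star
        self.interaction = interaction
        self.c_cond = c_cond
        self.alpha = alpha
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = covariates

    def _as_design(self, X) -> CodedDesign:
        if isinstance(X, CodedDesign):
            return X
        df = pd.DataFrame(X)
        return CodedDesign(
            outcome=df[self.outcome].to_numpy(dtype=float),
            exposure=df[self.exposure].to_numpy(dtype=float),
            mediator=df[self.mediator].to_numpy(dtype=float),
            covariates=df[list(self.covariates)].to_numpy(dtype=float),
            column_names=tuple(self.covariates),
            outcome_name=self.outcome,
        )

    def fit(self, X, y=None):
        design = self._as_design(X)
        prevalence = float(design.outcome.mean())
        if prevalence > PREVALENCE_WARN:
            warnings.warn(
                f"outcome prevalence {prevalence:.1%} exceeds {PREVALENCE_WARN:.0%}; "
                "the rare-outcome odds-ratio approximation may be strained",
                UserWarning,
                stacklevel=2,
            )
        Xm, ym, m_names = mediator_design(design)
        Xy, yy, o_names = outcome_design(design, self.interaction)
        self.mediator_fit_ = fit_ols(Xm, ym, m_names)
        self.outcome_fit_ = fit_logistic(Xy, yy, o_names, interaction=self.interaction)
        a_star = float(design.exposure.mean()) if self.a_star is None else float(self.a_star)
        a = a_star + 1.0 if self.a is None else float(self.a)
        c_cond = (
            design.covariates.mean(axis=0) if self.c_cond is None else np.asarray(self.c_cond)
        )
        self.spec_ = MediationSpec(
            a=a, a_star=a_star, interaction=self.interaction, c_cond=c_cond, alpha=self.alpha
        )
        self.estimates_ = estimate(
            self.mediator_fit_, self.outcome_fit_, self.spec_, design.outcome_name
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.vif_ = vif(Xy, o_names)
        self.n_ = design.n
        self.prevalence_ = prevalence
        return self


def bootstrap_mediation(
    design: CodedDesign,
    spec: MediationSpec,
    B: int = 2000,
    seed: int | None = None,
    max_dropped_fraction: float = 0.10,
) -> dict:
    """Participant-level nonparametric bootstrap of all mediation quantities.

    Resamples rows with replacement, refits both models per resample and
    returns percentile ``alpha/2`` and ``1 - alpha/2`` bounds plus the
    resample draws.  Resamples that separate or fail to converge are
    dropped and counted; more than ``max_dropped_fraction`` dropped is an
    error (the data are too unstable to bootstrap).
    """
    if B < 200:
        raise ValueError("bootstrap needs B >= 200")
    rng = np.random.default_rng(seed)
    n = design.n
    draws = {k: [] for k in ("log_te", "log_nde", "log_nie", "pm")}
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = CodedDesign(
            outcome=design.outcome[idx],
            exposure=design.exposure[idx],
            mediator=design.mediator[idx],
            covariates=design.covariates[idx],
            column_names=design.column_names,
            outcome_name=design.outcome_name,
        )
        try:
            Xm, ym, m_names = mediator_design(boot)
            Xy, yy, o_names = outcome_design(boot, spec.interaction)
            med = fit_ols(Xm, ym, m_names)
            out = fit_logistic(Xy, yy, o_names, interaction=spec.interaction)
            te, nde, nie = natural_effects(med, out, spec)
            pm = proportion_mediated(float(np.exp(nde)), float(np.exp(nie)))
        except (SeparationError, RuntimeError, np.linalg.LinAlgError, ValueError,
                ZeroDivisionError):
            dropped += 1
            continue
        draws["log_te"].append(te)
        draws["log_nde"].append(nde)
        draws["log_nie"].append(nie)
        draws["pm"].append(pm)
    if dropped > max_dropped_fraction * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap resamples failed (separation/non-convergence); "
            "estimates unstable"
        )
    lo_q, hi_q = spec.alpha / 2, 1 - spec.alpha / 2
    result: dict = {"B": B, "dropped": dropped}
    for key, vals in draws.items():
        arr = np.asarray(vals)
        result[key] = {
            "lo": float(np.quantile(arr, lo_q)),
            "hi": float(np.quantile(arr, hi_q)),
            "se": float(arr.std(ddof=1)),
        }
    for scale_key, log_key in (("or_te", "log_te"), ("or_nde", "log_nde"), ("or_nie", "log_nie")):
        result[scale_key] = {
            "lo": float(np.exp(result[log_key]["lo"])),
            "hi": float(np.exp(result[log_key]["hi"])),
        }
    return result


@dataclass
class InteractionReport:
    """Does age modify the frailty-outcome relationship?  Wald and LR tests
    of the product term, plus the shift in the natural effects when the
    interaction is added."""

    theta3: float
    wald_z: float
    wald_p: float
    lr_stat: float
    lr_df: int
    lr_p: float
    delta_log_nde: float
    delta_log_nie: float
    with_interaction: MediationEstimates | None = None
    without_interaction: MediationEstimates | None = None

    def to_dict(self) -> dict:
        return {
            "theta3": self.theta3,
            "wald_z": self.wald_z,
            "wald_p": self.wald_p,
            "lr_stat": self.lr_stat,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "delta_log_nde": self.delta_log_nde,
            "delta_log_nie": self.delta_log_nie,
        }


def test_interaction(design: CodedDesign, spec: MediationSpec) -> InteractionReport:
    """Fit the outcome model with and without the age x frailty product term
    and report Wald/LR tests alongside the induced change in effects."""
    Xm, ym, m_names = mediator_design(design)
    med = fit_ols(Xm, ym, m_names)

    Xy0, yy, o_names0 = outcome_design(design, interaction=False)
    Xy1, _, o_names1 = outcome_design(design, interaction=True)
    out0 = fit_logistic(Xy0, yy, o_names0, interaction=False)
    out1 = fit_logistic(Xy1, yy, o_names1, interaction=True)

    z, p_wald = wald_test(out1, 3)
    lr_stat, lr_df, lr_p = lr_test(out1, out0)

    spec0 = MediationSpec(
        a=spec.a, a_star=spec.a_star, interaction=False, c_cond=spec.c_cond, alpha=spec.alpha
    )
    spec1 = MediationSpec(
        a=spec.a, a_star=spec.a_star, interaction=True, c_cond=spec.c_cond, alpha=spec.alpha
    )
    est0 = estimate(med, out0, spec0, design.outcome_name)
    est1 = estimate(med, out1, spec1, design.outcome_name)
    return InteractionReport(
        theta3=out1.theta3,
        wald_z=z,
        wald_p=p_wald,
        lr_stat=lr_stat,
        lr_df=lr_df,
        lr_p=lr_p,
        delta_log_nde=est1.log_nde - est0.log_nde,
        delta_log_nie=est1.log_nie - est0.log_nie,
        with_interaction=est1,
        without_interaction=est0,
    )
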
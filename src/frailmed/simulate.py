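"""Synthetic stroke-reperfusion cohorts with known ground truth.

The generator emulates the marginal structure of a reperfusion-treated
ischemic-stroke cohort: age from a truncated normal (mean 67.7, SD 13.1
years, floor 19 — the inclusion criterion is age over 18), sex/race/smoking
as independent categorical draws at the observed prevalences, admission
NIHSS as a rounded lognormal clipped to [0, 42] (median 12, IQR roughly
7-18), a frailty index linear in age with Gaussian noise (or, in
``deficit_level`` mode, 31 Bernoulli deficits with age-dependent logits
whose induced FI-age slope matches the linear coefficient), and a binary
90-day outcome from a logistic model.  Because the generative coefficients
are known, the true natural direct/indirect effects are computable by an
estimator-free counterfactual Monte-Carlo (:func:`true_effects`), which is
the oracle for parameter-recovery and coverage experiments
(:func:`recovery_experiment`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import COVARIATE_COLUMNS, CodedDesign, CohortRecord
from .frailty import DeficitSchema, default_schema
from .glm import SeparationError, fit_logistic, fit_ols
from .mediation import (
    MediationSpec,
    _pm_gradient,
    delta_method_se,
    mediator_design,
    natural_effects,
    outcome_design,
    proportion_mediated,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "TrueEffects",
    "simulate_cohort",
    "simulate_records",
    "simulate_design",
    "true_effects",
    "recovery_experiment",
    "calibrate_theta0",
    "composite_demo_params",
    "mortality_demo_params",
    "rare_outcome_params",
    "strong_interaction_params",
]

#: internal seed for intercept calibration, fixed so presets are stable
_CALIBRATION_SEED = 12345
#: share of deaths among poor composite outcomes used for mRS assignment
_DEATH_SHARE_POOR = 54 / 137


@dataclass
class SimulationParams:
    """Generative truth for one synthetic-cohort scenario.

    ``beta`` = (beta0, beta1, beta2) is the mediator-model truth (beta1 in
    FI units per year), ``sigma`` the mediator residual SD, ``theta`` =
    (theta0..theta4) the outcome-model truth on the logit scale (theta1
    per year of age, theta2 per FI unit, theta3 the age x FI product).
    """

    n: int = 292
    age_mean: float = 67.7
    age_sd: float = 13.1
    age_min: float = 19.0
    p_male: float = 0.565
    p_white: float = 0.890
    smoking_probs: tuple[float, float, float] = (0.517, 0.192, 0.291)
    nihss_meanlog: float = float(np.log(12.0))
    nihss_sdlog: float = 0.70
    beta0: float = -0.0503
    beta1: float = 0.002
    beta2: tuple[float, ...] = (-0.005, 0.0, 0.001, 0.005, 0.005)
    sigma: float = 0.045
    theta0: float = -5.0
    theta1: float = float(np.log(1.02))
    theta2: float = 5.0
    theta3: float = 0.0
    theta4: tuple[float, ...] = (0.0, 0.0, 0.08, 0.0, 0.0)
    outcome_name: str = "composite"
    mediator_mode: str = "gaussian"
    death_share_poor: float = _DEATH_SHARE_POOR

    def __post_init__(self) -> None:
        for p in (self.p_male, self.p_white, *self.smoking_probs):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9:
            raise ValueError("smoking_probs must sum to 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mediator_mode not in ("gaussian", "deficit_level"):
            raise ValueError("mediator_mode must be 'gaussian' or 'deficit_level'")
        if self.outcome_name not in ("composite", "death"):
            raise ValueError("outcome_name must be 'composite' or 'death'")
        if len(self.beta2) != 5 or len(self.theta4) != 5:
            raise ValueError("beta2/theta4 must cover the 5 coded covariates")

    @property
    def covariate_means(self) -> np.ndarray:
        """Expected coded covariates (male, white, NIHSS mean, former,
        current); the NIHSS mean uses the lognormal formula, ignoring the
        mild [0, 42] clipping."""
        nihss_mean = float(np.exp(self.nihss_meanlog + self.nihss_sdlog**2 / 2))
        return np.array(
            [self.p_male, self.p_white, nihss_mean,
             self.smoking_probs[1], self.smoking_probs[2]]
        )

    def with_calibrated_intercept(self, target_prevalence: float) -> "SimulationParams":
        """Return a copy whose theta0 is solved (deterministically, large-n)
        so the generated outcome prevalence matches ``target_prevalence``."""
        t0 = calibrate_theta0(self, target_prevalence)
        return replace(self, theta0=t0)


# deficit_level mode: item prevalences at the mean age, mean 0.10 across
# the 31 packaged items
_ITEM_BASE_PREV = np.linspace(0.01, 0.19, 31)


def _draw_covariates(params: SimulationParams, rng: np.random.Generator, n: int):
    a = (params.age_min - params.age_mean) / params.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
    )
    male = rng.random(n) < params.p_male
    white = rng.random(n) < params.p_white
    smoking = rng.choice(3, size=n, p=params.smoking_probs)  # 0 never, 1 former, 2 current
    nihss = np.clip(
        np.round(rng.lognormal(params.nihss_meanlog, params.nihss_sdlog, size=n)), 0, 42
    )
    C = np.column_stack(
        [male.astype(float), white.astype(float), nihss,
         (smoking == 1).astype(float), (smoking == 2).astype(float)]
    )
    return age, C, smoking


def _deficit_logits(params: SimulationParams, age: np.ndarray) -> np.ndarray:
    """Per-item logits with a common age slope calibrated so the induced
    FI-age slope at the mean age equals beta1."""
    pbar = _ITEM_BASE_PREV
    gamma1 = params.beta1 / float(np.mean(pbar * (1 - pbar)))
    base = special.logit(pbar)
    return base[None, :] + gamma1 * (age[:, None] - params.age_mean)


def _draw_mediator(
    params: SimulationParams, age: np.ndarray, C: np.ndarray, rng: np.random.Generator
):
    """Returns (fi, deficits-or-None, clip_rate)."""
    if params.mediator_mode == "deficit_level":
        probs = special.expit(_deficit_logits(params, age))
        deficits = (rng.random(probs.shape) < probs).astype(float)
        return deficits.mean(axis=1), deficits, 0.0
    mu = params.beta0 + params.beta1 * age + C @ np.asarray(params.beta2)
    raw = mu + rng.normal(0.0, params.sigma, size=age.size)
    fi = np.clip(raw, 0.0, 1.0)
    clip_rate = float(np.mean(raw != fi))
    if clip_rate > 0.05:
        warnings.warn(
            f"{clip_rate:.1%} of mediator draws clipped to [0,1]; generative "
            "truth is distorted",
            UserWarning,
            stacklevel=3,
        )
    return fi, None, clip_rate


def _outcome_prob(params: SimulationParams, age, fi, C) -> np.ndarray:
    lp = (
        params.theta0
        + params.theta1 * age
        + params.theta2 * fi
        + params.theta3 * age * fi
        + C @ np.asarray(params.theta4)
    )
    return special.expit(lp)


def simulate_design(
    params: SimulationParams, seed: int | np.random.Generator | None = None
) -> CodedDesign:
    """Fast path: draw a cohort directly as a coded design (no CSV-shaped
    intermediates); used by the recovery and bootstrap experiments."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    age, C, _ = _draw_covariates(params, rng, params.n)
    fi, _, _ = _draw_mediator(params, age, C, rng)
    y = (rng.random(params.n) < _outcome_prob(params, age, fi, C)).astype(float)
    return CodedDesign(
        outcome=y,
        exposure=age,
        mediator=fi,
        covariates=C,
        column_names=COVARIATE_COLUMNS,
        outcome_name=params.outcome_name,
    )


def _assign_mrs(
    params: SimulationParams, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """mRS consistent with the simulated dichotomy.

    Composite scenario: poor outcomes (Y=1) die with the study's observed
    share of deaths among poor outcomes and are otherwise uniform over
    mRS 3-5, so the same cohort also reproduces the mortality margin;
    good outcomes are uniform over 0-2.  Mortality scenario: Y=1 is
    mRS 6, Y=0 uniform over 0-5.
    """
    n = y.size
    mrs = np.empty(n, dtype=int)
    if params.outcome_name == "composite":
        poor = y == 1
        died = poor & (rng.random(n) < params.death_share_poor)
        mrs[died] = 6
        mrs[poor & ~died] = rng.integers(3, 6, size=int((poor & ~died).sum()))
        mrs[~poor] = rng.integers(0, 3, size=int((~poor).sum()))
    else:
        mrs[y == 1] = 6
        mrs[y == 0] = rng.integers(0, 6, size=int((y == 0).sum()))
    return mrs


def simulate_cohort(
    params: SimulationParams,
    seed: int | None = None,
    schema: DeficitSchema | None = None,
) -> pd.DataFrame:
    """Draw one cohort as a participant-level table.

    Gaussian mediator mode emits a ``frailty_index`` column; deficit mode
    emits one 0/1 column per schema item (the FI is then recomputed
    downstream, exactly matching the Bernoulli-draw ratio).  Fully
    reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    schema = schema if schema is not None else default_schema()
    age, C, smoking = _draw_covariates(params, rng, params.n)
    fi, deficits, _ = _draw_mediator(params, age, C, rng)
    y = (rng.random(params.n) < _outcome_prob(params, age, fi, C)).astype(int)
    mrs = _assign_mrs(params, y, rng)
    df = pd.DataFrame(
        {
            "id": [f"sim{i:06d}" for i in range(params.n)],
            "age_years": age,
            "sex": np.where(C[:, 0] == 1, "male", "female"),
            "race": np.where(C[:, 1] == 1, "white", "black"),
            "smoking": np.array(["never", "former", "current"])[smoking],
            "nihss": C[:, 2].astype(int),
            "mrs_90d": mrs,
            "died_90d": mrs == 6,
        }
    )
    if deficits is not None:
        if deficits.shape[1] != schema.size:
            raise ValueError("schema size does not match the simulated deficit count")
        for j, name in enumerate(schema.names):
            df[name] = deficits[:, j].astype(int)
    else:
        df["frailty_index"] = fi
    return df


def simulate_records(
    params: SimulationParams,
    seed: int | None = None,
    schema: DeficitSchema | None = None,
) -> list[CohortRecord]:
    """Like :func:`simulate_cohort` but as validated records."""
    schema = schema if schema is not None else default_schema()
    df = simulate_cohort(params, seed, schema)
    has_deficits = schema.names[0] in df.columns
    records = []
    for _, row in df.iterrows():
        rec = CohortRecord(
            id=row["id"],
            age_years=float(row["age_years"]),
            sex=row["sex"],
            race=row["race"],
            smoking=row["smoking"],
            nihss=float(row["nihss"]),
            deficits=(
                np.array([float(row[n]) for n in schema.names]) if has_deficits else None
            ),
            frailty_index=(None if has_deficits else float(row["frailty_index"])),
            mrs_90d=int(row["mrs_90d"]),
            died_90d=bool(row["died_90d"]),
        )
        rec.validate(schema if has_deficits else None)
        records.append(rec)
    return records


def calibrate_theta0(
    params: SimulationParams, target_prevalence: float, n: int = 400_000
) -> float:
    """Solve the outcome-model intercept so the marginal outcome prevalence
    hits ``target_prevalence``, by root-finding on one large deterministic
    draw of (age, covariates, mediator)."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    big = replace(params, n=n)
    age, C, _ = _draw_covariates(big, rng, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fi, _, _ = _draw_mediator(big, age, C, rng)
    rest = (
        params.theta1 * age
        + params.theta2 * fi
        + params.theta3 * age * fi
        + C @ np.asarray(params.theta4)
    )

    def gap(t0: float) -> float:
        return float(np.mean(special.expit(t0 + rest))) - target_prevalence

    return float(optimize.brentq(gap, -30.0, 10.0, xtol=1e-10))


def composite_demo_params(n: int = 292) -> SimulationParams:
    """Demo scenario echoing the motivating cohort: composite poor outcome
    (mRS > 2) at 46.9% prevalence, mediator mean 0.10, direct OR about
    1.02/year and mediated OR about 1.01/year (proportion mediated near a
    third).  Illustrative, not a reproduction of any real cohort."""
    p = SimulationParams(n=n, outcome_name="composite")
    return p.with_calibrated_intercept(137 / 292)


def mortality_demo_params(n: int = 292) -> SimulationParams:
    """Demo scenario calibrated to the 18.5% 90-day mortality margin."""
    p = SimulationParams(n=n, outcome_name="death")
    return p.with_calibrated_intercept(54 / 292)


def rare_outcome_params(
    n: int = 5000, interaction: bool = False, prevalence: float = 0.02
) -> SimulationParams:
    """Rare-outcome regime where the odds-ratio natural-effect formulas are
    near-exact: ~2% prevalence, mediator mean 0.13 with SD 0.035 so that
    [0,1] clipping is negligible (~0.1% of draws)."""
    p = SimulationParams(
        n=n,
        outcome_name="death",
        beta0=0.13 - 0.002 * 67.7 - float(
            np.asarray((-0.005, 0.0, 0.001, 0.005, 0.005))
            @ SimulationParams().covariate_means
        ),
        sigma=0.035,
        theta3=0.04 if interaction else 0.0,
    )
    return p.with_calibrated_intercept(prevalence)


def strong_interaction_params(
    n: int = 2000, theta3: float = 0.6, prevalence: float = 0.2
) -> SimulationParams:
    """Scenario with a detectable age x frailty interaction.

    theta2 is offset by ``-theta3 * mean age`` so the frailty slope at the
    mean age stays at its usual value; otherwise the total slope
    ``theta2 + theta3*age`` saturates the probabilities and the
    interaction becomes undetectable at any sample size."""
    base = rare_outcome_params(n=n, prevalence=prevalence)
    p = replace(base, theta3=theta3, theta2=base.theta2 - theta3 * base.age_mean)
    return p.with_calibrated_intercept(prevalence)


@dataclass
class TrueEffects:
    """Estimator-free counterfactual ground truth with Monte-Carlo SEs."""

    or_te: float
    or_nde: float
    or_nie: float
    pm: float
    log_te: float
    log_nde: float
    log_nie: float
    se_log_te: float
    se_log_nde: float
    se_log_nie: float
    se_pm: float
    n_mc: int
    a: float
    a_star: float
    c_cond: np.ndarray


def true_effects(
    params: SimulationParams,
    a: float | None = None,
    a_star: float | None = None,
    c_cond=None,
    n_mc: int = 10**6,
    seed: int | None = None,
) -> TrueEffects:
    """Counterfactual Monte-Carlo evaluation of the true natural effects.

    Draws the mediator under the reference and comparison exposures
    (independent draws per counterfactual arm, so the Monte-Carlo SEs are
    the plain ones), averages the outcome-model probabilities at the
    conditioning covariates c_cond, and converts

        P[Y(a, M(a))], P[Y(a, M(a*))], P[Y(a*, M(a*))]

    into odds ratios.  Mirrors the generator exactly, including the [0,1]
    clipping in gaussian mode and the Bernoulli deficits in deficit mode,
    so it is the ground truth for the data the generator emits.
    """
    if n_mc < 10**5:
        raise ValueError("n_mc must be at least 1e5 for a usable oracle")
    a_star = params.age_mean if a_star is None else float(a_star)
    a = a_star + 1.0 if a is None else float(a)
    c = params.covariate_means if c_cond is None else np.asarray(c_cond, dtype=float)
    rng = np.random.default_rng(seed)

    def draw_m(age_val: float) -> np.ndarray:
        if params.mediator_mode == "deficit_level":
            p = special.expit(_deficit_logits(params, np.full(1, age_val)))[0]
            chunks = []
            for start in range(0, n_mc, 10**6):  # bound memory for large n_mc
                size = min(10**6, n_mc - start)
                chunks.append((rng.random((size, p.size)) < p[None, :]).mean(axis=1))
            return np.concatenate(chunks)
        base = params.beta0 + float(np.asarray(params.beta2) @ c)
        return np.clip(
            base + params.beta1 * age_val + rng.normal(0.0, params.sigma, size=n_mc),
            0.0, 1.0,
        )

    cc = np.broadcast_to(c, (n_mc, c.size))
    s11 = _outcome_prob(params, a, draw_m(a), cc)           # Y(a, M(a))
    s10 = _outcome_prob(params, a, draw_m(a_star), cc)      # Y(a, M(a*))
    s00 = _outcome_prob(params, a_star, draw_m(a_star), cc)  # Y(a*, M(a*))
    P = np.array([s11.mean(), s10.mean(), s00.mean()])
    # the three arms use independent draws, so the means are independent
    S = np.diag([s11.var(ddof=1), s10.var(ddof=1), s00.var(ddof=1)]) / n_mc

    logit = lambda p: np.log(p / (1 - p))
    dlogit = 1.0 / (P * (1 - P))
    log_nde = logit(P[1]) - logit(P[2])
    log_nie = logit(P[0]) - logit(P[1])
    log_te = log_nde + log_nie
    g_nde = np.array([0.0, dlogit[1], -dlogit[2]])
    g_nie = np.array([dlogit[0], -dlogit[1], 0.0])
    cov2 = np.empty((2, 2))
    cov2[0, 0] = g_nde @ S @ g_nde
    cov2[1, 1] = g_nie @ S @ g_nie
    cov2[0, 1] = cov2[1, 0] = g_nde @ S @ g_nie
    or_nde, or_nie = float(np.exp(log_nde)), float(np.exp(log_nie))
    pm = proportion_mediated(or_nde, or_nie)
    g_pm = _pm_gradient(log_nde, log_nie)
    return TrueEffects(
        or_te=float(np.exp(log_te)),
        or_nde=or_nde,
        or_nie=or_nie,
        pm=float(pm),
        log_te=float(log_te),
        log_nde=float(log_nde),
        log_nie=float(log_nie),
        se_log_te=float(np.sqrt(max(cov2.sum(), 0.0))),
        se_log_nde=float(np.sqrt(max(cov2[0, 0], 0.0))),
        se_log_nie=float(np.sqrt(max(cov2[1, 1], 0.0))),
        se_pm=float(np.sqrt(max(g_pm @ cov2 @ g_pm, 0.0))),
        n_mc=n_mc,
        a=a,
        a_star=a_star,
        c_cond=c,
    )


@dataclass
class RecoveryResult:
    """Parameter-recovery experiment output."""

    table: pd.DataFrame
    truth: TrueEffects
    n_reps: int
    n_failed: int
    estimates: pd.DataFrame


def recovery_experiment(
    params: SimulationParams,
    n_reps: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
    n_mc: int = 10**7,
) -> RecoveryResult:
    """Repeatedly simulate -> fit -> estimate, and tabulate bias, Monte-Carlo
    SE of the bias, RMSE and CI coverage for log NDE, log NIE and PM
    against the counterfactual truth.

    With ``n_reps == 1`` the table reports single-replicate errors and no
    coverage column.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    rng = np.random.default_rng(seed)
    truth = true_effects(params, n_mc=n_mc, seed=int(rng.integers(2**31)))
    spec = MediationSpec(
        a=truth.a,
        a_star=truth.a_star,
        interaction=params.theta3 != 0.0,
        c_cond=truth.c_cond,
        alpha=alpha,
    )
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        design = simulate_design(params, rng)
        try:
            Xm, ym, m_names = mediator_design(design)
            Xy, yy, o_names = outcome_design(design, spec.interaction)
            med = fit_ols(Xm, ym, m_names)
            out = fit_logistic(Xy, yy, o_names, interaction=spec.interaction)
            _, log_nde, log_nie = natural_effects(med, out, spec)
            _, se_nde, se_nie, cov = delta_method_se(med, out, spec)
            pm = proportion_mediated(float(np.exp(log_nde)), float(np.exp(log_nie)))
        except (SeparationError, RuntimeError, np.linalg.LinAlgError, ZeroDivisionError):
            n_failed += 1
            continue
        rows.append(
            {
                "log_nde": log_nde,
                "log_nie": log_nie,
                "pm": pm,
                "se_log_nde": se_nde,
                "se_log_nie": se_nie,
                "cover_nde": abs(log_nde - truth.log_nde) <= z * se_nde,
                "cover_nie": abs(log_nie - truth.log_nie) <= z * se_nie,
            }
        )
    est = pd.DataFrame(rows)
    if est.empty:
        raise RuntimeError("every replicate failed; cannot summarise recovery")
    out_rows = []
    for qty, truth_val, cover_col in (
        ("log_nde", truth.log_nde, "cover_nde"),
        ("log_nie", truth.log_nie, "cover_nie"),
        ("pm", truth.pm, None),
    ):
        vals = est[qty].to_numpy()
        bias = float(vals.mean() - truth_val)
        mc_se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        row = {
            "quantity": qty,
            "truth": truth_val,
            "mean_estimate": float(vals.mean()),
            "bias": bias,
            "mc_se": mc_se,
            "rmse": float(np.sqrt(np.mean((vals - truth_val) ** 2))),
        }
        if cover_col is not None and len(vals) > 1:
            row["coverage"] = float(est[cover_col].mean())
        out_rows.append(row)
    return RecoveryResult(
        table=pd.DataFrame(out_rows),
        truth=truth,
        n_reps=n_reps,
        n_failed=n_failed,
        estimates=est,
    )
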
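"""Stage/sex inference over the TFA metric table.

Each metric x vessel x component x pacing-frequency cell is modelled
separately with a linear mixed-effects model: a random intercept per
participant and fixed effects for CO2 stage (eucapnia as reference, giving
hypocapnia and hypercapnia contrasts) and sex (female as reference).  Models
are fitted by maximum likelihood so the likelihood-ratio test against the
fixed-effects-free null (random intercept only) is valid; the LR statistic is
referred to a chi-squared distribution with 3 degrees of freedom (two stage
contrasts plus one sex contrast).  No multiple-testing correction is applied:
each cell is reported on its own, as is conventional for these repeated-
measures physiology designs.

The a-priori sample-size computation for a single regression coefficient uses
the large-sample normal approximation
``n = ceil((z_{1-alpha} + z_{power})^2 / f^2)``, which with a large effect
size f^2 = 0.35, alpha = 0.05 one-tailed and power 0.80 gives n = 18.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scs
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ConvergenceError, ValidationError

__all__ = [
    "LmeResult",
    "PowerSpec",
    "fit_stage_sex_lme",
    "lr_test",
    "required_sample_size",
    "simulate_metric_table",
]

_STAGE_TERM = "C(stage, Treatment('eucapnia'))"
_SEX_TERM = "C(sex, Treatment('female'))"
_FULL_FORMULA = f"value ~ {_STAGE_TERM} + {_SEX_TERM}"


@dataclass
class LmeResult:
    """Fixed-effect estimates from one stage/sex mixed model."""

    beta_hypocapnia: float
    beta_hypercapnia: float
    beta_sex_male: float
    ci95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    loglik_full: float
    loglik_null: float
    lr_stat: float
    lr_p: float
    converged: bool
    n_obs: int
    n_participants: int


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power analysis inputs.

    ``n_predictors`` is carried for the record; the normal-approximation
    formula for a single coefficient does not use it.
    """

    f_squared: float = 0.35
    alpha: float = 0.05
    power: float = 0.80
    tails: str = "one"  # one | two
    n_predictors: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValidationError("power must lie in (0, 1)")
        if self.f_squared <= 0:
            raise ValidationError("f_squared must be positive")
        if self.tails not in ("one", "two"):
            raise ValidationError("tails must be 'one' or 'two'")


def simulate_metric_table(
    rng: np.random.Generator,
    stage_effects: dict[str, float] | None = None,
    sex_effect: float = 0.0,
    intercept: float = 0.47,
    subject_sd: float = 0.10,
    residual_sd: float = 0.10,
    n_per_sex: int = 10,
) -> pd.DataFrame:
    """Simulate one long-format metric cell for calibration studies.

    One value per participant x stage, with a Gaussian participant random
    intercept and residual.  The defaults mimic a phase-like metric: an
    eucapnic level of 0.47 rad with between-subject and residual spreads of
    0.1 rad each, at the emulated design size of 10 + 10 participants across
    three CO2 stages.  Used to study the calibration (type-I error) and
    directional power of the stage/sex mixed model.
    """
    stage_effects = stage_effects or {}
    rows = []
    for p in range(2 * n_per_sex):
        sex = "female" if p < n_per_sex else "male"
        u = rng.normal(0.0, subject_sd)
        for stage in ("hypocapnia", "eucapnia", "hypercapnia"):
            value = (
                intercept
                + stage_effects.get(stage, 0.0)
                + (sex_effect if sex == "male" else 0.0)
                + u
                + rng.normal(0.0, residual_sd)
            )
            rows.append((f"P{p:02d}", sex, stage, value))
    return pd.DataFrame(rows, columns=["participant", "sex", "stage", "value"])


def fit_stage_sex_lme(
    table: pd.DataFrame,
    metric_name: str | None = None,
    vessel: str | None = None,
    component: str | None = None,
    ssm_frequency: float | None = None,
) -> LmeResult:
    """Fit the stage + sex mixed model for one metric cell.

    ``table`` is the long-format metric table; the optional selectors filter
    it down to one metric x vessel x component x frequency cell first.  The
    model has a participant random intercept and is fitted by ML, and is
    compared against the intercept-plus-random-effect null with an LR test on
    3 degrees of freedom.
    """
    df = table
    for col, val in (
        ("metric_name", metric_name),
        ("vessel", vessel),
        ("component", component),
        ("ssm_frequency", ssm_frequency),
    ):
        if val is not None:
            if col not in df.columns:
                raise ValidationError(f"metric table lacks column {col!r}")
            df = df[df[col] == val]
    df = df.copy()
    for col in ("participant", "sex", "stage", "value"):
        if col not in df.columns:
            raise ValidationError(f"metric table lacks column {col!r}")

    n_participants = df["participant"].nunique()
    if n_participants < 2:
        raise ValidationError("need at least 2 participants for a random intercept")
    stages_per = df.groupby("participant")["stage"].nunique()
    if (stages_per >= 2).sum() < 2:
        raise ValidationError("need >= 2 participants observed in >= 2 stages")
    if df["value"].var(ddof=0) <= 0:
        raise ValidationError("outcome has zero variance")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            full = smf.mixedlm(_FULL_FORMULA, df, groups=df["participant"]).fit(reml=False)
            null = smf.mixedlm("value ~ 1", df, groups=df["participant"]).fit(reml=False)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                full = smf.mixedlm(_FULL_FORMULA, df, groups=df["participant"]).fit(reml=False)
                null = smf.mixedlm("value ~ 1", df, groups=df["participant"]).fit(reml=False)
    converged = converged and bool(full.converged) and bool(null.converged)
    if not np.isfinite(full.llf) or not np.isfinite(null.llf):
        raise ConvergenceError("mixed-model likelihood did not converge")

    names = {
        "beta_hypocapnia": f"{_STAGE_TERM}[T.hypocapnia]",
        "beta_hypercapnia": f"{_STAGE_TERM}[T.hypercapnia]",
        "beta_sex_male": f"{_SEX_TERM}[T.male]",
    }
    params = full.params
    ci = full.conf_int(alpha=0.05)
    betas, ci95, pvals = {}, {}, {}
    for label, term in names.items():
        if term in params.index:
            betas[label] = float(params[term])
            ci95[label] = (float(ci.loc[term, 0]), float(ci.loc[term, 1]))
            pvals[label] = float(full.pvalues[term])
        else:  # contrast absent (e.g. single-sex or two-stage designs)
            betas[label] = np.nan
            ci95[label] = (np.nan, np.nan)
            pvals[label] = np.nan

    df_lr = sum(1 for t in names.values() if t in params.index)
    lr_stat = max(0.0, 2.0 * (full.llf - null.llf))
    lr_p = lr_test(full.llf, null.llf, df=max(df_lr, 1))
    return LmeResult(
        beta_hypocapnia=betas["beta_hypocapnia"],
        beta_hypercapnia=betas["beta_hypercapnia"],
        beta_sex_male=betas["beta_sex_male"],
        ci95=ci95,
        p_values=pvals,
        loglik_full=float(full.llf),
        loglik_null=float(null.llf),
        lr_stat=lr_stat,
        lr_p=lr_p,
        converged=converged,
        n_obs=len(df),
        n_participants=int(n_participants),
    )


def lr_test(loglik_full: float, loglik_null: float, df: int = 3) -> float:
    """Likelihood-ratio p-value for nested ML fits.

    ``p = P(chi2_df >= 2 * (llf_full - llf_null))`` with the statistic clipped
    at zero.  The full model's likelihood may not be meaningfully below the
    null's (they are nested); a deficit beyond numerical tolerance indicates a
    failed fit and raises.
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    tol = 1e-6 * (1.0 + abs(loglik_null))
    if loglik_full < loglik_null - tol:
        raise ValidationError(
            "full-model log-likelihood is below the null's beyond tolerance; "
            "the full fit likely failed"
        )
    stat = max(0.0, 2.0 * (loglik_full - loglik_null))
    return float(scs.chi2.sf(stat, df))


def required_sample_size(spec: PowerSpec) -> int:
    """Sample size for detecting a single coefficient of effect size f^2.

    Large-sample normal approximation:
    ``n = ceil((z_{1-alpha} + z_{power})^2 / f_squared)`` for a one-tailed
    test, with ``z_{1-alpha/2}`` replacing ``z_{1-alpha}`` for two tails.
    """
    z_alpha = (
        scs.norm.ppf(1.0 - spec.alpha)
        if spec.tails == "one"
        else scs.norm.ppf(1.0 - spec.alpha / 2.0)
    )
    z_power = scs.norm.ppf(spec.power)
    return int(np.ceil((z_alpha + z_power) ** 2 / spec.f_squared))
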
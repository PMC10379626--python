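"""Mixed-effects inference on the carving and fit outcomes.

Three linear mixed-effects model shapes are used, all fit by REML:

* ``eq1`` — on-snow turn metrics: fixed configuration, turn-direction and
  trial-number effects with a per-subject random intercept and a random
  configuration slope, ``Outcome ~ Config + TurnDirection + TrialNo +
  (Config | Subject)``.
* ``eq2`` — subjective scores (one observation per subject and boot):
  ``Outcome ~ Config + (1 | Subject)``.
* ``eq3`` — in-lab static pressures, pooling both BOA tension conditions and
  adjusting for shell overlap: ``Outcome ~ Config + Overlap + (1 | Subject)``.

Group differences are reported as percent differences between the
estimated marginal means (EMMs) of the two configurations.  The EMM
reference grid holds turn direction at its observed proportion and
trial number / overlap at their observed means, with random effects at
zero; the configuration p-value is the large-sample Wald test of the
configuration coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "ModelError",
    "transform_fit_score",
    "fit_model",
    "summarize_effects",
    "MODEL_COVARIATES",
]

logger = logging.getLogger(__name__)

MODEL_COVARIATES = {
    "eq1": ("turn_direction", "trial_no"),
    "eq2": (),
    "eq3": ("overlap",),
}


class ModelError(ValueError):
    """The data cannot support the requested model."""


@dataclass(frozen=True)
class EffectEstimate:
    """Fitted configuration effect for one outcome under one model."""

    outcome: str
    model_id: str
    fixed_effects: dict          # name -> (coefficient, standard error)
    emm_boa: float
    emm_buckle: float
    percent_difference: float    # 100 * (EMM_BOA - EMM_Buckle) / EMM_Buckle
    p_value_config: float
    n_obs: int
    n_subjects: int
    random_slope: bool
    fell_back_to_intercept: bool = False


def transform_fit_score(score: float) -> float:
    """Fold a 0–10 regional fit rating onto a 0–5 badness scale.

    On the raw scale 5 is a perfect fit, 0 too loose and 10 too tight; the
    transformed score ``|score - 5|`` is 0 when optimal and 5 at either
    extreme, so smaller is better.
    """
    s = np.asarray(score, dtype=float)
    if np.any((s < 0) | (s > 10)):
        raise ValueError("fit scores must lie in [0, 10]")
    out = np.abs(s - 5.0)
    return float(out) if out.ndim == 0 else out


def _design(records: pd.DataFrame, model_id: str, outcome: str):
    needed = {"subject_id", "config", outcome} | set(MODEL_COVARIATES[model_id])
    missing = needed - set(records.columns)
    if missing:
        raise ModelError(f"{model_id}: missing columns {sorted(missing)}")
    df = records.dropna(subset=sorted(needed)).copy()
    configs = set(df["config"])
    if not configs == {"BOA", "Buckle"}:
        raise ModelError(f"need both configurations, got {sorted(configs)}")
    if df["subject_id"].nunique() < 2:
        raise ModelError("need at least 2 subjects")
    exog = pd.DataFrame(index=df.index)
    exog["Intercept"] = 1.0
    exog["config_boa"] = (df["config"] == "BOA").astype(float)
    if "turn_direction" in MODEL_COVARIATES[model_id]:
        exog["dir_left"] = (df["turn_direction"] == "left").astype(float)
    if "trial_no" in MODEL_COVARIATES[model_id]:
        exog["trial_no"] = df["trial_no"].astype(float)
    if "overlap" in MODEL_COVARIATES[model_id]:
        exog["overlap"] = df["overlap"].astype(float)
    return df, exog


def _fit_mixed(endog, exog, groups, exog_re):
    """REML fit; returns None when the likelihood is numerically degenerate
    (e.g. zero residual variance in noise-free simulations)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        try:
            return model.fit(reml=True, method=["lbfgs", "cg"], maxiter=200)
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            return None


def _is_singular(result, k_re: int) -> bool:
    if result is None or not result.converged:
        return True
    cov = np.atleast_2d(np.asarray(result.cov_re))
    if cov.shape[0] != k_re:
        return True
    eig = np.linalg.eigvalsh(cov)
    scale = max(result.scale, eig.max(), 1e-12)
    return bool(eig.min() < 1e-8 * scale)


def fit_model(records: pd.DataFrame, model_id: str, outcome: str) -> EffectEstimate:
    """REML fit of one model shape for one outcome column.

    ``records`` is a tidy table with one row per observation and columns
    ``subject_id``, ``config`` (BOA/Buckle), the outcome, and the covariates
    the model requires (``turn_direction`` and ``trial_no`` for eq1,
    ``overlap`` for eq3).

    A singular or non-converged random-slope fit under eq1 falls back to a
    random-intercept-only structure with a logged warning.
    """
    if model_id not in MODEL_COVARIATES:
        raise ModelError(f"unknown model {model_id!r}")
    df, exog = _design(records, model_id, outcome)
    endog = df[outcome].astype(float).to_numpy()
    groups = df["subject_id"].to_numpy()

    want_slope = model_id == "eq1"
    fell_back = False
    result = None
    if want_slope:
        exog_re = exog[["Intercept", "config_boa"]].to_numpy()
        result = _fit_mixed(endog, exog.to_numpy(), groups, exog_re)
        if _is_singular(result, 2):
            logger.warning(
                "singular random-slope fit for %s under eq1; "
                "falling back to random intercept only", outcome,
            )
            fell_back = True
            result = None
    if result is None:
        result = _fit_mixed(endog, exog.to_numpy(), groups, exog[["Intercept"]].to_numpy())

    k_fe = exog.shape[1]
    names = list(exog.columns)
    if result is not None:
        params = np.asarray(result.params)[:k_fe]
        bse = np.asarray(result.bse)[:k_fe]
    else:
        # Degenerate likelihood (e.g. a noise-free simulation): the fixed
        # effects are still identified; estimate them by least squares.
        logger.warning("mixed fit degenerate for %s/%s; using least squares",
                       model_id, outcome)
        ols = sm.OLS(endog, exog.to_numpy()).fit()
        params = np.asarray(ols.params)
        bse = np.asarray(ols.bse)
    fixed = {n: (float(b), float(s)) for n, b, s in zip(names, params, bse)}

    # EMM reference grid: covariates at observed means, random effects at zero.
    ref = exog.mean(axis=0)
    grid = {}
    for cfg, ind in (("BOA", 1.0), ("Buckle", 0.0)):
        row = ref.copy()
        row["Intercept"] = 1.0
        row["config_boa"] = ind
        grid[cfg] = float(row.to_numpy() @ params)
    emm_boa, emm_buckle = grid["BOA"], grid["Buckle"]
    pct = 100.0 * (emm_boa - emm_buckle) / emm_buckle

    i = names.index("config_boa")
    z = params[i] / bse[i] if bse[i] > 0 else np.inf
    from scipy.stats import norm

    p = float(2.0 * norm.sf(abs(z)))
    return EffectEstimate(
        outcome=outcome,
        model_id=model_id,
        fixed_effects=fixed,
        emm_boa=emm_boa,
        emm_buckle=emm_buckle,
        percent_difference=float(pct),
        p_value_config=p,
        n_obs=len(df),
        n_subjects=int(df["subject_id"].nunique()),
        random_slope=want_slope and not fell_back,
        fell_back_to_intercept=fell_back,
    )


def summarize_effects(estimates: list[EffectEstimate], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy report table: one row per fitted outcome, flagged at ``alpha``."""
    rows = [
        {
            "outcome": e.outcome,
            "model": e.model_id,
            "emm_boa": e.emm_boa,
            "emm_buckle": e.emm_buckle,
            "percent_difference": e.percent_difference,
            "p_value": e.p_value_config,
            "significant": e.p_value_config < alpha,
            "n_obs": e.n_obs,
            "n_subjects": e.n_subjects,
        }
        for e in estimates
    ]
    cols = [
        "outcome", "model", "emm_boa", "emm_buckle",
        "percent_difference", "p_value", "significant", "n_obs", "n_subjects",
    ]
    return pd.DataFrame(rows, columns=cols)
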
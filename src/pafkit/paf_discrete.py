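"""PAF and impact fractions for categorical risk factors under all designs.

Two estimation routes exist and are deliberately kept separate:

* the *direct* route standardises model predictions, reweighting cases and
  controls (and recalibrating the linear predictor) when a prevalence is
  supplied;
* the *Bruzzi* route needs only relative risks among cases and works without
  knowing the disease prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CohortTable, RiskFactorSpec, make_case_control_weights
from .model_adapters import OutcomeModelAdapter, recalibrate_to_prevalence


@dataclass
class PafResult:
    estimand: str
    estimate: float | np.ndarray
    method: str
    t_vector: np.ndarray | None = None
    ci: object = None
    meta: dict = field(default_factory=dict)

    def __float__(self):
        return float(np.asarray(self.estimate).ravel()[0])

    def __repr__(self):
        base = f"PafResult({self.estimand}: {np.round(self.estimate, 6)}, method={self.method}"
        if self.ci is not None:
            base += f", ci={self.ci}"
        return base + ")"


def _counterfactual_frame(table: CohortTable, rf: RiskFactorSpec) -> pd.DataFrame:
    """Copy of the table with the risk factor set to its reference level."""
    df = table.df.copy()
    col = df[rf.name]
    observed = set(col.dropna().unique())
    if isinstance(col.dtype, pd.CategoricalDtype):
        if rf.refval not in col.cat.categories:
            raise ValueError(f"refval {rf.refval!r} not a level of {rf.name!r}")
        df[rf.name] = pd.Categorical([rf.refval] * len(df), categories=col.cat.categories)
    else:
        if rf.refval not in observed and not rf.levels:
            raise ValueError(f"refval {rf.refval!r} not observed for {rf.name!r}")
        df[rf.name] = rf.refval
    return df


def _resolve_weights(table: CohortTable, weights) -> np.ndarray | None:
    if weights is None:
        return None
    if isinstance(weights, str):
        return table.df[weights].to_numpy(dtype=float)
    return np.asarray(weights, dtype=float)


def impact_fraction_direct(
    model: OutcomeModelAdapter,
    table: CohortTable,
    new_df: pd.DataFrame,
    weights=None,
    prevalence: float | None = None,
) -> float:
    """Weighted standardisation: ``(sum w p_obs - sum w p_new) / sum w p_obs``.

    When a prevalence is given, case-control weights are rebuilt from it and
    an offset is added to the linear predictor so the weighted mean predicted
    probability matches the prevalence (the same offset is applied to the
    counterfactual predictions).
    """
    if len(new_df) != table.n:
        raise ValueError("new_data must have the same number of rows as the table")
    from scipy.special import expit

    w = _resolve_weights(table, weights)
    if prevalence is not None:
        if w is not None:
            warnings.warn("both prevalence and weights supplied: prevalence-based "
                          "weights take precedence for the direct method")
        w = make_case_control_weights(table, prevalence)
        old_offset = model.offset_delta
        model.offset_delta = 0.0
        try:
            recalibrate_to_prevalence(model, table, w, prevalence)
            if model.family == "conditional_logit":
                # predictions on the probability scale via the solved offset
                p_obs = expit(model.linear_predictor(table.df) + model.offset_delta)
                p_new = expit(model.linear_predictor(new_df) + model.offset_delta)
            else:
                p_obs = model.predict(table.df)
                p_new = model.predict(new_df)
        finally:
            model.offset_delta = old_offset
    else:
        if w is None:
            w = np.ones(table.n)
        if model.family in ("conditional_logit",):
            raise ValueError("the direct method with a conditional-logistic model "
                             "requires a prevalence")
        p_obs = model.predict(table.df)
        p_new = model.predict(new_df)
    denom = float(np.sum(w * p_obs))
    if denom <= 0:
        raise ValueError("no predicted disease mass in the observed data")
    return float((np.sum(w * p_obs) - np.sum(w * p_new)) / denom)


def impact_fraction_bruzzi(
    model: OutcomeModelAdapter,
    table: CohortTable,
    new_df: pd.DataFrame,
    weights=None,
) -> float:
    """Case-only formula ``1 - (1/N_c) sum_cases RR_new / RR_obs`` where the
    relative risks come from ``exp`` of the linear predictor (an odds-ratio
    approximation for logistic-type models)."""
    if len(new_df) != table.n:
        raise ValueError("new_data must have the same number of rows as the table")
    w = _resolve_weights(table, weights)
    if w is None:
        w = np.ones(table.n)
    y = table.y
    cases = y == 1
    if cases.sum() < 1:
        raise ValueError("Bruzzi method needs at least one case")
    if model.family in ("binomial_logit", "binomial_log"):
        # true relative risks from predicted probabilities
        p_obs = np.asarray(model.predict(table.df))
        p_new = np.asarray(model.predict(new_df))
        if (p_obs[cases] == 0).any():
            raise ValueError("infinite relative-risk ratio encountered (RR = 0 case)")
        ratio = p_new[cases] / p_obs[cases]
    else:
        # conditional logistic: probabilities not identified, use the
        # odds-ratio approximation exp(lp contrast)
        lp_obs = model.linear_predictor(table.df)
        lp_new = model.linear_predictor(new_df)
        ratio = np.exp(lp_new[cases] - lp_obs[cases])
    if not np.isfinite(ratio).all():
        raise ValueError("infinite relative-risk ratio encountered (RR = 0 case)")
    return float(1.0 - np.sum(w[cases] * ratio) / np.sum(w[cases]))


def impact_fraction_survival(
    model: OutcomeModelAdapter,
    table: CohortTable,
    new_df: pd.DataFrame,
    t_vector,
) -> tuple[np.ndarray, np.ndarray]:
    """PAF(t) over ``t_vector`` from a proportional-hazards adapter.

    Each requested time is snapped to the nearest observed event time.
    Returns ``(times_used, estimates)``.
    """
    if model.extras is None:
        raise ValueError("survival impact fractions need a prop_hazards model")
    hr_obs = model.predict(table.df)
    hr_new = model.predict(new_df)
    ts, ests = [], []
    for t in np.atleast_1d(np.asarray(t_vector, dtype=float)):
        t_used, H0 = model.extras.nearest_event_time(t)
        if H0 <= 0:
            raise ValueError(f"no cumulative incidence at t={t}")
        p_obs = 1.0 - np.exp(-H0 * hr_obs)
        p_new = 1.0 - np.exp(-H0 * hr_new)
        ts.append(t_used)
        ests.append((p_obs.mean() - p_new.mean()) / p_obs.mean())
    return np.asarray(ts), np.asarray(ests)


def impact_fraction(
    model: OutcomeModelAdapter,
    table: CohortTable,
    new_table,
    weights=None,
    prevalence: float | None = None,
    method: str = "bruzzi",
    t_vector=None,
) -> PafResult:
    """Impact fraction for an arbitrary intervention described by ``new_table``
    (same shape as ``table``, risk factor / covariate values changed)."""
    new_df = new_table.df if isinstance(new_table, CohortTable) else pd.DataFrame(new_table)
    if sorted(new_df.columns) != sorted(table.df.columns):
        raise ValueError("new_data must carry the same columns as the table")
    if model.family == "prop_hazards":
        ts, est = impact_fraction_survival(model, table, new_df, t_vector)
        return PafResult("impact_fraction", est, "survival", t_vector=ts)
    if method in ("bruzzi", "B"):
        est = impact_fraction_bruzzi(model, table, new_df, weights)
        return PafResult("impact_fraction", est, "bruzzi")
    if method in ("direct", "D"):
        est = impact_fraction_direct(model, table, new_df, weights, prevalence)
        return PafResult("impact_fraction", est, "direct",
                         meta={"prevalence": prevalence})
    raise ValueError(f"unknown method {method!r}")


def paf_direct(
    model: OutcomeModelAdapter,
    table: CohortTable,
    rf: RiskFactorSpec | str,
    weights=None,
    prevalence: float | None = None,
) -> PafResult:
    """PAF by (weighted) standardisation: elimination sets every non-reference
    level of the risk factor to the reference value."""
    rf = table.risk_factor(rf) if isinstance(rf, str) else rf
    new_df = _counterfactual_frame(table, rf)
    est = impact_fraction_direct(model, table, new_df, weights, prevalence)
    return PafResult("PAF_prevalent", est, "direct",
                     meta={"risk_factor": rf.name, "refval": rf.refval,
                           "prevalence": prevalence})


def paf_bruzzi(
    model: OutcomeModelAdapter,
    table: CohortTable,
    rf: RiskFactorSpec | str,
    weights=None,
) -> PafResult:
    rf = table.risk_factor(rf) if isinstance(rf, str) else rf
    new_df = _counterfactual_frame(table, rf)
    est = impact_fraction_bruzzi(model, table, new_df, weights)
    return PafResult("PAF_prevalent", est, "bruzzi",
                     meta={"risk_factor": rf.name, "refval": rf.refval})


def paf_survival(
    model: OutcomeModelAdapter,
    table: CohortTable,
    rf: RiskFactorSpec | str,
    t_vector,
) -> PafResult:
    """PAF(t): compares model-implied cumulative incidence with and without
    the risk factor at each time in ``t_vector``."""
    rf = table.risk_factor(rf) if isinstance(rf, str) else rf
    new_df = _counterfactual_frame(table, rf)
    ts, est = impact_fraction_survival(model, table, new_df, t_vector)
    return PafResult("PAF_t", est, "survival", t_vector=ts,
                     meta={"risk_factor": rf.name, "refval": rf.refval})
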
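"""Pathway-specific PAF: disease burden attributable to one
risk factor -> mediator -> outcome pathway.

Continuous mediators use the rank-preserving counterfactual shift
``M - E(M|A,C) + E(M|A=0,C)`` (an unexposed subject keeps their observed
mediator value); discrete mediators use a mixture over mediator levels with
weights from the mediator model at ``A = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortTable, RiskFactorSpec, make_case_control_weights
from .model_adapters import OutcomeModelAdapter
from .paf_discrete import PafResult, _counterfactual_frame


@dataclass
class MediatorModelSet:
    """One fitted model per mediator (regressing the mediator on the risk
    factor and confounders, never on other mediators) plus the outcome model
    (outcome on risk factor, confounders and all mediators)."""

    mediator_models: list[OutcomeModelAdapter]
    outcome_model: OutcomeModelAdapter
    riskfactor: str

    @property
    def mediators(self) -> list[str]:
        return [m.outcome for m in self.mediator_models]

    def __post_init__(self):
        import re

        def mentions(formula: str, name: str) -> bool:
            return re.search(rf"\b{re.escape(name)}\b", formula) is not None

        for m in self.mediator_models:
            if not mentions(self.outcome_model.formula, m.outcome):
                raise ValueError(
                    f"mediator {m.outcome!r} missing from the outcome model formula"
                )
            if not mentions(m.formula, self.riskfactor):
                raise ValueError(
                    f"risk factor {self.riskfactor!r} missing from the model for "
                    f"mediator {m.outcome!r}"
                )
            rhs = m.formula.split("~", 1)[1]
            for other in self.mediator_models:
                if other is not m and mentions(rhs, other.outcome):
                    raise ValueError(
                        f"mediator model for {m.outcome!r} conditions on mediator "
                        f"{other.outcome!r}"
                    )


def _weights_for(table: CohortTable, prevalence, weights) -> np.ndarray:
    if prevalence is not None:
        return make_case_control_weights(table, prevalence)
    if weights is None:
        return np.ones(table.n)
    if isinstance(weights, str):
        return table.df[weights].to_numpy(dtype=float)
    return np.asarray(weights, dtype=float)


def ps_paf_pathway(
    model_set: MediatorModelSet,
    table: CohortTable,
    rf: RiskFactorSpec | str,
    k: int,
    weights=None,
    prevalence: float | None = None,
) -> PafResult:
    """PS-PAF for the k-th declared mediator (0-based)."""
    rf = table.risk_factor(rf) if isinstance(rf, str) else rf
    if not 0 <= k < len(model_set.mediator_models):
        raise ValueError(f"mediator index {k} out of range")
    w = _weights_for(table, prevalence, weights)
    y = table.y
    if np.isnan(y).any():
        raise ValueError("outcome has missing values")
    med_model = model_set.mediator_models[k]
    med_name = med_model.outcome
    cf = _counterfactual_frame(table, rf)  # A -> refval, all else observed

    if med_model.family == "linear":
        shift = med_model.predict(table.df) - med_model.predict(cf)
        new_df = table.df.copy()
        new_df[med_name] = new_df[med_name].to_numpy(dtype=float) - shift
        p_cf = model_set.outcome_model.predict(new_df)
    elif med_model.family in ("binomial_logit", "binomial_log", "ordinal_logit"):
        if med_model.family == "ordinal_logit":
            probs = med_model.predict(cf)  # frame: level -> prob, at A=0
            levels = list(probs.columns)
            probs = probs.to_numpy()
        else:
            p1 = np.asarray(med_model.predict(cf))
            probs = np.column_stack([1 - p1, p1])
            col = table.df[med_name]
            if isinstance(col.dtype, pd.CategoricalDtype):
                levels = list(col.cat.categories)
            else:
                levels = sorted(col.unique())
        p_cf = np.zeros(table.n)
        for j, lev in enumerate(levels):
            dfm = table.df.copy()
            if isinstance(dfm[med_name].dtype, pd.CategoricalDtype):
                dfm[med_name] = pd.Categorical([lev] * table.n,
                                               categories=dfm[med_name].cat.categories)
            else:
                dfm[med_name] = lev
            p_cf += probs[:, j] * np.asarray(model_set.outcome_model.predict(dfm))
    else:
        raise ValueError(f"unsupported mediator family {med_model.family!r}")

    denom = float(np.sum(w * y))
    if denom <= 0:
        raise ValueError("no weighted cases")
    est = float((np.sum(w * y) - np.sum(w * np.asarray(p_cf))) / denom)
    return PafResult("PS_PAF", est, "pathway",
                     meta={"mediator": med_name, "risk_factor": rf.name})


def ps_paf_direct(
    model_set: MediatorModelSet,
    table: CohortTable,
    rf: RiskFactorSpec | str,
    weights=None,
    prevalence: float | None = None,
) -> PafResult:
    """Direct PS-PAF: risk factor to reference, mediators held at observed
    values."""
    rf = table.risk_factor(rf) if isinstance(rf, str) else rf
    w = _weights_for(table, prevalence, weights)
    y = table.y
    cf = _counterfactual_frame(table, rf)
    p_cf = np.asarray(model_set.outcome_model.predict(cf))
    denom = float(np.sum(w * y))
    if denom <= 0:
        raise ValueError("no weighted cases")
    est = float((np.sum(w * y) - np.sum(w * p_cf)) / denom)
    return PafResult("PS_PAF", est, "direct", meta={"risk_factor": rf.name})


def ps_paf_all(
    model_set: MediatorModelSet,
    table: CohortTable,
    rf: RiskFactorSpec | str,
    prevalence: float | None = None,
    weights=None,
) -> pd.DataFrame:
    """One row per pathway (direct plus each mediator)."""
    rf = table.risk_factor(rf) if isinstance(rf, str) else rf
    rows = [("direct", float(ps_paf_direct(model_set, table, rf, weights, prevalence)))]
    for k, name in enumerate(model_set.mediators):
        rows.append(
            (name, float(ps_paf_pathway(model_set, table, rf, k, weights, prevalence)))
        )
    return pd.DataFrame(rows, columns=["pathway", "estimate"]).set_index("pathway")
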
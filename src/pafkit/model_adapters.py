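"""Uniform contract over fitted statistical models.

Every estimator in the package asks a fitted model the same question —
"what would you predict under a counterfactual risk-factor assignment?" —
through :class:`OutcomeModelAdapter`, without knowing the model family.

Families
--------
binomial_logit / binomial_log
    Weighted GLM (statsmodels); predictions are probabilities.
linear
    Weighted least squares; predictions are conditional means; response
    residuals are stored for deterministic counterfactual simulation.
ordinal_logit
    Weighted proportional-odds cumulative logit (own likelihood, since the
    statsmodels ordered model has no prior-weight support); predictions are
    per-category probabilities.
conditional_logit
    Matched-set conditional logistic regression (statsmodels); predictions on
    the relative-risk scale ``exp(x'beta)``.
prop_hazards
    Cox regression (lifelines, Efron ties); predictions are hazard ratios
    relative to the all-reference row; the Breslow baseline cumulative hazard
    is the default, with the Kalbfleisch-Prentice variant available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import patsy
import scipy.optimize
import statsmodels.api as sm
from scipy.special import expit, logit

from ._splines import ns
from .data_model import CohortTable

FAMILIES = (
    "binomial_logit",
    "binomial_log",
    "linear",
    "ordinal_logit",
    "conditional_logit",
    "prop_hazards",
)

_EVAL_ENV = patsy.EvalEnvironment([{"ns": ns}])


def _as_df(table) -> pd.DataFrame:
    return table.df if isinstance(table, CohortTable) else pd.DataFrame(table)


def _split_formula(formula: str) -> tuple[str, str]:
    lhs, sep, rhs = formula.partition("~")
    if not sep:
        raise ValueError(f"formula {formula!r} needs '~'")
    return lhs.strip(), rhs.strip()


class _WeightedOrdinalLogit:
    """Proportional-odds cumulative logit fitted by weighted maximum likelihood.

    ``P(Y <= k | x) = expit(alpha_k - x'beta)`` with increasing cutpoints.
    """

    def __init__(self, y_codes: np.ndarray, X: np.ndarray, w: np.ndarray, n_levels: int):
        self.y = y_codes
        self.X = X
        self.w = w
        self.K = n_levels

    def _unpack(self, theta):
        p = self.X.shape[1]
        beta = theta[:p]
        raw = theta[p:]
        alpha = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
        return beta, alpha

    def _cat_probs(self, beta, alpha, X):
        eta = X @ beta
        cum = expit(alpha[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def nll(self, theta):
        beta, alpha = self._unpack(theta)
        probs = self._cat_probs(beta, alpha, self.X)
        p_obs = probs[np.arange(len(self.y)), self.y]
        return -np.sum(self.w * np.log(np.clip(p_obs, 1e-300, None)))

    def grad(self, theta):
        p = self.X.shape[1]
        beta, alpha = self._unpack(theta)
        n = len(self.y)
        eta = self.X @ beta
        aug = np.concatenate([[-np.inf], alpha, [np.inf]])
        upper = aug[self.y + 1] - eta
        lower = aug[self.y] - eta
        Fu, Fl = expit(upper), expit(lower)
        fu = Fu * (1 - Fu)
        fl = Fl * (1 - Fl)
        p_obs = np.clip(Fu - Fl, 1e-300, None)
        wq = self.w / p_obs
        # d nll / d eta_i = + wq * (fu - fl)   (since dp/deta = -(fu - fl))
        g_beta = self.X.T @ (wq * (fu - fl))
        g_alpha = np.zeros(self.K - 1)
        has_upper = self.y < self.K - 1
        np.add.at(g_alpha, self.y[has_upper], -(wq * fu)[has_upper])
        has_lower = self.y > 0
        np.add.at(g_alpha, self.y[has_lower] - 1, (wq * fl)[has_lower])
        # chain rule to raw parameterisation
        raw = theta[p:]
        g_raw = np.zeros_like(raw)
        g_raw[0] = g_alpha.sum()
        for m in range(1, self.K - 1):
            g_raw[m] = np.exp(raw[m]) * g_alpha[m:].sum()
        return np.concatenate([g_beta, g_raw])

    def fit(self):
        p = self.X.shape[1]
        # standardise columns for the optimiser
        scale = self.X.std(axis=0)
        scale[scale == 0] = 1.0
        X_orig = self.X
        self.X = X_orig / scale
        # start from the weighted marginal cutpoints, zero slopes
        counts = np.bincount(self.y, weights=self.w, minlength=self.K)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        alpha0 = logit(np.clip(cum, 1e-6, 1 - 1e-6))
        raw0 = np.concatenate([[alpha0[0]], np.log(np.clip(np.diff(alpha0), 1e-6, None))])
        theta0 = np.concatenate([np.zeros(p), raw0])
        res = scipy.optimize.minimize(self.nll, theta0, jac=self.grad, method="BFGS",
                                      options={"maxiter": 2000, "gtol": 1e-7})
        if not np.isfinite(res.fun):
            raise RuntimeError("ordinal_logit fit failed to converge")
        self.beta, self.alpha = self._unpack(res.x)
        self.beta = self.beta / scale
        self.X = X_orig
        return self

    def predict_probs(self, X: np.ndarray) -> np.ndarray:
        return self._cat_probs(self.beta, self.alpha, X)


@dataclass
class SurvivalAdapterExtras:
    """Baseline cumulative hazard step function and event-time grid.

    The stored curve is referenced to the conventional all-reference row
    (factors at first level, plain numerics at 0, splined variables at their
    observed minimum) while hazard-ratio predictions are centred at the
    training mean — the pairing the R survival ecosystem produces, kept here
    so cumulative-incidence results agree with it.
    """

    event_times: np.ndarray
    cumhaz: np.ndarray  # aligned with event_times, nondecreasing
    lp_center: float = 0.0  # training-mean linear predictor

    def baseline_cumhaz(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, None)], 0.0)
        return out

    def nearest_event_time(self, t: float) -> tuple[float, float]:
        """(event time closest to ``t``, cumulative hazard there)."""
        i = int(np.argmin((self.event_times - t) ** 2))
        return float(self.event_times[i]), float(self.cumhaz[i])


@dataclass
class OutcomeModelAdapter:
    family: str
    formula: str
    outcome: str
    design_info: object
    params: np.ndarray
    offset_delta: float = 0.0
    weights_used: np.ndarray | None = None
    levels: list | None = None  # ordinal families: category levels in order
    residuals: np.ndarray | None = None  # linear family: response residuals
    extras: SurvivalAdapterExtras | None = None
    strata_col: str | None = None
    _fit: object = field(default=None, repr=False)
    _ordinal: _WeightedOrdinalLogit | None = field(default=None, repr=False)
    _stratum_centers: dict | None = field(default=None, repr=False)

    # -- design ------------------------------------------------------------
    def design_matrix(self, data) -> np.ndarray:
        df = _as_df(data)
        (X,) = patsy.build_design_matrices([self.design_info], df)
        return np.asarray(X)

    def _lp_matrix(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params

    def linear_predictor(self, data) -> np.ndarray:
        X = self.design_matrix(data)
        if self.family == "conditional_logit":
            # stratum effects profiled out: subtract the training-stratum mean
            # of the fitted linear predictor (matched-set contrasts survive)
            lp = self._lp_matrix(X)
            if self._stratum_centers is not None:
                df = _as_df(data)
                if self.strata_col in df.columns:
                    centres = (
                        df[self.strata_col].map(self._stratum_centers)
                        .fillna(0.0).to_numpy(dtype=float)
                    )
                    lp = lp - centres
            return lp
        if self.family in ("prop_hazards", "ordinal_logit"):
            return self._lp_matrix(X)
        return self._lp_matrix(X) + self.offset_delta

    # -- predictions -------------------------------------------------------
    def predict(self, data):
        """Response-scale prediction: probabilities (binomial), means
        (linear), per-category probability frame (ordinal), relative risk
        ``exp(lp)`` (conditional_logit / prop_hazards)."""
        df = _as_df(data)
        lp = self.linear_predictor(df)
        if self.family == "binomial_logit":
            return expit(lp)
        if self.family == "binomial_log":
            return np.clip(np.exp(lp), 0.0, 1.0)
        if self.family == "linear":
            return lp
        if self.family == "prop_hazards":
            centre = self.extras.lp_center if self.extras is not None else 0.0
            return np.exp(lp - centre)
        if self.family == "conditional_logit":
            return np.exp(lp)
        if self.family == "ordinal_logit":
            X = self.design_matrix(df)
            probs = self._ordinal.predict_probs(X)
            return pd.DataFrame(probs, columns=self.levels, index=df.index)
        raise AssertionError(self.family)

    def predict_counterfactual(self, data, assignments: Mapping | None = None):
        """Predict on a copy of ``data`` with columns overwritten.

        For ``prop_hazards`` the returned values are hazard ratios under the
        assignment.  The original table is untouched.
        """
        df = _as_df(data)
        if assignments:
            df = df.copy()
            for col, val in assignments.items():
                if isinstance(df[col].dtype, pd.CategoricalDtype):
                    cats = df[col].cat.categories
                    vals = pd.Series(val, index=df.index) if np.isscalar(val) else pd.Series(np.asarray(val), index=df.index)
                    bad = ~vals.isin(cats)
                    if bad.any():
                        raise ValueError(
                            f"assignment value(s) {sorted(vals[bad].unique())} not levels of {col!r}"
                        )
                    df[col] = pd.Categorical(vals, categories=cats)
                else:
                    df[col] = val
        return self.predict(df)


def fit_model(
    table,
    formula: str,
    family: str,
    weights: np.ndarray | str | None = None,
) -> OutcomeModelAdapter:
    """Fit a model and wrap it in an :class:`OutcomeModelAdapter`.

    ``weights`` may be a per-row array or the name of a column.  For
    ``conditional_logit`` the table must declare matched strata; for
    ``prop_hazards`` it must declare time and event columns (the formula LHS
    is then only a label).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    df = _as_df(table)
    outcome, rhs = _split_formula(formula)

    if isinstance(weights, str):
        w = df[weights].to_numpy(dtype=float)
    elif weights is not None:
        w = np.asarray(weights, dtype=float)
    else:
        w = np.ones(len(df))

    X_dm = patsy.dmatrix(rhs, df, eval_env=_EVAL_ENV, return_type="matrix")
    design_info = X_dm.design_info
    X = np.asarray(X_dm)
    if len(X) != len(df):
        raise ValueError("missing values in model columns; run data_clean first")

    adapter = OutcomeModelAdapter(
        family=family,
        formula=formula,
        outcome=outcome,
        design_info=design_info,
        params=np.zeros(X.shape[1]),
        weights_used=w,
    )

    try:
        if family in ("binomial_logit", "binomial_log"):
            y = df[outcome].to_numpy(dtype=float)
            link = sm.families.links.Logit() if family == "binomial_logit" else sm.families.links.Log()
            fit = sm.GLM(y, X, family=sm.families.Binomial(link=link), var_weights=w).fit(maxiter=200)
            adapter.params = np.asarray(fit.params)
            adapter._fit = fit
        elif family == "linear":
            y = df[outcome].to_numpy(dtype=float)
            fit = sm.WLS(y, X, weights=w).fit()
            adapter.params = np.asarray(fit.params)
            adapter.residuals = y - X @ adapter.params
            adapter._fit = fit
        elif family == "ordinal_logit":
            col = df[outcome]
            if isinstance(col.dtype, pd.CategoricalDtype):
                levels = list(col.cat.categories)
                codes = col.cat.codes.to_numpy()
            else:
                levels = sorted(col.unique())
                codes = col.map({v: i for i, v in enumerate(levels)}).to_numpy()
            has_icept = "Intercept" in design_info.column_names
            keep = [i for i, nm in enumerate(design_info.column_names) if nm != "Intercept"]
            Xo = X[:, keep]
            om = _WeightedOrdinalLogit(codes, Xo, w, len(levels)).fit()
            params = np.zeros(X.shape[1])
            params[keep] = om.beta
            adapter.params = params
            adapter.levels = levels
            adapter._ordinal = _OrdinalView(om, keep, X.shape[1])
        elif family == "conditional_logit":
            strata_col = table.strata if isinstance(table, CohortTable) else None
            if strata_col is None:
                raise ValueError("conditional_logit requires a table with declared strata")
            y = df[outcome].to_numpy(dtype=float)
            keep = [i for i, nm in enumerate(design_info.column_names) if nm != "Intercept"]
            from statsmodels.discrete.conditional_models import ConditionalLogit

            groups = df[strata_col].to_numpy()
            Xc = X[:, keep]
            # columns constant within every matched set carry no conditional
            # information (flat likelihood): drop them, coefficient 0
            demeaned = Xc - pd.DataFrame(Xc).groupby(groups).transform("mean").to_numpy()
            spread = np.abs(demeaned).max(axis=0)
            informative = spread > 1e-9 * (1.0 + np.abs(Xc).max(axis=0))
            keep = [k for k, ok in zip(keep, informative) if ok]
            Xc = Xc[:, informative]
            # standardise columns for the optimiser, then undo the scaling
            scale = Xc.std(axis=0)
            scale[scale == 0] = 1.0
            model_cl = ConditionalLogit(y, Xc / scale, groups=groups)
            try:
                fit = model_cl.fit(disp=False)
                beta = np.asarray(fit.params)
            except (ValueError, np.linalg.LinAlgError):
                res = scipy.optimize.minimize(
                    lambda p: -model_cl.loglike(p),
                    np.zeros(Xc.shape[1]),
                    jac=lambda p: -model_cl.score(p),
                    method="BFGS", options={"maxiter": 500, "gtol": 1e-6},
                )
                fit = None
                beta = res.x
            params = np.zeros(X.shape[1])
            params[keep] = beta / scale
            adapter.params = params
            adapter._fit = fit
            adapter.strata_col = strata_col
            lp_train = X @ params
            adapter._stratum_centers = (
                pd.Series(lp_train).groupby(pd.Series(groups)).mean().to_dict()
            )
        elif family == "prop_hazards":
            time_col = table.time if isinstance(table, CohortTable) else None
            event_col = table.event if isinstance(table, CohortTable) else None
            if time_col is None or event_col is None:
                raise ValueError("prop_hazards requires a table with time and event columns")
            keep = [i for i, nm in enumerate(design_info.column_names) if nm != "Intercept"]
            from lifelines import CoxPHFitter

            cox_df = pd.DataFrame(X[:, keep], columns=[f"x{i}" for i in range(len(keep))])
            cox_df["__t"] = df[time_col].to_numpy(dtype=float)
            cox_df["__e"] = df[event_col].to_numpy(dtype=float)
            if not np.allclose(w, 1.0):
                cox_df["__w"] = w
                cph = CoxPHFitter().fit(cox_df, "__t", "__e", weights_col="__w", robust=False)
            else:
                cph = CoxPHFitter().fit(cox_df, "__t", "__e")
            params = np.zeros(X.shape[1])
            params[keep] = cph.params_.to_numpy()
            adapter.params = params
            adapter._fit = cph
            lp_train = X[:, keep] @ cph.params_.to_numpy()
            extras = _baseline_cumhaz(
                cox_df["__t"].to_numpy(), cox_df["__e"].to_numpy(), lp_train, w
            )
            # re-reference the baseline to the conventional all-reference row
            ref_row = _reference_row(df, rhs)
            (X_ref,) = patsy.build_design_matrices([design_info], ref_row)
            lp_ref = float(np.asarray(X_ref)[0, keep] @ cph.params_.to_numpy())
            extras.cumhaz = extras.cumhaz * np.exp(lp_ref)
            # hazard-ratio reference: continuous columns at training means,
            # binary columns (factor dummies and 0/1 numerics) at 0
            Xk = X[:, keep]
            col_means = Xk.mean(axis=0)
            is_binary = np.array([set(np.unique(Xk[:, j])) <= {0.0, 1.0}
                                  for j in range(Xk.shape[1])])
            col_means[is_binary] = 0.0
            extras.lp_center = float(col_means @ cph.params_.to_numpy())
            adapter.extras = extras
    except (np.linalg.LinAlgError, ValueError, RuntimeError) as err:
        if isinstance(err, ValueError) and "requires" in str(err):
            raise
        raise RuntimeError(
            f"model fit failed (family={family!r}, formula={formula!r}): {err}"
        ) from err

    return adapter


def _reference_row(df: pd.DataFrame, rhs: str) -> pd.DataFrame:
    """One-row frame at the reference configuration: categoricals at their
    first level, plain numerics at 0, spline-wrapped numerics at the observed
    minimum (where a natural-spline basis is identically zero)."""
    import re

    splined = set(re.findall(r"ns\(\s*([A-Za-z_][A-Za-z0-9_.]*)", rhs))
    row = df.iloc[[0]].copy()
    for col in df.columns:
        if not re.search(rf"\b{re.escape(col)}\b", rhs):
            continue
        if isinstance(df[col].dtype, pd.CategoricalDtype):
            row[col] = pd.Categorical([df[col].cat.categories[0]],
                                      categories=df[col].cat.categories)
        elif df[col].dtype == object:
            row[col] = sorted(df[col].dropna().unique())[0]
        elif col in splined:
            row[col] = float(df[col].min())
        else:
            row[col] = 0.0
    return row


class _OrdinalView:
    """Maps the full design matrix (incl. intercept column) onto the
    intercept-free ordinal fit."""

    def __init__(self, om: _WeightedOrdinalLogit, keep: list[int], ncol: int):
        self.om = om
        self.keep = keep
        self.ncol = ncol

    def predict_probs(self, X: np.ndarray) -> np.ndarray:
        return self.om.predict_probs(X[:, self.keep])


def _baseline_cumhaz(t, e, lp, w, method: str = "breslow") -> SurvivalAdapterExtras:
    """Baseline cumulative hazard on the raw (uncentered) linear predictor.

    Breslow: increments ``d_k / sum_{risk set} w r``.  The
    Kalbfleisch-Prentice variant uses the untied closed form
    ``-log((1 - r_i / S_i) ** (1 / r_i))`` and falls back to Breslow at tied
    event times.
    """
    t = np.asarray(t, float)
    e = np.asarray(e, float)
    r = w * np.exp(lp)
    order = np.argsort(t, kind="mergesort")
    t_s, e_s, r_s = t[order], e[order], r[order]
    # cumulative risk-set total from the right
    rev_cum = np.cumsum(r_s[::-1])[::-1]
    event_times = []
    increments = []
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e_s[k] == 1]
        if d_idx:
            S = rev_cum[i]
            if method == "breslow" or len(d_idx) > 1:
                inc = len(d_idx) / S
            else:
                rk = r_s[d_idx[0]]
                inc = -np.log(max(1.0 - rk / S, 1e-300)) / rk
            event_times.append(t_s[i])
            increments.append(inc)
        i = j
    event_times = np.asarray(event_times)
    cumhaz = np.cumsum(np.asarray(increments))
    return SurvivalAdapterExtras(event_times=event_times, cumhaz=cumhaz)


def recalibrate_to_prevalence(
    model: OutcomeModelAdapter,
    table,
    weights: np.ndarray | None,
    prevalence: float,
) -> float:
    """Solve for the linear-predictor offset that makes the weighted mean
    predicted probability equal ``prevalence``; stores and returns it.

    Monotone in the offset, so the root is unique.
    """
    if model.family not in ("binomial_logit", "binomial_log", "conditional_logit"):
        raise ValueError("prevalence recalibration requires a binomial family")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    df = _as_df(table)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    X = model.design_matrix(df)
    lp = X @ model.params

    if model.family in ("binomial_logit", "conditional_logit"):
        def gap(c):
            return np.average(expit(lp + c), weights=w) - prevalence
    else:
        def gap(c):
            return np.average(np.exp(np.clip(lp + c, None, 0.0)), weights=w) - prevalence

    lo, hi = -100.0, 100.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("prevalence outside the achievable range of the model")
    offset = scipy.optimize.brentq(gap, lo, hi, xtol=1e-12)
    model.offset_delta = float(offset)
    return model.offset_delta


def predict_counterfactual(model: OutcomeModelAdapter, table, assignments=None):
    """Module-level convenience mirroring the adapter method."""
    return model.predict_counterfactual(table, assignments)
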
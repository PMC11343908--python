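"""Summary-data PAF: Levin and Miettinen formulas, Monte-Carlo interval
propagation, the first-order "approximate PAF", and the fan-plot / nomogram
data layers.

A note on the Miettinen denominator: the probabilistically consistent form
``1 - P + P * RR_u`` (equivalently ``1 + P (RR_u - 1)``) is used for the case
prevalence ``P(A=1|Y=1) = P RR_u / (1 - P + P RR_u)``; it reduces to 1 when
P = 1, which the often-printed ``1 + P RR_u`` does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .paf_discrete import PafResult


def _as_vec(x):
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class SummaryInputs:
    """Prevalence and relative-risk summaries for one (possibly multi-level)
    risk factor.  Interval inputs are (lower, upper) pairs, one per level."""

    prev: np.ndarray
    rr_adjusted: np.ndarray | None = None
    rr_unadjusted: np.ndarray | None = None
    conf_prev: np.ndarray | None = None
    conf_rr: np.ndarray | None = None
    conf_rru: np.ndarray | None = None
    ci_level: float = 0.95

    def __post_init__(self):
        self.prev = _as_vec(self.prev)
        if not ((self.prev > 0) & (self.prev < 1)).all() or self.prev.sum() >= 1:
            raise ValueError("prevalences must lie in (0,1) and sum to < 1")
        for name in ("rr_adjusted", "rr_unadjusted"):
            v = getattr(self, name)
            if v is not None:
                v = _as_vec(v)
                if (v <= 0).any():
                    raise ValueError(f"{name} must be positive")
                setattr(self, name, v)
        for name in ("conf_prev", "conf_rr", "conf_rru"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape[1] != 2 or (v[:, 0] > v[:, 1]).any():
                    raise ValueError(f"{name} must be (lower, upper) pairs")
                setattr(self, name, v)

    @classmethod
    def from_intervals(cls, conf_prev, conf_rr=None, conf_rru=None, ci_level=0.95):
        """Point estimates taken as interval midpoints: logit-scale midpoint
        for prevalence, geometric midpoint for relative risks."""
        conf_prev = np.atleast_2d(np.asarray(conf_prev, dtype=float))
        prev = expit(logit(conf_prev).mean(axis=1))
        rr = rru = None
        if conf_rr is not None:
            conf_rr = np.atleast_2d(np.asarray(conf_rr, dtype=float))
            rr = np.exp(np.log(conf_rr).mean(axis=1))
        if conf_rru is not None:
            conf_rru = np.atleast_2d(np.asarray(conf_rru, dtype=float))
            rru = np.exp(np.log(conf_rru).mean(axis=1))
        return cls(prev=prev, rr_adjusted=rr, rr_unadjusted=rru,
                   conf_prev=conf_prev, conf_rr=conf_rr, conf_rru=conf_rru,
                   ci_level=ci_level)


def _levin(prev, rr):
    excess = float(np.sum(prev * (rr - 1.0)))
    denom = 1.0 + excess
    if denom <= 0:
        raise ValueError("Levin denominator <= 0")
    return excess / denom


def _miettinen(prev, rr_e, rr_u):
    denom = 1.0 + float(np.sum(prev * (rr_u - 1.0)))
    if denom <= 0:
        raise ValueError("Miettinen denominator <= 0")
    case_prev = prev * rr_u / denom
    return float(np.sum(case_prev * (rr_e - 1.0) / rr_e))


def paf_levin(inputs: SummaryInputs) -> PafResult:
    """``sum_l P_l (RR_l - 1) / (1 + sum_l P_l (RR_l - 1))``."""
    if inputs.rr_adjusted is None:
        raise ValueError("Levin formula needs rr_adjusted")
    est = _levin(inputs.prev, inputs.rr_adjusted)
    ci = None
    if inputs.conf_prev is not None and inputs.conf_rr is not None:
        ci = propagate_ci(inputs, formula="levin")
    return PafResult("PAF_prevalent", est, "levin", ci=ci)


def paf_miettinen(inputs: SummaryInputs) -> PafResult:
    """Case prevalence from the unadjusted RR, attributable share from the
    adjusted RR (proxy for the causal RR in the exposed)."""
    if inputs.rr_adjusted is None or inputs.rr_unadjusted is None:
        raise ValueError("Miettinen formula needs rr_adjusted and rr_unadjusted")
    est = _miettinen(inputs.prev, inputs.rr_adjusted, inputs.rr_unadjusted)
    ci = None
    if (inputs.conf_prev is not None and inputs.conf_rr is not None
            and inputs.conf_rru is not None):
        ci = propagate_ci(inputs, formula="miettinen")
    return PafResult("PAF_prevalent", est, "miettinen", ci=ci)


def propagate_ci(
    inputs: SummaryInputs,
    formula: str = "levin",
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo imprecision propagation.

    Prevalences are drawn as independent normals on the logit scale and RRs
    on the log scale, each with SD = half-width / z, then the PAF formula is
    recomputed per draw and empirical quantiles returned.
    """
    rng = np.random.default_rng(seed)
    z = norm.ppf(1 - (1 - inputs.ci_level) / 2)

    def draws_logit(conf, point):
        mid = logit(point)
        sd = (logit(conf[:, 1]) - logit(conf[:, 0])) / (2 * z)
        if not np.isfinite(mid).all() or not np.isfinite(sd).all():
            raise ValueError("non-finite transformed interval bounds")
        return expit(rng.normal(mid, sd, size=(n_draws, len(point))))

    def draws_log(conf, point):
        mid = np.log(point)
        sd = (np.log(conf[:, 1]) - np.log(conf[:, 0])) / (2 * z)
        if not np.isfinite(mid).all() or not np.isfinite(sd).all():
            raise ValueError("non-finite transformed interval bounds")
        return np.exp(rng.normal(mid, sd, size=(n_draws, len(point))))

    if inputs.conf_prev is None or inputs.conf_rr is None:
        raise ValueError("interval propagation needs conf_prev and conf_rr")
    P = draws_logit(inputs.conf_prev, inputs.prev)
    RR = draws_log(inputs.conf_rr, inputs.rr_adjusted)
    if formula == "levin":
        excess = np.sum(P * (RR - 1.0), axis=1)
        vals = excess / (1.0 + excess)
    elif formula == "miettinen":
        if inputs.conf_rru is None:
            raise ValueError("Miettinen propagation needs conf_rru")
        RRu = draws_log(inputs.conf_rru, inputs.rr_unadjusted)
        denom = 1.0 + np.sum(P * (RRu - 1.0), axis=1)
        case_prev = P * RRu / denom[:, None]
        vals = np.sum(case_prev * (RR - 1.0) / RR, axis=1)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    alpha = 1 - inputs.ci_level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# approximate PAF, fan plots and nomograms


@dataclass
class RfSummary:
    """Per-risk-factor prevalence-in-controls and log-odds-ratio summary used
    by the plotting layers."""

    rf_names: list[str]
    rf_prev: np.ndarray
    risk: np.ndarray
    log_scale: bool = True
    rf_prev_new: np.ndarray | None = None

    def __post_init__(self):
        self.rf_prev = _as_vec(self.rf_prev)
        self.risk = _as_vec(self.risk)
        if len(self.rf_names) != len(self.rf_prev) or len(self.rf_names) != len(self.risk):
            raise ValueError("rf_names, rf_prev and risk must align")
        if not ((self.rf_prev > 0) & (self.rf_prev < 1)).all():
            raise ValueError("prevalences must lie in (0,1)")
        if not self.log_scale:
            if (self.risk <= 0).any():
                raise ValueError("odds ratios must be positive")
            self.risk = np.log(self.risk)
            self.log_scale = True
        if self.rf_prev_new is not None:
            self.rf_prev_new = _as_vec(self.rf_prev_new)

    @property
    def approx_paf(self) -> np.ndarray:
        """First-order approximation ``log(OR) * prevalence_in_controls``."""
        return self.risk * self.rf_prev


def approximate_paf(rf_summary: RfSummary) -> np.ndarray:
    return rf_summary.approx_paf


def fan_plot(rf_summary: RfSummary, ax=None):
    """Scatter of (prevalence, log OR) with rays of constant approximate PAF.

    Returns ``(fig, coords)`` where ``coords`` carries the plotted points and
    ray slopes so the geometry is testable without rendering.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(rf_summary.rf_names) == 0:
        raise ValueError("empty risk factor summary")
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 6))
    else:
        fig = ax.figure
    x = rf_summary.rf_prev
    y = rf_summary.risk
    apaf = rf_summary.approx_paf
    # ray through (x_i, y_i) anchored so its y-intercept equals the approx PAF:
    # y = a_i + slope_i * x with slope_i = (y_i - a_i)/x_i and a_i = apaf_i
    slopes = (y - apaf) / x
    coords = {
        "prevalence": x.copy(),
        "log_or": y.copy(),
        "approx_paf": apaf.copy(),
        "ray_intercepts": apaf.copy(),
        "ray_slopes": slopes,
    }
    ax.scatter(x, y)
    for xi, yi, ai, name in zip(x, y, apaf, rf_summary.rf_names):
        ax.plot([0, xi], [ai, yi], lw=0.8, alpha=0.6)
        ax.annotate(name, (xi, yi), fontsize=8)
    ax.set_xlabel("risk factor prevalence (controls)")
    ax.set_ylabel("log odds ratio")
    ax.set_xlim(left=0)
    return fig, coords


def nomogram(rf_summary: RfSummary, type: str = "rn"):
    """Three-axis nomogram: each factor is a polyline across the axes.

    ``type="rn"`` draws prevalence / OR / approximate PAF;
    ``type="n"`` puts the OR on the left axis.  When a post-intervention
    prevalence exists, a second (rotated) line is drawn for that factor.
    Returns ``(fig, coords)``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if type not in ("rn", "n"):
        raise ValueError("type must be 'rn' or 'n'")
    if len(rf_summary.rf_names) == 0:
        raise ValueError("empty risk factor summary")
    fig, ax = plt.subplots(figsize=(7, 6))
    apaf = rf_summary.approx_paf
    if type == "rn":
        axis_vals = [rf_summary.rf_prev, rf_summary.risk, apaf]
        labels = ["prevalence", "log OR", "approx PAF"]
    else:
        axis_vals = [rf_summary.risk, rf_summary.rf_prev, apaf]
        labels = ["log OR", "prevalence", "approx PAF"]
    xpos = [0.0, 0.5, 1.0]
    lines = {}
    for i, name in enumerate(rf_summary.rf_names):
        ys = [v[i] for v in axis_vals]
        lines[name] = list(zip(xpos, ys))
        ax.plot(xpos, ys, marker="o", lw=1)
        ax.annotate(name, (xpos[-1], ys[-1]), fontsize=8)
    rotated = {}
    if rf_summary.rf_prev_new is not None:
        new_apaf = rf_summary.risk * rf_summary.rf_prev_new
        for i, name in enumerate(rf_summary.rf_names):
            if np.isnan(rf_summary.rf_prev_new[i]):
                continue
            if type == "rn":
                ys = [rf_summary.rf_prev_new[i], rf_summary.risk[i], new_apaf[i]]
            else:
                ys = [rf_summary.risk[i], rf_summary.rf_prev_new[i], new_apaf[i]]
            rotated[name] = list(zip(xpos, ys))
            ax.plot(xpos, ys, marker="o", lw=1, ls="--")
    for xp, lab in zip(xpos, labels):
        ax.axvline(xp, color="0.8", lw=0.5)
        ax.text(xp, 1.02, lab, transform=ax.get_xaxis_transform(), ha="center")
    ax.set_xticks([])
    coords = {"lines": lines, "rotated": rotated, "axis_labels": labels,
              "approx_paf": apaf.copy()}
    return fig, coords
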
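"""PAF_q for continuous exposures.

The target of inference is the impact fraction of an intervention that moves
everyone outside the lowest-risk 100q% of exposure values onto the nearest
point of that region.  The exposure-risk curve is the partial effect of the
exposure (all other model terms held fixed), referenced to the observed
median, which is valid because models here are additive in the exposure term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortTable, DesignContext
from .model_adapters import OutcomeModelAdapter
from .paf_discrete import (
    PafResult,
    impact_fraction_bruzzi,
    impact_fraction_direct,
    impact_fraction_survival,
)


@dataclass
class RiskCurve:
    exposure: str
    grid: np.ndarray
    rel_risk: np.ndarray  # normalised so r(observed median) = 1

    def at(self, x) -> np.ndarray:
        """Relative risk interpolated at arbitrary exposure values."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.rel_risk)

    @property
    def x_min_risk(self) -> float:
        return float(self.grid[int(np.argmin(self.rel_risk))])


@dataclass
class RiskQuantileRegion:
    exposure: str
    q: float
    interval: tuple[float, float]
    risk_curve: RiskCurve
    threshold: float

    @property
    def x_min_risk(self) -> float:
        return self.risk_curve.x_min_risk

    def projection(self, x) -> np.ndarray:
        """Nearest point of the closed interval; ties toward the lower end."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.interval
        return np.clip(x, lo, hi)

    def contains(self, x) -> np.ndarray:
        lo, hi = self.interval
        x = np.asarray(x, dtype=float)
        return (x >= lo) & (x <= hi)


def estimate_risk_curve(
    model: OutcomeModelAdapter,
    table: CohortTable,
    exposure: str,
    grid_size: int = 1000,
    bounds: tuple[float, float] | None = None,
) -> RiskCurve:
    """Relative-risk curve over an equally spaced grid spanning the observed
    exposure range (or user bounds), from the exposure's partial linear
    predictor with the observed median as reference."""
    x = table.df[exposure].to_numpy(dtype=float)
    if exposure not in model.formula:
        raise ValueError(f"exposure {exposure!r} does not appear in the model formula")
    lo, hi = bounds if bounds is not None else (np.nanmin(x), np.nanmax(x))
    grid = np.linspace(lo, hi, grid_size)
    template = table.df.iloc[[0]].copy()
    rep = pd.concat([template] * grid_size, ignore_index=True)
    rep[exposure] = grid
    lp_grid = model.linear_predictor(rep)
    med = float(np.nanmedian(x))
    ref = template.copy()
    ref[exposure] = med
    lp_ref = model.linear_predictor(ref)[0]
    return RiskCurve(exposure=exposure, grid=grid, rel_risk=np.exp(lp_grid - lp_ref))


def _weighted_quantile(values: np.ndarray, q: float, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return float(v[np.searchsorted(cw, q, side="left").clip(0, len(v) - 1)])


def build_region(
    risk_curve: RiskCurve,
    table: CohortTable,
    q: float,
    weights: np.ndarray | None = None,
) -> RiskQuantileRegion:
    """Lowest-risk exposure interval carrying 100q% of the (weighted)
    population risk distribution.

    Threshold = q-quantile of the per-subject relative risks; the region is
    the maximal contiguous grid run containing the risk minimiser on which the
    curve stays below the threshold.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    x_obs = table.df[risk_curve.exposure].to_numpy(dtype=float)
    r_obs = risk_curve.at(x_obs)
    w = np.ones(len(x_obs)) if weights is None else np.asarray(weights, dtype=float)
    tau = _weighted_quantile(r_obs, q, w)
    below = risk_curve.rel_risk <= tau
    i_min = int(np.argmin(risk_curve.rel_risk))
    below[i_min] = True  # the minimiser always qualifies
    lo_i = i_min
    while lo_i > 0 and below[lo_i - 1]:
        lo_i -= 1
    hi_i = i_min
    while hi_i < len(below) - 1 and below[hi_i + 1]:
        hi_i += 1
    interval = (float(risk_curve.grid[lo_i]), float(risk_curve.grid[hi_i]))
    return RiskQuantileRegion(exposure=risk_curve.exposure, q=q,
                              interval=interval, risk_curve=risk_curve,
                              threshold=float(tau))


def paf_q(
    model: OutcomeModelAdapter,
    table: CohortTable,
    riskfactor_vec: list[str],
    q_vec,
    design: DesignContext | None = None,
    t: float | None = None,
    weights=None,
    grid_size: int = 1000,
) -> pd.DataFrame:
    """PAF_q over a grid of exposures and quantiles.

    Returns a frame with one row per risk factor and one column per q.  The
    estimation route follows the design: direct standardisation
    (cross-sectional / survey), the case-only ratio formula (case-control), or
    the survival formula at a single time ``t`` (cohort with a
    proportional-hazards model).
    """
    design = design or DesignContext()
    q_vec = np.atleast_1d(np.asarray(q_vec, dtype=float))
    if ((q_vec <= 0) | (q_vec > 1)).any():
        raise ValueError("q values must lie in (0, 1]")
    if model.family == "prop_hazards":
        t_arr = np.atleast_1d(np.asarray(t, dtype=float)) if t is not None else None
        if t_arr is None or len(t_arr) != 1:
            raise ValueError("survival PAF_q can only be evaluated at a single time")
    if isinstance(weights, str):
        weights = table.df[weights].to_numpy(dtype=float)
    rows = {}
    for exposure in riskfactor_vec:
        curve = estimate_risk_curve(model, table, exposure, grid_size=grid_size)
        x_obs = table.df[exposure].to_numpy(dtype=float)
        vals = []
        for q in q_vec:
            region = build_region(curve, table, float(q), weights=weights)
            new_df = table.df.copy()
            new_df[exposure] = region.projection(x_obs)
            if model.family == "prop_hazards":
                _, est = impact_fraction_survival(model, table, new_df, [float(t)])
                vals.append(float(est[0]))
            elif design.calculation_method == "bruzzi":
                vals.append(impact_fraction_bruzzi(model, table, new_df, weights))
            else:
                vals.append(
                    impact_fraction_direct(model, table, new_df, weights,
                                           design.prevalence)
                )
        rows[exposure] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=[f"q={q:g}" for q in q_vec])
    out.index.name = "riskfactor"
    return out


def paf_q_results(df: pd.DataFrame, design: DesignContext | None = None) -> list[PafResult]:
    """Flatten a :func:`paf_q` frame into PafResult records."""
    design = design or DesignContext()
    out = []
    for rf, row in df.iterrows():
        for col, val in row.items():
            out.append(PafResult("PAF_q", float(val), design.calculation_method,
                                 meta={"risk_factor": rf, "q": float(col.split("=")[1])}))
    return out


def plot_continuous(
    model: OutcomeModelAdapter,
    table: CohortTable,
    exposure: str,
    q_list=(0.1, 0.2, 0.3),
    grid_size: int = 1000,
    weights=None,
):
    """Risk curve with exposure-density overlay and shaded lowest-risk
    regions for each q.  Returns ``(fig, coords)`` with plotted coordinates
    exposed for testing."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    curve = estimate_risk_curve(model, table, exposure, grid_size=grid_size)
    if isinstance(weights, str):
        weights = table.df[weights].to_numpy(dtype=float)
    regions = {q: build_region(curve, table, q, weights=weights) for q in q_list}
    x_obs = table.df[exposure].dropna().to_numpy(dtype=float)
    kde = gaussian_kde(x_obs)
    dens = kde(curve.grid)

    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 7), sharex=True,
                                   height_ratios=[3, 1])
    ax0.plot(curve.grid, curve.rel_risk, color="k")
    ax0.set_ylabel("relative risk (median ref.)")
    for i, (q, reg) in enumerate(sorted(regions.items(), reverse=True)):
        ax0.axvspan(*reg.interval, alpha=0.15 + 0.1 * i, color="tab:blue",
                    label=f"q={q:g}")
    ax0.legend()
    ax1.plot(curve.grid, dens, color="tab:gray")
    ax1.fill_between(curve.grid, dens, alpha=0.3, color="tab:gray")
    ax1.set_xlabel(exposure)
    ax1.set_ylabel("density")
    coords = {
        "grid": curve.grid,
        "rel_risk": curve.rel_risk,
        "density": dens,
        "regions": {q: reg.interval for q, reg in regions.items()},
    }
    return fig, coords
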
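"""Bootstrap confidence intervals for every estimator.

The statistic is a callable evaluated on a resampled table and is expected to
refit its models internally; any weight column travels with the resampled
rows.  Matched case-control tables resample whole matched sets so the
case/control balance survives resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import CohortTable


@dataclass
class BootstrapConfig:
    boot_rep: int = 50
    ci_type: str = "norm"  # norm | basic | perc | bca
    ci_level: float = 0.95
    resample_unit: str = "row"  # row | stratum
    seed: int | None = None
    verbose: bool = True

    def __post_init__(self):
        if self.boot_rep < 2:
            raise ValueError("boot_rep must be >= 2")
        if self.ci_type not in ("norm", "basic", "perc", "bca"):
            raise ValueError(f"unknown ci_type {self.ci_type!r}")
        if self.resample_unit not in ("row", "stratum"):
            raise ValueError(f"unknown resample_unit {self.resample_unit!r}")


@dataclass
class BootstrapResult:
    point: np.ndarray
    bias: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ci_type: str
    ci_level: float
    boot_rep: int
    replicates: np.ndarray = field(repr=False, default=None)

    @property
    def debiased(self) -> np.ndarray:
        return self.point - self.bias

    def interval(self, i: int = 0) -> tuple[float, float]:
        return float(self.lower[i]), float(self.upper[i])


def _resample_table(table: CohortTable, rng: np.random.Generator, unit: str) -> CohortTable:
    df = table.df
    if unit == "stratum":
        if table.strata is None:
            raise ValueError("stratum resampling needs declared strata")
        codes, uniques = pd.factorize(df[table.strata])
        groups = [np.flatnonzero(codes == g) for g in range(len(uniques))]
        take = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([groups[t] for t in take])
        new = df.iloc[idx].copy()
        # relabel so resampled copies of a stratum stay distinct
        sizes = [len(groups[t]) for t in take]
        new[table.strata] = np.repeat(np.arange(len(take)), sizes)
        return table.with_df(new.reset_index(drop=True))
    idx = rng.integers(0, len(df), size=len(df))
    return table.with_df(df.iloc[idx].reset_index(drop=True))


def bootstrap_ci(
    statistic,
    table: CohortTable,
    config: BootstrapConfig | None = None,
    survey_warning: bool = False,
) -> BootstrapResult:
    """Bootstrap the statistic; returns point estimate, bias, SE and the
    requested interval type (componentwise for vector statistics).

    norm:  bias-corrected symmetric ``(theta - bias) +/- z * SE``.
    basic / perc / bca: the standard definitions; bca needs
    ``boot_rep`` greater than the number of resample units.
    """
    config = config or BootstrapConfig()
    if config.resample_unit == "stratum" and table.strata is None:
        raise ValueError("stratum resampling needs declared strata")
    if survey_warning:
        warnings.warn("plain bootstrap may be incorrect for cluster-sampled "
                      "surveys; supply a custom resampling scheme if needed")
    rng = np.random.default_rng(config.seed)
    point = np.atleast_1d(np.asarray(statistic(table), dtype=float))

    n_units = table.n
    if config.resample_unit == "stratum":
        n_units = table.df[table.strata].nunique()
    if config.ci_type == "bca" and config.boot_rep <= n_units:
        raise ValueError(
            f"bca needs boot_rep > number of resample units ({n_units})"
        )

    reps = np.empty((config.boot_rep, len(point)))
    for b in range(config.boot_rep):
        rt = _resample_table(table, rng, config.resample_unit)
        reps[b] = np.atleast_1d(np.asarray(statistic(rt), dtype=float))

    bias = reps.mean(axis=0) - point
    se = reps.std(axis=0, ddof=1)
    alpha = 1 - config.ci_level
    z = norm.ppf(1 - alpha / 2)

    if config.ci_type == "norm":
        centre = point - bias
        lower, upper = centre - z * se, centre + z * se
    elif config.ci_type == "perc":
        lower = np.quantile(reps, alpha / 2, axis=0)
        upper = np.quantile(reps, 1 - alpha / 2, axis=0)
    elif config.ci_type == "basic":
        qlo = np.quantile(reps, alpha / 2, axis=0)
        qhi = np.quantile(reps, 1 - alpha / 2, axis=0)
        lower, upper = 2 * point - qhi, 2 * point - qlo
    else:  # bca
        lower = np.empty_like(point)
        upper = np.empty_like(point)
        jack = _jackknife(statistic, table, config.resample_unit, len(point))
        for i in range(len(point)):
            lower[i], upper[i] = _bca_interval(
                point[i], reps[:, i], jack[:, i], alpha
            )
    return BootstrapResult(point=point, bias=bias, se=se, lower=lower,
                           upper=upper, ci_type=config.ci_type,
                           ci_level=config.ci_level, boot_rep=config.boot_rep,
                           replicates=reps)


def _jackknife(statistic, table: CohortTable, unit: str, dim: int) -> np.ndarray:
    df = table.df
    if unit == "stratum":
        codes, uniques = pd.factorize(df[table.strata])
        units = [np.flatnonzero(codes != g) for g in range(len(uniques))]
    else:
        units = [np.delete(np.arange(len(df)), i) for i in range(len(df))]
    out = np.empty((len(units), dim))
    for i, keep in enumerate(units):
        rt = table.with_df(df.iloc[keep].reset_index(drop=True))
        out[i] = np.atleast_1d(np.asarray(statistic(rt), dtype=float))
    return out


def _bca_interval(theta, reps, jack, alpha):
    eps = 1e-12
    prop = np.clip(np.mean(reps < theta), eps, 1 - eps)
    z0 = norm.ppf(prop)
    jbar = jack.mean()
    num = np.sum((jbar - jack) ** 3)
    den = 6.0 * (np.sum((jbar - jack) ** 2) ** 1.5 + eps)
    a = num / den
    z = norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(reps, adj)
    return lo, hi
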
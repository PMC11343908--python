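"""Core tabular types, case-control weight construction and dataset cleaning."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class RiskFactorSpec:
    """A categorical risk factor with a declared reference ("eliminated") level."""

    name: str
    refval: object = 0
    levels: tuple = ()

    def __post_init__(self):
        if self.levels and self.refval not in self.levels:
            raise ValueError(
                f"reference value {self.refval!r} not among levels of {self.name!r}"
            )
        if self.levels and len(self.levels) < 2:
            raise ValueError(f"risk factor {self.name!r} needs >= 2 levels")


@dataclass(frozen=True)
class DesignContext:
    """Study design plus the calculation method used downstream.

    ``calculation_method`` is "bruzzi" (case-only relative-risk formula) or
    "direct" (weighted standardisation).
    """

    design: str = "cross_sectional"
    prevalence: float | None = None
    calculation_method: str = "bruzzi"

    _DESIGNS = ("cross_sectional", "case_control", "cohort", "survey")

    def __post_init__(self):
        if self.design not in self._DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.calculation_method not in ("bruzzi", "direct"):
            raise ValueError(f"unknown calculation_method {self.calculation_method!r}")
        if self.prevalence is not None and not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if (
            self.design == "case_control"
            and self.calculation_method == "direct"
            and self.prevalence is None
        ):
            raise ValueError(
                "case_control design with the direct method requires prevalence ('prev')"
            )


@dataclass
class CohortTable:
    """One row per subject: binary outcome, risk factors, covariates and
    optional weights / matched strata / survival columns.

    The underlying frame is available as ``.df``; accessor properties return
    the role columns.  Validation happens on construction.
    """

    df: pd.DataFrame
    outcome: str
    risk_factors: list[RiskFactorSpec] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    weights: str | None = None
    strata: str | None = None
    time: str | None = None
    event: str | None = None

    def __post_init__(self):
        self.df = pd.DataFrame(self.df)
        self._validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.outcome].to_numpy(dtype=float)

    @property
    def w(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.n)
        return self.df[self.weights].to_numpy(dtype=float)

    def risk_factor(self, name: str) -> RiskFactorSpec:
        for rf in self.risk_factors:
            if rf.name == name:
                return rf
        raise KeyError(f"no declared risk factor {name!r}")

    def replace(self, **changes) -> "CohortTable":
        return dataclasses.replace(self, **changes)

    def with_df(self, df: pd.DataFrame) -> "CohortTable":
        return dataclasses.replace(self, df=df)

    # -- validation --------------------------------------------------------
    def _validate(self):
        cols = set(self.df.columns)
        for c in [self.outcome, self.weights, self.strata, self.time, self.event]:
            if c is not None and c not in cols:
                raise ValueError(f"declared column {c!r} missing from table")
        y = self.df[self.outcome].dropna()
        if not set(np.unique(y.to_numpy())) <= {0, 1, 0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if self.weights is not None:
            w = self.df[self.weights].to_numpy(dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("weights must be nonnegative with at least one positive")
        for rf in self.risk_factors:
            if rf.name not in cols:
                raise ValueError(f"risk factor column {rf.name!r} missing")
            col = self.df[rf.name].dropna()
            observed = set(col.unique())
            continuous = (
                pd.api.types.is_float_dtype(col)
                and col.nunique() > 12
                and not (col == col.round()).all()
            )
            if continuous:
                continue  # continuous exposures: no level check
            if rf.levels:
                if rf.refval not in set(rf.levels) | observed:
                    raise ValueError(f"refval absent for risk factor {rf.name!r}")
            elif observed and rf.refval not in observed:
                raise ValueError(
                    f"reference value {rf.refval!r} not observed for {rf.name!r}"
                )
        if self.time is not None:
            t = self.df[self.time].to_numpy(dtype=float)
            if (t[~np.isnan(t)] < 0).any():
                raise ValueError("time values must be nonnegative")
            if self.event is None:
                raise ValueError("time column requires an event column")
            ev = self.df[self.event].dropna()
            if not set(np.unique(ev.to_numpy())) <= {0, 1, 0.0, 1.0}:
                raise ValueError("event must be binary 0/1")

    def validate_strata_balance(self):
        """Check each matched set has at least one case and one control."""
        if self.strata is None:
            raise ValueError("no strata declared")
        g = self.df.groupby(self.strata)[self.outcome]
        bad = g.agg(lambda s: not (0 < s.sum() < len(s)) if len(s) > 1 else s.sum() not in (0, len(s)))
        counts = g.agg(["sum", "count"])
        bad = (counts["sum"] == 0) | (counts["sum"] == counts["count"])
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} matched strata lack a case or a control"
            )


def make_case_control_weights(table: CohortTable, prevalence: float) -> np.ndarray:
    """Per-row weights recalibrating a case-control sample to prevalence ``prevalence``.

    Cases receive ``prev / p_bar`` and controls ``(1 - prev) / (1 - p_bar)``
    where ``p_bar`` is the sample case fraction, so the weighted case fraction
    equals ``prevalence`` exactly and the weights sum to ~N.  For a 1:1 design
    the (case, control) pair is proportional to ``(prev, 1 - prev)``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    y = table.y
    n_cases = y.sum()
    if n_cases == 0 or n_cases == len(y):
        raise ValueError("degenerate case-control table: no cases or no controls")
    p_bar = n_cases / len(y)
    w = np.where(y == 1, prevalence / p_bar, (1 - prevalence) / (1 - p_bar))
    return w


def data_clean(
    table: CohortTable,
    prevalence: float | None = None,
    vars: list[str] | None = None,
    weights_col: str = "weights",
) -> CohortTable:
    """Restrict to ``vars``, drop rows with missing values, optionally attach
    prevalence-calibrated case-control weights.
    """
    df = table.df
    if vars is not None:
        missing = set(vars) - set(df.columns)
        if missing:
            raise ValueError(f"unknown columns requested: {sorted(missing)}")
        keep = list(vars)
        for extra in [table.outcome, table.weights, table.strata, table.time, table.event]:
            if extra is not None and extra not in keep:
                keep.append(extra)
        df = df[keep]
    df = df.dropna()
    if len(df) == 0:
        raise ValueError("all rows removed by missing-value filtering")
    out = table.with_df(df.reset_index(drop=True))
    out.risk_factors = [rf for rf in table.risk_factors if rf.name in df.columns]
    out.covariates = [c for c in table.covariates if c in df.columns]
    if prevalence is not None:
        w = make_case_control_weights(out, prevalence)
        new_df = out.df.copy()
        new_df[weights_col] = w
        out = out.with_df(new_df)
        out.weights = weights_col
    return out


# ---------------------------------------------------------------------------
# delimited IO with a column-role sidecar


def read_table(
    path,
    sidecar=None,
    sep: str = ",",
    outcome: str | None = None,
    riskfactors: dict | None = None,
    covariates: list[str] | None = None,
    weights: str | None = None,
    strata: str | None = None,
    time: str | None = None,
    event: str | None = None,
    categorical: list[str] | None = None,
) -> CohortTable:
    """Read a delimited file plus column roles (from a YAML/JSON sidecar or
    keyword arguments) into a :class:`CohortTable`."""
    roles = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            roles = yaml.safe_load(fh) or {}
    if outcome is not None:
        roles["outcome"] = outcome
    if riskfactors is not None:
        roles["riskfactors"] = riskfactors
    for key, val in [
        ("covariates", covariates),
        ("weights", weights),
        ("strata", strata),
        ("time", time),
        ("event", event),
        ("categorical", categorical),
    ]:
        if val is not None:
            roles[key] = val
    if "outcome" not in roles:
        raise ValueError("an outcome column must be declared")
    df = pd.read_csv(path, sep=sep)
    for col in roles.get("categorical", []):
        df[col] = df[col].astype("category")
    rf_specs = [
        RiskFactorSpec(name=name, refval=ref)
        for name, ref in (roles.get("riskfactors") or {}).items()
    ]
    return CohortTable(
        df=df,
        outcome=roles["outcome"],
        risk_factors=rf_specs,
        covariates=roles.get("covariates", []),
        weights=roles.get("weights"),
        strata=roles.get("strata"),
        time=roles.get("time"),
        event=roles.get("event"),
    )


def write_table(table: CohortTable, path, sep: str = ",") -> None:
    table.df.to_csv(path, sep=sep, index=False)
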
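"""Synthetic-population generator and ground-truth oracle.

Populations are simulated from a configurable causal Bayesian network; study
designs are sampled from them; oracle PAFs come from brute-force paired
counterfactual Monte-Carlo (common random numbers), which is the reference
every estimator module is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .causal_sim import CausalDAG
from .data_model import CohortTable, RiskFactorSpec, make_case_control_weights

_FAMILIES = ("linear", "logistic", "ordinal", "categorical")


@dataclass
class NodeLaw:
    """Generative law for one node given its parents (all numeric-coded).

    linear:      value = intercept + x'coef + noise_sd * z
    logistic:    P(1)  = expit(intercept + x'coef)
    ordinal:     P(Y <= k) = expit(cutpoints[k] - x'coef); levels 0..K-1
    categorical: softmax over per-level logits (level 0 is baseline)
    """

    family: str
    coef: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 1.0
    cutpoints: tuple = ()
    level_logits: tuple = ()  # categorical: ((intercept, {parent: coef}), ...)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class SurvivalLaw:
    """Exponential event times with rate ``base_rate * exp(x'coef)`` and
    independent exponential censoring."""

    base_rate: float
    coef: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.1


@dataclass
class GenerativeConfig:
    dag: CausalDAG
    node_laws: dict[str, NodeLaw]
    survival: SurvivalLaw | None = None
    seed: int | None = None

    def __post_init__(self):
        missing = set(self.dag.node_vec) - set(self.node_laws)
        if missing:
            raise ValueError(f"laws missing for nodes: {sorted(missing)}")
        for node, law in self.node_laws.items():
            extra = set(law.coef) - set(self.dag.parents(node))
            if extra:
                raise ValueError(
                    f"law for {node!r} references non-parents: {sorted(extra)}"
                )


def _linpred(law_coef: dict, intercept: float, values: dict, n: int) -> np.ndarray:
    lp = np.full(n, intercept, dtype=float)
    for parent, beta in law_coef.items():
        lp += beta * values[parent]
    return lp


def _draw_node(law: NodeLaw, values: dict, noise: np.ndarray, n: int) -> np.ndarray:
    if law.family == "linear":
        return _linpred(law.coef, law.intercept, values, n) + law.noise_sd * noise
    if law.family == "logistic":
        p = expit(_linpred(law.coef, law.intercept, values, n))
        u = noise  # uniforms
        return (u < p).astype(float)
    if law.family == "ordinal":
        lat = _linpred(law.coef, law.intercept, values, n)
        cuts = np.asarray(law.cutpoints, dtype=float)
        cum = expit(cuts[None, :] - lat[:, None])  # n x (K-1)
        u = noise[:, None]
        return (u > cum).sum(axis=1).astype(float)
    if law.family == "categorical":
        logits = np.zeros((n, len(law.level_logits) + 1))
        for j, (icpt, coefs) in enumerate(law.level_logits, start=1):
            logits[:, j] = _linpred(coefs, icpt, values, n)
        ex = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = ex / ex.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        return (noise[:, None] > cum).sum(axis=1).astype(float)
    raise AssertionError(law.family)


def _noise_for(law: NodeLaw, rng: np.random.Generator, n: int) -> np.ndarray:
    if law.family == "linear":
        return rng.standard_normal(n)
    return rng.random(n)


def _simulate(
    config: GenerativeConfig,
    n: int,
    noises: dict[str, np.ndarray],
    intervention: dict | None = None,
) -> dict[str, np.ndarray]:
    """One pass through the network in topological order, reusing the supplied
    noise arrays (common random numbers across factual/counterfactual)."""
    intervention = intervention or {}
    kind = intervention.get("type")
    values: dict[str, np.ndarray] = {}
    for node in config.dag.node_vec:
        law = config.node_laws[node]
        if kind == "eliminate" and node in intervention["nodes"]:
            ref = config.dag.risk_nodes.get(node, 0)
            values[node] = np.full(n, float(ref))
            continue
        if kind == "freeze_mediator" and node == intervention["mediator"]:
            rf = intervention["riskfactor"]
            ref = float(config.dag.risk_nodes.get(rf, 0))
            frozen = dict(values)
            frozen[rf] = np.full(n, ref)
            values[node] = _draw_node(law, frozen, noises[node], n)
            continue
        values[node] = _draw_node(law, values, noises[node], n)
        if kind == "shift" and node == intervention["node"]:
            values[node] = np.asarray(intervention["fn"](values[node]), dtype=float)
    return values


def _outcome_prob(config: GenerativeConfig, values: dict, n: int) -> np.ndarray:
    law = config.node_laws[config.dag.outcome_node]
    if law.family != "logistic":
        raise ValueError("outcome law must be logistic")
    return expit(_linpred(law.coef, law.intercept, values, n))


def generate_population(config: GenerativeConfig, n: int, seed=None) -> CohortTable:
    """Draw n rows from the network; optional survival columns come from the
    exponential law with hazard proportional to exp of the covariate score."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    noises = {node: _noise_for(config.node_laws[node], rng, n)
              for node in config.dag.node_vec}
    values = _simulate(config, n, noises)
    df = pd.DataFrame({node: values[node] for node in config.dag.node_vec})
    table_kwargs = {}
    if config.survival is not None:
        rate = config.survival.base_rate * np.exp(
            _linpred(config.survival.coef, 0.0, values, n)
        )
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.exponential(1.0 / config.survival.censor_rate, size=n)
        df["time"] = np.minimum(t_event, t_cens)
        df["event"] = (t_event <= t_cens).astype(float)
        table_kwargs = {"time": "time", "event": "event"}
    rf_specs = [RiskFactorSpec(name=k, refval=v) for k, v in config.dag.risk_nodes.items()]
    return CohortTable(df=df, outcome=config.dag.outcome_node,
                       risk_factors=rf_specs, **table_kwargs)


def sample_case_control(
    population: CohortTable,
    n_cases: int,
    ratio: int = 1,
    matching_vars: list[str] | None = None,
    seed=None,
) -> CohortTable:
    """Case-control sample: all-or-sampled cases plus ``ratio`` controls per
    case (exact-matched on ``matching_vars`` when given, with stratum labels);
    weights recalibrate to the population case fraction."""
    rng = np.random.default_rng(seed)
    df = population.df
    y = population.y
    prevalence = float(y.mean())
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if len(case_idx) < n_cases:
        raise ValueError(f"population has only {len(case_idx)} cases")
    chosen_cases = rng.choice(case_idx, size=n_cases, replace=False)

    rows, strata = [], []
    if matching_vars:
        key = df[matching_vars].astype(float).apply(tuple, axis=1)
        pools = {k: list(rng.permutation(np.flatnonzero((y == 0) & (key == k).to_numpy())))
                 for k in key.iloc[chosen_cases].unique()}
        dropped = 0
        sid = 0
        for ci in chosen_cases:
            k = key.iloc[ci]
            pool = pools.get(k, [])
            if len(pool) < ratio:
                dropped += 1
                continue
            picks = [pool.pop() for _ in range(ratio)]
            rows.extend([ci, *picks])
            strata.extend([sid] * (1 + ratio))
            sid += 1
        if dropped:
            import warnings

            warnings.warn(f"dropped {dropped} cases lacking matched controls")
        out = df.iloc[rows].copy()
        out["stratum"] = strata
        strata_col = "stratum"
    else:
        chosen_ctrl = rng.choice(ctrl_idx, size=ratio * n_cases, replace=False)
        out = df.iloc[np.concatenate([chosen_cases, chosen_ctrl])].copy()
        strata_col = None
    out = out.reset_index(drop=True)
    tmp = population.with_df(out)
    tmp.strata = strata_col
    w = make_case_control_weights(tmp, prevalence)
    out["weights"] = w
    res = population.with_df(out)
    res.strata = strata_col
    res.weights = "weights"
    return res


def oracle_paf(
    config: GenerativeConfig,
    intervention: dict | list | str,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Brute-force PAF ``(P(Y=1) - P(Y_cf=1)) / P(Y=1)`` by paired Monte-Carlo.

    ``intervention`` is a dict (see :func:`_simulate`) or a shorthand: a node
    name / list of node names meaning elimination of those risk nodes.
    Outcome probabilities are averaged directly (no outcome draw needed),
    sharing all node noise between the factual and counterfactual passes.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc below 10^4 gives an unreliable oracle")
    if isinstance(intervention, str):
        intervention = {"type": "eliminate", "nodes": [intervention]}
    elif isinstance(intervention, (list, tuple)):
        intervention = {"type": "eliminate", "nodes": list(intervention)}
    rng = np.random.default_rng(seed)
    noises = {node: _noise_for(config.node_laws[node], rng, n_mc)
              for node in config.dag.node_vec}
    fact = _simulate(config, n_mc, noises)
    cf = _simulate(config, n_mc, noises, intervention)
    p1 = _outcome_prob(config, fact, n_mc).mean()
    p0 = _outcome_prob(config, cf, n_mc).mean()
    return float((p1 - p0) / p1)


# ---------------------------------------------------------------------------
# ready-made fixture configurations


def stroke_like_config(seed: int | None = None) -> GenerativeConfig:
    """Confounder -> behaviour -> physiology -> preclinical disease -> outcome,
    mirroring the structure of a matched case-control stroke study: a mix of
    binary, ordinal and continuous risk factors and a rare outcome."""
    nodes = ["c_age", "c_sex", "b_smoking", "b_alcohol", "p_pressure", "pcd_diabetes", "y"]
    parents = {
        "b_smoking": ["c_age", "c_sex"],
        "b_alcohol": ["c_age", "c_sex"],
        "p_pressure": ["c_age", "c_sex", "b_smoking", "b_alcohol"],
        "pcd_diabetes": ["c_age", "b_smoking", "p_pressure"],
        "y": ["c_age", "c_sex", "b_smoking", "b_alcohol", "p_pressure", "pcd_diabetes"],
    }
    dag = CausalDAG(
        node_vec=nodes,
        parent_list=parents,
        risk_nodes={"b_smoking": 0, "b_alcohol": 0, "p_pressure": 0.0, "pcd_diabetes": 0},
        outcome_node="y",
    )
    laws = {
        "c_age": NodeLaw("linear", intercept=0.0, noise_sd=1.0),
        "c_sex": NodeLaw("logistic", intercept=0.0),
        "b_smoking": NodeLaw("logistic", intercept=-1.0,
                             coef={"c_age": 0.3, "c_sex": 0.4}),
        "b_alcohol": NodeLaw("ordinal", coef={"c_age": 0.2, "c_sex": 0.3},
                             cutpoints=(0.5, 2.0)),
        "p_pressure": NodeLaw("linear", intercept=0.0, noise_sd=1.0,
                              coef={"c_age": 0.3, "c_sex": 0.1,
                                    "b_smoking": 0.5, "b_alcohol": 0.2}),
        "pcd_diabetes": NodeLaw("logistic", intercept=-2.0,
                                coef={"c_age": 0.2, "b_smoking": 0.3,
                                      "p_pressure": 0.4}),
        "y": NodeLaw("logistic", intercept=-5.0,
                     coef={"c_age": 0.2, "c_sex": 0.1, "b_smoking": 0.6,
                           "b_alcohol": 0.25, "p_pressure": 0.5,
                           "pcd_diabetes": 0.7}),
    }
    survival = SurvivalLaw(base_rate=0.02,
                           coef={"c_age": 0.2, "p_pressure": 0.4, "b_smoking": 0.3},
                           censor_rate=0.05)
    return GenerativeConfig(dag=dag, node_laws=laws, survival=survival, seed=seed)


def chronic_cough_config(seed: int | None = None) -> GenerativeConfig:
    """Two binary risk factors plus one ordinal, with one binary factor
    upstream of the others."""
    dag = CausalDAG(
        node_vec=["urban", "smoking_cat", "occupational", "y"],
        parent_list={
            "smoking_cat": ["urban"],
            "occupational": ["urban"],
            "y": ["urban", "smoking_cat", "occupational"],
        },
        risk_nodes={"urban": 0, "smoking_cat": 0, "occupational": 0},
        outcome_node="y",
    )
    laws = {
        "urban": NodeLaw("logistic", intercept=-0.3),
        "smoking_cat": NodeLaw("ordinal", coef={"urban": 0.4},
                               cutpoints=(0.0, 1.2, 2.2)),
        "occupational": NodeLaw("logistic", intercept=-1.2, coef={"urban": 0.5}),
        "y": NodeLaw("logistic", intercept=-3.0,
                     coef={"urban": 0.4, "smoking_cat": 0.35, "occupational": 0.5}),
    }
    return GenerativeConfig(dag=dag, node_laws=laws, seed=seed)
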
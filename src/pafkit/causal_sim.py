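"""Causal-DAG machinery: per-node model fitting, recursive do-operator
simulation, and joint / sequential / average PAF.

Elimination of a risk-factor set is simulated one factor at a time: the
factor's column is pinned at its reference value and every strict descendant
(topological order, outcome excluded) is resimulated from its fitted node
model given the current parent values.  Continuous nodes are deterministic —
new prediction plus the subject's stored residual; discrete and ordinal nodes
are redrawn from the predicted category distribution, which is the only
source of simulation randomness.  The outcome node is never simulated: the
estimator standardises predicted outcome probabilities over the simulated
counterfactual data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .data_model import CohortTable, make_case_control_weights
from .model_adapters import OutcomeModelAdapter, fit_model
from .paf_discrete import PafResult


@dataclass
class CausalDAG:
    node_vec: list[str]
    parent_list: dict[str, list[str]]
    risk_nodes: dict[str, object]  # node -> reference value
    outcome_node: str

    def __post_init__(self):
        if self.outcome_node not in self.node_vec:
            raise ValueError("outcome node must be in node_vec")
        if set(self.parent_list) - set(self.node_vec):
            raise ValueError("parent_list keys must be nodes")
        g = nx.DiGraph()
        g.add_nodes_from(self.node_vec)
        for child, parents in self.parent_list.items():
            for p in parents:
                if p in self.node_vec:
                    g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph is cyclic")
        pos = {n: i for i, n in enumerate(self.node_vec)}
        for p, c in g.edges:
            if pos[p] > pos[c]:
                raise ValueError(
                    f"node_vec is not topologically sorted: {p!r} is a parent of "
                    f"{c!r} but listed after it"
                )
        if any(True for _ in g.successors(self.outcome_node)):
            raise ValueError("outcome node must have no children")
        for rn in self.risk_nodes:
            if rn not in self.node_vec:
                raise ValueError(f"risk node {rn!r} not in node_vec")
        self._graph = g

    def parents(self, node: str) -> list[str]:
        return list(self.parent_list.get(node, []))

    def descendants(self, node: str) -> list[str]:
        """Strict descendants in node_vec order, outcome excluded."""
        desc = nx.descendants(self._graph, node)
        return [n for n in self.node_vec if n in desc and n != self.outcome_node]

    @classmethod
    def from_yaml(cls, path) -> "CausalDAG":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(
            node_vec=list(spec["nodes"]),
            parent_list={k: list(v) for k, v in (spec.get("parents") or {}).items()},
            risk_nodes=dict(spec.get("risk_nodes") or {}),
            outcome_node=spec["outcome"],
        )


@dataclass
class NodeModelList:
    """Fitted adapters per non-root node (roots have none) plus metadata
    needed to resimulate: residuals live on the linear adapters."""

    models: dict[str, OutcomeModelAdapter]
    fit_weights: np.ndarray | None = None

    def __getitem__(self, node: str) -> OutcomeModelAdapter:
        return self.models[node]

    def __contains__(self, node: str) -> bool:
        return node in self.models


def _infer_family(col: pd.Series, is_outcome: bool) -> str:
    if is_outcome:
        return "binomial_logit"
    vals = col.dropna().unique()
    if len(vals) == 2:
        return "binomial_logit"
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        return "ordinal_logit"
    return "linear"


def make_node_formula(
    node: str,
    parents: list[str],
    common_terms: str = "",
    spline_nodes=(),
    df_spline: int = 3,
) -> str:
    terms = []
    if common_terms:
        terms.append(common_terms)
    for p in parents:
        if p in spline_nodes:
            terms.append(f"ns({p}, df={df_spline})")
        else:
            terms.append(p)
    rhs = " + ".join(terms) if terms else "1"
    return f"{node} ~ {rhs}"


def automatic_fit(
    table: CohortTable,
    dag: CausalDAG,
    prevalence: float | None = None,
    spline_nodes=(),
    common_terms: str = "",
    df_spline: int = 3,
    weights=None,
) -> NodeModelList:
    """Fit an additive model for every non-root node on its parents.

    Model families follow node type (binary -> logistic, categorical ->
    proportional-odds, numeric -> linear); all fits are weighted by
    prevalence-calibrated case-control weights when ``prevalence`` is given.
    """
    df = table.df
    missing = set(dag.node_vec) - set(df.columns)
    if missing:
        raise ValueError(f"DAG nodes missing from table: {sorted(missing)}")
    if prevalence is not None:
        w = make_case_control_weights(table, prevalence)
    elif weights is not None:
        w = df[weights].to_numpy(float) if isinstance(weights, str) else np.asarray(weights, float)
    else:
        w = np.ones(table.n)

    models: dict[str, OutcomeModelAdapter] = {}
    for node in dag.node_vec:
        parents = dag.parents(node)
        if not parents and node != dag.outcome_node:
            continue  # root: no model
        family = _infer_family(df[node], node == dag.outcome_node)
        formula = make_node_formula(node, parents, common_terms, spline_nodes, df_spline)
        models[node] = fit_model(table, formula, family, weights=w)
    return NodeModelList(models=models, fit_weights=w)


# ---------------------------------------------------------------------------
# do-operator simulation


def _set_reference(df: pd.DataFrame, node: str, refval) -> None:
    col = df[node]
    if isinstance(col.dtype, pd.CategoricalDtype):
        df[node] = pd.Categorical([refval] * len(df), categories=col.cat.categories)
    else:
        df[node] = refval


def _resimulate_node(
    df: pd.DataFrame, node: str, model: OutcomeModelAdapter, rng: np.random.Generator
) -> None:
    if model.family == "linear":
        if model.residuals is None:
            raise ValueError(f"no stored residuals for continuous node {node!r}")
        df[node] = np.asarray(model.predict(df)) + model.residuals
    elif model.family in ("binomial_logit", "binomial_log"):
        p = np.asarray(model.predict(df))
        draw = (rng.random(len(df)) < p).astype(int)
        col = df[node]
        if isinstance(col.dtype, pd.CategoricalDtype):
            cats = list(col.cat.categories)
            df[node] = pd.Categorical([cats[d] for d in draw], categories=cats)
        else:
            levels = sorted(pd.unique(col.dropna()))
            lo, hi = (levels + [0, 1])[:2] if len(levels) < 2 else (levels[0], levels[1])
            df[node] = np.where(draw == 1, hi, lo)
    elif model.family == "ordinal_logit":
        probs = model.predict(df)
        cum = np.cumsum(probs.to_numpy(), axis=1)
        u = rng.random(len(df))
        idx = (u[:, None] > cum).sum(axis=1)
        levels = list(probs.columns)
        vals = [levels[i] for i in idx]
        col = df[node]
        if isinstance(col.dtype, pd.CategoricalDtype):
            df[node] = pd.Categorical(vals, categories=col.cat.categories)
        else:
            df[node] = vals
    else:
        raise ValueError(f"cannot simulate node {node!r} with family {model.family!r}")


def _eliminate(
    df: pd.DataFrame,
    node: str,
    dag: CausalDAG,
    models: NodeModelList,
    rng: np.random.Generator,
    pinned: set,
) -> None:
    """In-place: pin ``node`` at its reference value and resimulate its strict
    descendants (excluding the outcome and previously pinned nodes)."""
    _set_reference(df, node, dag.risk_nodes[node])
    for d in dag.descendants(node):
        if d in pinned:
            continue
        if d not in models:
            raise ValueError(f"no fitted model for descendant node {d!r}")
        _resimulate_node(df, d, models[d], rng)


@dataclass
class SimulatedDataset:
    df: pd.DataFrame
    intervention: tuple
    seed: int | None = None


def simulate_do(
    table: CohortTable,
    dag: CausalDAG,
    models: NodeModelList,
    intervention,
    seed=None,
) -> SimulatedDataset:
    """Counterfactual dataset D_S for pinning the risk nodes in
    ``intervention`` at their reference levels."""
    bad = [s for s in intervention if s not in dag.risk_nodes]
    if bad:
        raise ValueError(f"not declared risk nodes: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = table.df.copy()
    pinned: set = set()
    for s in intervention:
        pinned.add(s)
        _eliminate(df, s, dag, models, rng, pinned)
    return SimulatedDataset(df=df, intervention=tuple(intervention),
                            seed=None if isinstance(seed, np.random.Generator) else seed)


# ---------------------------------------------------------------------------
# joint / sequential / average PAF


def _estimation_weights(table: CohortTable, prevalence, weights) -> np.ndarray:
    if prevalence is not None:
        return make_case_control_weights(table, prevalence)
    if weights is None:
        return np.ones(table.n)
    if isinstance(weights, str):
        return table.df[weights].to_numpy(dtype=float)
    return np.asarray(weights, dtype=float)


def _baseline(table: CohortTable, dag: CausalDAG, models: NodeModelList,
              w: np.ndarray) -> float:
    p0 = np.asarray(models[dag.outcome_node].predict(table.df))
    base = float(np.sum(w * p0))
    if base <= 0:
        raise ValueError("no weighted disease mass under the fitted outcome model")
    return base


def joint_paf(
    table: CohortTable,
    dag: CausalDAG,
    models: NodeModelList,
    riskfactors,
    prevalence: float | None = None,
    weights=None,
    nsim: int = 1,
    seed=None,
) -> PafResult:
    """Joint PAF for simultaneously eliminating ``riskfactors``, averaged over
    ``nsim`` independent simulations of the counterfactual data."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    riskfactors = [riskfactors] if isinstance(riskfactors, str) else list(riskfactors)
    w = _estimation_weights(table, prevalence, weights)
    base = _baseline(table, dag, models, w)
    outcome_model = models[dag.outcome_node]
    vals = []
    for _ in range(nsim):
        sim = simulate_do(table, dag, models, riskfactors, seed=rng)
        p = np.asarray(outcome_model.predict(sim.df))
        vals.append((base - float(np.sum(w * p))) / base)
    return PafResult("joint_PAF", float(np.mean(vals)), "do_operator",
                     meta={"riskfactors": tuple(riskfactors), "nsim": nsim})


def seq_paf(
    table: CohortTable,
    dag: CausalDAG,
    models: NodeModelList,
    vars,
    prevalence: float | None = None,
    weights=None,
    nsim: int = 1,
    seed=None,
) -> PafResult:
    """Sequential PAF for the last element of ``vars`` given prior elimination
    of the others; the two joint PAFs share one simulation chain, so
    sequential PAFs telescope exactly."""
    vars = list(vars)
    if len(vars) < 1 or len(set(vars)) != len(vars):
        raise ValueError("vars must be a nonempty list of distinct risk nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = _estimation_weights(table, prevalence, weights)
    base = _baseline(table, dag, models, w)
    outcome_model = models[dag.outcome_node]
    vals = []
    for _ in range(nsim):
        df = table.df.copy()
        pinned: set = set()
        for s in vars[:-1]:
            pinned.add(s)
            _eliminate(df, s, dag, models, rng, pinned)
        p_s = np.asarray(outcome_model.predict(df))
        paf_s = (base - float(np.sum(w * p_s))) / base if len(vars) > 1 else 0.0
        pinned.add(vars[-1])
        _eliminate(df, vars[-1], dag, models, rng, pinned)
        p_sj = np.asarray(outcome_model.predict(df))
        paf_sj = (base - float(np.sum(w * p_sj))) / base
        vals.append(paf_sj - paf_s)
    return PafResult("sequential_PAF", float(np.mean(vals)), "do_operator",
                     meta={"vars": tuple(vars), "nsim": nsim})


@dataclass
class AveragePafResult:
    apaf: pd.Series
    saf_by_position: pd.DataFrame  # rows: elimination position, cols: factor
    joint: float
    margin_of_error: pd.Series | None = None
    subset_pafs: dict | None = None
    meta: dict = field(default_factory=dict)


def _exact_subset_pafs(table, dag, models, factors, w, base, rng):
    """Joint PAF for every nonempty subset, depth-first so each child dataset
    extends its parent's simulation."""
    outcome_model = models[dag.outcome_node]
    pafs: dict[frozenset, float] = {}

    def recurse(subset: tuple, df: pd.DataFrame, start: int):
        for i in range(start, len(factors)):
            f = factors[i]
            child = subset + (f,)
            df_child = df.copy()
            pinned = set(child)
            _eliminate(df_child, f, dag, models, rng, pinned)
            p = np.asarray(outcome_model.predict(df_child))
            pafs[frozenset(child)] = (base - float(np.sum(w * p))) / base
            recurse(child, df_child, i + 1)

    recurse((), table.df.copy(), 0)
    return pafs


def apaf_weight(K: int, j: int) -> float:
    """Permutation weight ``(K-j)!(j-1)!/K!`` for a factor eliminated in
    position j (1-based)."""
    return math.factorial(K - j) * math.factorial(j - 1) / math.factorial(K)


def average_paf(
    table: CohortTable,
    dag: CausalDAG,
    models: NodeModelList,
    risk_set,
    exact: bool = True,
    nperm: int | None = None,
    correct_order: int | None = None,
    prevalence: float | None = None,
    weights=None,
    seed=None,
    max_exact_k: int = 15,
) -> AveragePafResult:
    """Average PAF for each factor in ``risk_set`` plus sequential PAF by
    elimination position.

    ``exact=True`` evaluates the joint PAF of every nonempty subset
    (2^K - 1 simulations, reusing parent-subset datasets) and combines the
    sequential PAFs with the permutation weights.  ``exact=False`` averages
    over ``nperm`` sampled permutations, optionally stratified so the first
    ``correct_order`` positions are jointly uniform, and reports a 95%
    margin of error for the permutation-sampling noise.
    """
    factors = list(risk_set)
    K = len(factors)
    if K < 1:
        raise ValueError("risk_set must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = _estimation_weights(table, prevalence, weights)
    base = _baseline(table, dag, models, w)
    outcome_model = models[dag.outcome_node]
    positions = [f"position {j}" for j in range(1, K + 1)]

    if exact:
        if K > max_exact_k:
            raise ValueError(
                f"exact mode needs 2^{K}-1 joint-PAF evaluations; limit is K <= {max_exact_k}"
            )
        pafs = _exact_subset_pafs(table, dag, models, factors, w, base, rng)
        pafs[frozenset()] = 0.0
        saf = pd.DataFrame(0.0, index=positions, columns=factors)
        for k in factors:
            others = [f for f in factors if f != k]
            for j in range(1, K + 1):
                vals = [
                    pafs[frozenset(S) | {k}] - pafs[frozenset(S)]
                    for S in combinations(others, j - 1)
                ]
                saf.loc[f"position {j}", k] = float(np.mean(vals))
        apaf = saf.mean(axis=0)
        joint = pafs[frozenset(factors)]
        return AveragePafResult(apaf=apaf, saf_by_position=saf, joint=joint,
                                subset_pafs={tuple(sorted(s)): v for s, v in pafs.items()},
                                meta={"exact": True})

    # --- permutation sampling ------------------------------------------
    if correct_order is not None:
        correct_order = min(correct_order, K)
        stratum = math.factorial(K) // math.factorial(K - correct_order)
        if nperm is None:
            nperm = stratum
        if nperm % stratum != 0:
            raise ValueError(
                f"stratified sampling needs nperm to be a multiple of {stratum}"
            )
        prefixes = list(permutations(range(K), correct_order)) * (nperm // stratum)
    else:
        if nperm is None or nperm < 1:
            raise ValueError("approximate mode needs nperm >= 1")
        prefixes = [() for _ in range(nperm)]

    saf_samples = np.zeros((nperm, K))  # columns aligned with `factors`
    pos_samples = np.full((nperm, K), np.nan)  # by elimination position
    pos_factor = np.zeros((nperm, K), dtype=int)
    for i, prefix in enumerate(prefixes):
        rest = [j for j in range(K) if j not in prefix]
        order = list(prefix) + list(rng.permutation(rest))
        df = table.df.copy()
        pinned: set = set()
        prev_pred = None
        base_i = base
        for pos, fidx in enumerate(order):
            f = factors[fidx]
            pinned.add(f)
            _eliminate(df, f, dag, models, rng, pinned)
            p = np.asarray(outcome_model.predict(df))
            cur = float(np.sum(w * p))
            prev = base_i if prev_pred is None else prev_pred
            saf_val = (prev - cur) / base
            saf_samples[i, fidx] = saf_val
            pos_samples[i, pos] = saf_val
            pos_factor[i, pos] = fidx
            prev_pred = cur

    apaf = pd.Series(saf_samples.mean(axis=0), index=factors)
    saf = pd.DataFrame(np.nan, index=positions, columns=factors)
    for j in range(K):
        for fidx, f in enumerate(factors):
            mask = pos_factor[:, j] == fidx
            if mask.any():
                saf.loc[f"position {j + 1}", f] = float(pos_samples[mask, j].mean())
    joint = float(saf_samples.sum(axis=1).mean())
    z = norm.ppf(0.975)
    moe = pd.Series(z * saf_samples.std(axis=0, ddof=1) / np.sqrt(nperm), index=factors)
    return AveragePafResult(apaf=apaf, saf_by_position=saf, joint=joint,
                            margin_of_error=moe,
                            meta={"exact": False, "nperm": nperm,
                                  "correct_order": correct_order})


def naive_joint_paf(
    model: OutcomeModelAdapter,
    table: CohortTable,
    risk_refvals: dict,
    prevalence: float | None = None,
    weights=None,
) -> PafResult:
    """Causally agnostic joint PAF from a single outcome regression: all risk
    factors set to reference in one counterfactual prediction, no propagation
    through the graph.  Biased when one risk factor confounds another;
    provided for the documented bias contrast."""
    from .paf_discrete import impact_fraction_direct

    new_df = table.df.copy()
    for node, ref in risk_refvals.items():
        _set_reference(new_df, node, ref)
    est = impact_fraction_direct(model, table, new_df, weights, prevalence)
    return PafResult("joint_PAF", est, "single_regression",
                     meta={"riskfactors": tuple(risk_refvals)})
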
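"""Discrete Bayesian networks learned by max-min hill-climbing (MMHC).

MMHC is a hybrid structure learner: a constraint-based phase (MMPC) finds
each variable's candidate parents and children using the max-min heuristic
over a conditional G²-type dependence statistic, and a score-based phase
(greedy hill-climbing restricted to the discovered skeleton) orients edges
by maximising a decomposable score (BIC by default, BDeu optional).
Parameters are estimated as smoothed conditional probability tables and the
survival-status posterior is obtained by exact enumeration over the Markov
factorization  P(X₁,…,Xₙ) = ∏ᵢ P(Xᵢ | Pa(Xᵢ)).

All variables are discrete and encoded as integer levels 0…k−1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "CPCSet",
    "DiscreteBayesianNetwork",
    "assoc",
    "min_assoc",
    "mmpc",
    "build_skeleton",
    "hill_climb",
    "fit_parameters",
    "mmhc",
    "predict_outcome",
    "structural_hamming_distance",
    "cpdag",
    "shd_cpdag",
]


# ---------------------------------------------------------------------------
# conditional dependence statistic (Assoc / MinAssoc)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssocResult:
    """G²-type conditional dependence of ``x`` and ``t`` given ``z``."""

    statistic: float
    df: int
    p_value: float
    x: str
    t: str
    z: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.statistic < -1e-9:
            raise ValueError("Assoc statistic must be non-negative")


def _levels_of(data: pd.DataFrame, columns) -> dict[str, int]:
    return {c: int(data[c].max()) + 1 for c in columns}


def _encode(data: pd.DataFrame, cols: tuple[str, ...], levels: dict[str, int]) -> tuple[np.ndarray, int]:
    """Map the tuple of columns to a single flat stratum code."""
    code = np.zeros(len(data), dtype=np.int64)
    size = 1
    for c in cols:
        code = code * levels[c] + data[c].to_numpy()
        size *= levels[c]
    return code, size


def assoc(data: pd.DataFrame, x: str, t: str, z: tuple[str, ...] = (),
          levels: dict[str, int] | None = None) -> AssocResult:
    """Conditional dependence Assoc(X, T | Z).

    The statistic is the likelihood-ratio form
    ``2 Σ_{a,b,c} N_abc · ln(N_abc · N_c / (N_ac · N_bc))`` over the joint
    cell counts of (X=a, T=b, Z=c); cells with zero count contribute zero,
    and empty conditioning strata neither contribute nor reduce the degrees
    of freedom ``(|X|−1)(|T|−1)·Π|Zᵢ|``.
    """
    z = tuple(z)
    names = {x, t, *z}
    if len(names) != 2 + len(z):
        raise ValueError("x, t and z must be pairwise disjoint")
    if len(data) == 0:
        raise ValueError("empty data")
    if levels is None:
        levels = _levels_of(data, (x, t, *z))
    kx, kt = levels[x], levels[t]
    zcode, nz = _encode(data, z, levels)
    xv = data[x].to_numpy()
    tv = data[t].to_numpy()
    flat = (zcode * kx + xv) * kt + tv
    n_abc = np.bincount(flat, minlength=nz * kx * kt).reshape(nz, kx, kt).astype(float)
    n_ac = n_abc.sum(axis=2, keepdims=True)
    n_bc = n_abc.sum(axis=1, keepdims=True)
    n_c = n_abc.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = n_abc * n_c / (n_ac * n_bc)
        term = n_abc * np.log(ratio)
    stat = 2.0 * float(term[n_abc > 0].sum())
    stat = max(stat, 0.0)
    df = (kx - 1) * (kt - 1) * nz
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return AssocResult(stat, df, p, x, t, z)


def _subsets(z: tuple[str, ...], maxk: int):
    """Subsets of z up to size maxk, smallest first, lexicographic within size."""
    z = tuple(sorted(z))
    for size in range(min(len(z), maxk) + 1):
        yield from itertools.combinations(z, size)


def min_assoc(data: pd.DataFrame, x: str, t: str, z: tuple[str, ...],
              maxk: int = 3, levels: dict[str, int] | None = None,
              min_n_per_df: float | None = None,
              _cache: dict | None = None) -> tuple[AssocResult, tuple[str, ...]]:
    """MinAssoc(X, T | Z): the weakest dependence over subsets S ⊆ Z.

    "Weakest" means largest p-value; ties go to the smallest subset and then
    lexicographic order (guaranteed by the enumeration order with a strict
    improvement test).  When ``min_n_per_df`` is set, a subset whose test has
    fewer than that many samples per degree of freedom is treated as
    uninformative (non-significant, p = 1) — the small-sample reliability
    guard used during MMPC.
    """
    if levels is None:
        levels = _levels_of(data, (x, t, *z))
    n = len(data)
    best: AssocResult | None = None
    best_s: tuple[str, ...] = ()
    for s in _subsets(z, maxk):
        key = (min(x, t), max(x, t), s)
        if _cache is not None and key in _cache:
            res = _cache[key]
        else:
            res = assoc(data, x, t, s, levels=levels)
            if _cache is not None:
                _cache[key] = res
        p = res.p_value
        if min_n_per_df is not None and res.df > 0 and n / res.df < min_n_per_df:
            res = AssocResult(res.statistic, res.df, 1.0, res.x, res.t, res.z)
            p = 1.0
        if best is None or p > best.p_value:
            best, best_s = res, s
    assert best is not None
    return best, best_s


# ---------------------------------------------------------------------------
# MMPC skeleton discovery
# ---------------------------------------------------------------------------

@dataclass
class CPCSet:
    """Candidate parents and children of a target variable."""

    target: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.target in self.members:
            raise ValueError("target cannot be in its own CPC")


def _cpc_raw(target: str, data: pd.DataFrame, variables: list[str],
             alpha: float, maxk: int, levels: dict[str, int],
             min_n_per_df: float | None, cache: dict) -> list[str]:
    cpc: list[str] = []
    remaining = sorted(v for v in variables if v != target)
    # forward: admit the variable with the strongest worst-case dependence
    while remaining:
        best_var, best_p, best_res = None, None, None
        for x in remaining:
            res, _ = min_assoc(data, x, target, tuple(cpc), maxk=maxk,
                               levels=levels, min_n_per_df=min_n_per_df,
                               _cache=cache)
            if best_p is None or res.p_value < best_p:
                best_var, best_p, best_res = x, res.p_value, res
        if best_p is None or best_p >= alpha:
            break
        cpc.append(best_var)
        remaining.remove(best_var)
    # backward: drop members rendered independent by some subset of the rest
    for x in sorted(cpc):
        others = tuple(v for v in cpc if v != x)
        res, _ = min_assoc(data, x, target, others, maxk=maxk, levels=levels,
                           min_n_per_df=min_n_per_df, _cache=cache)
        if res.p_value >= alpha:
            cpc.remove(x)
    return sorted(cpc)


def mmpc(target: str, data: pd.DataFrame, alpha: float = 0.05, maxk: int = 3,
         symmetry: bool = True, min_n_per_df: float | None = 5.0,
         _cache: dict | None = None) -> CPCSet:
    """Max-min parents-and-children set of ``target``.

    Phase 1 repeatedly admits the variable maximising the min-association
    with the target given the current CPC (i.e. smallest worst-case p),
    provided it is conditionally dependent at ``alpha``; phase 2 removes
    members made independent by some subset of the remainder.  With
    ``symmetry`` the asymmetric false positives are pruned: X stays in
    CPC(target) only if target ∈ CPC(X).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    variables = list(data.columns)
    levels = _levels_of(data, variables)
    cache = {} if _cache is None else _cache
    cpc = _cpc_raw(target, data, variables, alpha, maxk, levels, min_n_per_df, cache)
    if symmetry:
        kept = []
        for x in cpc:
            back = _cpc_raw(x, data, variables, alpha, maxk, levels, min_n_per_df, cache)
            if target in back:
                kept.append(x)
        cpc = kept
    return CPCSet(target, tuple(cpc))


def build_skeleton(data: pd.DataFrame, alpha: float = 0.05, maxk: int = 3,
                   min_n_per_df: float | None = 5.0) -> nx.Graph:
    """Symmetric undirected skeleton: union of all pairwise-confirmed CPC sets."""
    cache: dict = {}
    variables = list(data.columns)
    levels = _levels_of(data, variables)
    raw = {t: set(_cpc_raw(t, data, variables, alpha, maxk, levels, min_n_per_df, cache))
           for t in variables}
    g = nx.Graph()
    g.add_nodes_from(variables)
    for t in variables:
        for x in raw[t]:
            if t in raw[x]:
                g.add_edge(t, x)
    return g


# ---------------------------------------------------------------------------
# decomposable scores and greedy hill-climbing
# ---------------------------------------------------------------------------

def _family_counts(data: pd.DataFrame, node: str, parents: tuple[str, ...],
                   levels: dict[str, int]) -> np.ndarray:
    """Counts of shape (parent configurations, node levels)."""
    pcode, np_cfg = _encode(data, parents, levels)
    k = levels[node]
    flat = pcode * k + data[node].to_numpy()
    return np.bincount(flat, minlength=np_cfg * k).reshape(np_cfg, k).astype(float)


def family_score(data: pd.DataFrame, node: str, parents: tuple[str, ...],
                 levels: dict[str, int], score: str = "bic",
                 bdeu_ess: float = 10.0) -> float:
    """BIC (log-likelihood minus ½·ln n per free parameter) or BDeu marginal
    likelihood of one node given a parent set."""
    counts = _family_counts(data, node, parents, levels)
    k = levels[node]
    if score == "bic":
        row = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = counts * (np.log(counts) - np.log(row))
        loglik = float(ll[counts > 0].sum())
        n_params = (k - 1) * counts.shape[0]
        return loglik - 0.5 * math.log(len(data)) * n_params
    if score == "bdeu":
        q = counts.shape[0]
        a_row = bdeu_ess / q
        a_cell = bdeu_ess / (q * k)
        row = counts.sum(axis=1)
        val = (gammaln(a_row) - gammaln(a_row + row)).sum()
        val += (gammaln(a_cell + counts) - gammaln(a_cell)).sum()
        return float(val)
    raise ValueError(f"unknown score {score!r}")


@dataclass
class HillClimbResult:
    graph: nx.DiGraph
    score: float
    moves: list[tuple[str, str, str, float]]  # (op, u, v, delta)


def hill_climb(skeleton: nx.Graph, data: pd.DataFrame, score: str = "bic",
               bdeu_ess: float = 10.0, max_iter: int = 10_000) -> HillClimbResult:
    """Greedy search over add / delete / reverse moves.

    Edge additions are restricted to skeleton pairs; cycles are forbidden;
    the best strictly score-improving move is taken until none remains.
    Node scores are cached per (node, parent set).
    """
    variables = list(skeleton.nodes)
    levels = _levels_of(data, variables)
    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def ns(node: str, parents: frozenset) -> float:
        key = (node, tuple(sorted(parents)))
        if key not in cache:
            cache[key] = family_score(data, node, key[1], levels, score, bdeu_ess)
        return cache[key]

    g = nx.DiGraph()
    g.add_nodes_from(variables)
    parents = {v: frozenset() for v in variables}
    total = sum(ns(v, parents[v]) for v in variables)
    moves: list[tuple[str, str, str, float]] = []

    skel_pairs = {frozenset(e) for e in skeleton.edges}

    for _ in range(max_iter):
        best: tuple[float, str, str, str] | None = None
        for u, v in itertools.permutations(variables, 2):
            if g.has_edge(u, v):
                # delete
                d = ns(v, parents[v] - {u}) - ns(v, parents[v])
                if best is None or d > best[0]:
                    best = (d, "delete", u, v)
                # reverse
                if not g.has_edge(v, u):
                    g.remove_edge(u, v)
                    ok = not nx.has_path(g, u, v)
                    g.add_edge(u, v)
                    if ok:
                        d = (ns(v, parents[v] - {u}) - ns(v, parents[v])
                             + ns(u, parents[u] | {v}) - ns(u, parents[u]))
                        if d > best[0]:
                            best = (d, "reverse", u, v)
            elif frozenset((u, v)) in skel_pairs and not g.has_edge(v, u):
                if nx.has_path(g, v, u):
                    continue
                d = ns(v, parents[v] | {u}) - ns(v, parents[v])
                if best is None or d > best[0]:
                    best = (d, "add", u, v)
        if best is None or best[0] <= 1e-9:
            break
        d, op, u, v = best
        if op == "add":
            g.add_edge(u, v)
            parents[v] = parents[v] | {u}
        elif op == "delete":
            g.remove_edge(u, v)
            parents[v] = parents[v] - {u}
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
            parents[v] = parents[v] - {u}
            parents[u] = parents[u] | {v}
        total += d
        moves.append((op, u, v, d))
    return HillClimbResult(g, total, moves)


# ---------------------------------------------------------------------------
# the network object and parameter fitting
# ---------------------------------------------------------------------------

@dataclass
class DiscreteBayesianNetwork:
    """A directed acyclic graph with per-node conditional probability tables.

    ``cpts[v]`` has shape ``(*parent levels in parents[v] order, levels[v])``
    and every row (last axis) sums to one.
    """

    nodes: list[str]
    levels: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    outcome: str | None = None
    n_fit: int | None = None

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set contains a cycle")
        for v in self.nodes:
            cpt = np.asarray(self.cpts[v], dtype=float)
            expect = tuple(self.levels[p] for p in self.parents[v]) + (self.levels[v],)
            if cpt.shape != expect:
                raise ValueError(f"CPT shape mismatch for {v}: {cpt.shape} vs {expect}")
            if np.any(np.abs(cpt.sum(axis=-1) - 1.0) > 1e-9):
                raise ValueError(f"CPT rows of {v} do not sum to 1")
            self.cpts[v] = cpt
        if self.outcome is not None and self.outcome not in self.nodes:
            raise ValueError("outcome node missing from network")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        return g

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(p, v) for v in self.nodes for p in self.parents[v]]

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))

    # -- plain-text serialization ------------------------------------------
    def to_text(self) -> str:
        lines = []
        for v in self.nodes:
            lines.append(f"node {v} levels {self.levels[v]}")
        for v in self.nodes:
            lines.append(f"parents {v}: {', '.join(self.parents[v])}")
        if self.outcome:
            lines.append(f"outcome {self.outcome}")
        for v in self.nodes:
            lines.append(f"cpt {v}")
            cpt = self.cpts[v].reshape(-1, self.levels[v])
            for row in cpt:
                lines.append(" ".join(format(x, ".12g") for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DiscreteBayesianNetwork":
        nodes, levels, parents, outcome = [], {}, {}, None
        cpt_rows: dict[str, list[list[float]]] = {}
        current = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("node "):
                _, name, _, k = line.split()
                nodes.append(name)
                levels[name] = int(k)
            elif line.startswith("parents "):
                head, _, tail = line.partition(":")
                name = head.split()[1]
                parents[name] = tuple(p.strip() for p in tail.split(",") if p.strip())
            elif line.startswith("outcome "):
                outcome = line.split()[1]
            elif line.startswith("cpt "):
                current = line.split()[1]
                cpt_rows[current] = []
            else:
                cpt_rows[current].append([float(x) for x in line.split()])
        cpts = {}
        for v in nodes:
            shape = tuple(levels[p] for p in parents[v]) + (levels[v],)
            cpts[v] = np.array(cpt_rows[v], dtype=float).reshape(shape)
        return cls(nodes, levels, parents, cpts, outcome=outcome)


def fit_parameters(graph: nx.DiGraph, data: pd.DataFrame, pseudocount: float = 1.0,
                   levels: dict[str, int] | None = None,
                   outcome: str | None = None) -> DiscreteBayesianNetwork:
    """Smoothed maximum-likelihood CPTs:
    each row = (count + pseudocount) / (row total + pseudocount·levels)."""
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("graph must be acyclic")
    missing = [v for v in graph.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"nodes absent from data: {missing}")
    nodes = sorted(graph.nodes)
    if levels is None:
        levels = _levels_of(data, nodes)
    parents = {v: tuple(sorted(graph.predecessors(v))) for v in nodes}
    cpts = {}
    for v in nodes:
        counts = _family_counts(data, v, parents[v], levels)
        counts += pseudocount
        cpt = counts / counts.sum(axis=1, keepdims=True)
        cpts[v] = cpt.reshape(tuple(levels[p] for p in parents[v]) + (levels[v],))
    return DiscreteBayesianNetwork(nodes, levels, parents, cpts,
                                   outcome=outcome, n_fit=len(data))


def mmhc(data: pd.DataFrame, alpha: float = 0.05, maxk: int = 3,
         score: str = "bic", bdeu_ess: float = 10.0, pseudocount: float = 1.0,
         outcome: str | None = None) -> tuple[DiscreteBayesianNetwork, HillClimbResult]:
    """Full MMHC: skeleton by MMPC, orientation by hill-climbing, CPT fit."""
    skel = build_skeleton(data, alpha=alpha, maxk=maxk)
    hc = hill_climb(skel, data, score=score, bdeu_ess=bdeu_ess)
    net = fit_parameters(hc.graph, data, pseudocount=pseudocount, outcome=outcome)
    return net, hc


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

def predict_outcome(net: DiscreteBayesianNetwork, evidence: dict[str, int],
                    target: str | None = None) -> dict:
    """Posterior over the outcome node by enumeration of the factorization.

    Sums the product ∏ᵢ P(Xᵢ | Pa(Xᵢ)) over every configuration of the
    unobserved non-target nodes, then normalizes.  Returns the posterior
    vector, the arg-max level (ties broken toward the lowest level, flagged)
    and the tie flag.
    """
    target = target or net.outcome
    if target is None:
        raise ValueError("no target node given and network has no outcome")
    for v, val in evidence.items():
        if v not in net.levels:
            raise ValueError(f"unknown evidence node {v!r}")
        if not 0 <= int(val) < net.levels[v]:
            raise ValueError(f"evidence value {val} outside levels of {v!r}")
    if target in evidence:
        raise ValueError("target cannot be part of the evidence")
    hidden = [v for v in net.nodes if v != target and v not in evidence]
    kt = net.levels[target]
    post = np.zeros(kt)
    for cfg in itertools.product(*(range(net.levels[v]) for v in hidden)):
        assign = dict(zip(hidden, cfg))
        assign.update(evidence)
        for y in range(kt):
            assign[target] = y
            p = 1.0
            for v in net.nodes:
                idx = tuple(assign[q] for q in net.parents[v]) + (assign[v],)
                p *= net.cpts[v][idx]
            post[y] += p
    total = post.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the network")
    post /= total
    best = int(np.argmax(post))
    tie = bool(np.sum(np.isclose(post, post[best], atol=1e-12)) > 1)
    if tie:
        logger.warning("posterior tie for target %s; lowest level reported", target)
    return {"posterior": post, "level": best, "tie": tie, "target": target}


# ---------------------------------------------------------------------------
# graph comparison
# ---------------------------------------------------------------------------

def structural_hamming_distance(g1: nx.DiGraph, g2: nx.DiGraph) -> int:
    """Edge insertions + deletions + reversals separating two DAGs."""
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")
    d = 0
    seen = set()
    for u, v in set(g1.edges) | set(g2.edges):
        pair = frozenset((u, v))
        if pair in seen:
            continue
        seen.add(pair)
        e1 = ("f" if g1.has_edge(u, v) else "") + ("b" if g1.has_edge(v, u) else "")
        e2 = ("f" if g2.has_edge(u, v) else "") + ("b" if g2.has_edge(v, u) else "")
        if e1 != e2:
            d += 1
    return d


def cpdag(g: nx.DiGraph) -> tuple[set[tuple[str, str]], set[frozenset]]:
    """Completed partially directed acyclic graph of a DAG.

    Returns (directed compelled edges, undirected reversible edges).
    V-structure edges are compelled; the Meek rules propagate orientation.
    """
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("input must be a DAG")
    skel = {frozenset(e) for e in g.edges}
    adj = lambda a, b: frozenset((a, b)) in skel
    directed: set[tuple[str, str]] = set()
    for v in g.nodes:
        ps = list(g.predecessors(v))
        for a, b in itertools.combinations(ps, 2):
            if not adj(a, b):
                directed.add((a, v))
                directed.add((b, v))
    undirected = {e for e in skel if (tuple(e)[0], tuple(e)[1]) not in directed
                  and (tuple(e)[1], tuple(e)[0]) not in directed}
    # Meek rules until fixpoint
    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # R1: z→x, z not adjacent to y  ⇒  x→y
                if any((z, x) in directed and not adj(z, y)
                       for z in g.nodes if z not in (x, y)):
                    directed.add((x, y)); undirected.discard(e); changed = True; break
                # R2: directed path x→z→y  ⇒  x→y
                if any((x, z) in directed and (z, y) in directed
                       for z in g.nodes if z not in (x, y)):
                    directed.add((x, y)); undirected.discard(e); changed = True; break
                # R3: x—z1→y, x—z2→y, z1 not adjacent z2  ⇒  x→y
                zs = [z for z in g.nodes if z not in (x, y)
                      and frozenset((x, z)) in undirected and (z, y) in directed]
                if any(not adj(z1, z2) for z1, z2 in itertools.combinations(zs, 2)):
                    directed.add((x, y)); undirected.discard(e); changed = True; break
            if changed:
                break
    return directed, undirected


def shd_cpdag(g1: nx.DiGraph, g2: nx.DiGraph) -> int:
    """Structural Hamming distance between the equivalence classes (CPDAGs)."""
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")
    d1, u1 = cpdag(g1)
    d2, u2 = cpdag(g2)

    def kind(dirs, undirs, u, v):
        if (u, v) in dirs:
            return ">"
        if (v, u) in dirs:
            return "<"
        if frozenset((u, v)) in undirs:
            return "-"
        return ""

    d = 0
    pairs = {frozenset((u, v)) for u, v in set(g1.edges) | set(g2.edges)}
    for pair in pairs:
        u, v = sorted(pair)
        if kind(d1, u1, u, v) != kind(d2, u2, u, v):
            d += 1
    return d
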
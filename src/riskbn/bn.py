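"""Hybrid Bayesian-network structure selection over {TTC, Offset, SA, SCR}.

The candidate space: the two manipulated factors are root nodes (no parents,
no edge between them) with discrete distributions fixed at the design
frequencies; the subjective-assessment node (SA) is Gaussian; the
skin-conductance node (SCR) is Tweedie compound-Poisson with a log link.
Each of SA and SCR may depend on any subset of the factors, and at most one
directed edge may join SA and SCR (in either direction), giving
4 x 4 x 3 = 48 acyclic structures per indicator pair.

Each structure is scored by the Bayesian Information Criterion

    BIC = -2 * LL + p * log(n),

which decomposes over nodes: the joint log-likelihood of a Bayesian network
is the sum of the conditional node log-likelihoods, so the network BIC is
the sum of per-node BICs.  Lower is better.  BIC differences are read with
the conventional grades of evidence: gaps above 2, 6 and 10 count as
positive, strong and very strong; structures within 2 of the best are
statistically indistinguishable from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import offset_marginal, ttc_marginal
from .tweedie import fit_tweedie_glm

__all__ = [
    "BNStructure",
    "NodeFit",
    "NetworkScore",
    "EvidenceGrades",
    "RankedReport",
    "enumerate_structures",
    "fit_node",
    "score_network",
    "score_all_structures",
    "rank_and_select",
]

FACTORS = ("TTC", "Offset")
_FACTOR_COL = {"TTC": "ttc_s", "Offset": "offset_m"}


@dataclass(frozen=True, order=True)
class BNStructure:
    """A candidate DAG, identified by the parent sets of SA and SCR."""

    sa_parents: tuple[str, ...]
    scr_parents: tuple[str, ...]

    def __post_init__(self) -> None:
        if "SCR" in self.sa_parents and "SA" in self.scr_parents:
            raise ValueError("cyclic structure: SA->SCR and SCR->SA")
        for p in self.sa_parents:
            if p not in FACTORS + ("SCR",):
                raise ValueError(f"invalid SA parent {p}")
        for p in self.scr_parents:
            if p not in FACTORS + ("SA",):
                raise ValueError(f"invalid SCR parent {p}")

    @property
    def has_inter_edge(self) -> bool:
        return "SCR" in self.sa_parents or "SA" in self.scr_parents

    def label(self, sa_name: str = "SA", scr_name: str = "SCR") -> str:
        def side(parents, rename):
            ps = [rename.get(p, p) for p in parents]
            return ",".join(ps) if ps else "."

        rename = {"SA": sa_name, "SCR": scr_name}
        return (f"L({sa_name}|{side(self.sa_parents, rename)}) * "
                f"L({scr_name}|{side(self.scr_parents, rename)})")

    def edges(self) -> list[tuple[str, str]]:
        return [(p, "SA") for p in self.sa_parents] + [
            (p, "SCR") for p in self.scr_parents
        ]


def _subsets(items: tuple[str, ...]):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def enumerate_structures() -> list[BNStructure]:
    """All 48 acyclic candidates: factor subsets for each child node times
    {no inter-node edge, SA->SCR, SCR->SA}."""
    out = []
    for sa_f in _subsets(FACTORS):
        for scr_f in _subsets(FACTORS):
            out.append(BNStructure(sa_parents=sa_f, scr_parents=scr_f))
            out.append(BNStructure(sa_parents=sa_f, scr_parents=scr_f + ("SA",)))
            out.append(BNStructure(sa_parents=sa_f + ("SCR",), scr_parents=scr_f))
    return sorted(out)


@dataclass
class NodeFit:
    """A fitted conditional distribution at one node."""

    node: str
    family: str  # "discrete-fixed" | "gaussian" | "tweedie"
    parents: tuple[str, ...]
    loglik: float
    n_params: int
    params: dict = field(default_factory=dict)

    def bic(self, n: int) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(n)


def _root_fit(node: str, data: pd.DataFrame) -> NodeFit:
    """Discrete root node with probabilities fixed from the design table.

    Fixed (not estimated) frequencies contribute zero free parameters; the
    log-likelihood is a data-dependent constant that cancels in comparisons
    but keeps totals absolute.
    """
    probs = ttc_marginal() if node == "TTC" else offset_marginal()
    col = _FACTOR_COL[node]
    values = data[col].to_numpy()
    p = np.array([probs[v] for v in values])
    return NodeFit(node=node, family="discrete-fixed", parents=(),
                   loglik=float(np.sum(np.log(p))), n_params=0,
                   params={"probs": {str(k): v for k, v in probs.items()}})


def _cell_labels(data: pd.DataFrame, parents: tuple[str, ...]) -> pd.Series:
    cols = [_FACTOR_COL[p] for p in parents if p in FACTORS]
    if not cols:
        return pd.Series("all", index=data.index)
    return data[cols].astype(str).agg("|".join, axis=1)


def _gaussian_fit(node: str, parents: tuple[str, ...], data: pd.DataFrame,
                  value_col: str, cont_col: str | None) -> NodeFit:
    """Gaussian node: per-cell (mean, SD) for discrete parents; with a
    continuous parent, per-cell intercepts plus a common slope and SD."""
    y = data[value_col].to_numpy(dtype=float)
    cells = _cell_labels(data, parents)
    has_cont = cont_col is not None
    if not has_cont:
        ll = 0.0
        n_cells = 0
        cell_params = {}
        for label in cells.unique():
            v = y[(cells == label).to_numpy()]
            if len(v) < 2:
                raise ValueError(f"node {node}: cell {label} has < 2 observations")
            m, sd = float(v.mean()), float(v.std(ddof=0))
            ll += float(np.sum(stats.norm.logpdf(v, m, sd)))
            cell_params[label] = {"mean": m, "sd": sd}
            n_cells += 1
        return NodeFit(node=node, family="gaussian", parents=parents,
                       loglik=ll, n_params=2 * n_cells,
                       params={"cells": cell_params})

    X = pd.get_dummies(cells, dtype=float).to_numpy()
    x = data[cont_col].to_numpy(dtype=float)
    X = np.column_stack([X, x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = float(np.sqrt(np.mean(resid**2)))
    ll = float(np.sum(stats.norm.logpdf(resid, 0.0, sd)))
    return NodeFit(node=node, family="gaussian", parents=parents,
                   loglik=ll, n_params=len(beta) + 1,
                   params={"coef": beta.tolist(), "sd": sd,
                           "slope": float(beta[-1])})


def _tweedie_fit(node: str, parents: tuple[str, ...], data: pd.DataFrame,
                 value_col: str, cont_col: str | None) -> NodeFit:
    """Tweedie node: log-link factor-cell means (shared phi, xi), plus a
    linear term on the continuous parent when present."""
    y = data[value_col].to_numpy(dtype=float)
    cells = _cell_labels(data, parents)
    X = pd.get_dummies(cells, dtype=float).to_numpy()
    if cont_col is not None:
        X = np.column_stack([X, data[cont_col].to_numpy(dtype=float)])
    fit = fit_tweedie_glm(y, X, add_intercept=False)
    return NodeFit(node=node, family="tweedie", parents=parents,
                   loglik=fit.loglik, n_params=fit.n_params,
                   params=fit.to_dict())


def fit_node(
    node: str,
    parents: tuple[str, ...],
    data: pd.DataFrame,
    sa_col: str = "sa",
    scr_col: str = "scr",
) -> NodeFit:
    """Fit the conditional distribution of one node given its parents.

    ``data`` must carry columns ``ttc_s``, ``offset_m`` and the two indicator
    columns.  Only the 8 observed factor combinations appear in the data;
    untested cells are never imputed.
    """
    if node in FACTORS:
        if parents:
            raise ValueError("factor nodes are roots")
        return _root_fit(node, data)
    if node == "SA":
        cont = scr_col if "SCR" in parents else None
        return _gaussian_fit(node, parents, data, sa_col, cont)
    if node == "SCR":
        cont = sa_col if "SA" in parents else None
        return _tweedie_fit(node, parents, data, scr_col, cont)
    raise ValueError(f"unknown node {node}")


@dataclass
class NetworkScore:
    """Per-node and total BIC of one candidate structure."""

    structure: BNStructure
    node_fits: dict
    node_bics: dict
    total_bic: float
    n: int

    @property
    def total_loglik(self) -> float:
        return sum(f.loglik for f in self.node_fits.values())


def score_network(
    structure: BNStructure,
    data: pd.DataFrame,
    sa_col: str = "sa",
    scr_col: str = "scr",
    _fit_cache: dict | None = None,
) -> NetworkScore:
    """Score one structure: node BICs from the conditional fits, summed."""
    n = len(data)
    cache = _fit_cache if _fit_cache is not None else {}

    def cached_fit(node, parents):
        key = (node, tuple(sorted(parents)))
        if key not in cache:
            try:
                cache[key] = fit_node(node, parents, data, sa_col, scr_col)
            except Exception as exc:  # noqa: BLE001 - annotate the node
                raise RuntimeError(f"fit failed at node {node}: {exc}") from exc
        return cache[key]

    fits = {
        "TTC": cached_fit("TTC", ()),
        "Offset": cached_fit("Offset", ()),
        "SA": cached_fit("SA", structure.sa_parents),
        "SCR": cached_fit("SCR", structure.scr_parents),
    }
    bics = {name: fit.bic(n) for name, fit in fits.items()}
    return NetworkScore(structure=structure, node_fits=fits, node_bics=bics,
                        total_bic=float(sum(bics.values())), n=n)


def score_all_structures(
    data: pd.DataFrame,
    sa_col: str = "sa",
    scr_col: str = "scr",
) -> list[NetworkScore]:
    """Exhaustively score all 48 candidates, sharing node fits across
    structures (each distinct parent set is fitted once)."""
    cache: dict = {}
    return [
        score_network(s, data, sa_col, scr_col, _fit_cache=cache)
        for s in enumerate_structures()
    ]


@dataclass(frozen=True)
class EvidenceGrades:
    """BIC-difference grades of evidence."""

    thresholds: tuple[float, float, float] = (2.0, 6.0, 10.0)
    labels: tuple[str, str, str] = ("positive", "strong", "very strong")

    def __post_init__(self) -> None:
        if not (self.thresholds[0] < self.thresholds[1] < self.thresholds[2]):
            raise ValueError("thresholds must be strictly increasing")

    def grade(self, gap: float) -> str:
        if gap > self.thresholds[2]:
            return self.labels[2]
        if gap > self.thresholds[1]:
            return self.labels[1]
        if gap > self.thresholds[0]:
            return self.labels[0]
        return "indistinguishable"


@dataclass
class RankedReport:
    """Structures in ascending BIC order with graded consecutive gaps."""

    scores: list
    gaps: list
    grades: list
    best: NetworkScore
    indistinguishable: list  # within 2 BIC of the best (including the best)

    def to_frame(self, sa_name: str = "SA", scr_name: str = "SCR") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": [s.structure.label(sa_name, scr_name) for s in self.scores],
                "bic": [s.total_bic for s in self.scores],
                "gap_to_next": self.gaps + [np.nan],
                "grade": self.grades + [""],
            }
        )


def rank_and_select(
    scores: list[NetworkScore],
    grades: EvidenceGrades | None = None,
) -> RankedReport:
    """Rank by total BIC (ties broken by structure serialization for
    determinism) and flag the set indistinguishable from the best."""
    if not scores:
        raise ValueError("no scores to rank")
    grades = grades or EvidenceGrades()
    ordered = sorted(scores, key=lambda s: (s.total_bic, s.structure))
    gaps = [b.total_bic - a.total_bic for a, b in zip(ordered[:-1], ordered[1:])]
    labels = [grades.grade(g) for g in gaps]
    best = ordered[0]
    indist = [s for s in ordered
              if s.total_bic - best.total_bic <= grades.thresholds[0]]
    return RankedReport(scores=ordered, gaps=gaps, grades=labels,
                        best=best, indistinguishable=indist)
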
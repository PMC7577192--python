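"""Inference of the two metabolic networks.

*Physiological network* — undirected, one node per biomarker.  Edges
are Spearman rank correlations that pass a significance gate (two-sided
p < 0.001 under the t approximation); the edge weight is the squared
rho, so weights are positive while the signed rho is retained as an
edge attribute.

*Pathological-states network* — directed, one node per binary state.
For an ordered pair (X, C) the arc weight is the binomial z-score

    epsilon(C|X) = N_x (P(c|x) - P(c)) / sqrt(N_x P(c) (1 - P(c)))

comparing the observed co-occurrence count among the N_x carriers of X
with its expectation under independence.  An arc X -> C is kept when
epsilon exceeds 1.96, the two-sided 95% normal quantile; epsilon is
not symmetric in its arguments, which is what gives the network its
directionality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from metabonet.catalog import VARIABLE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "spearman_matrix",
    "build_physio_network",
    "epsilon_statistic",
    "epsilon_matrix",
    "build_patho_network",
    "write_graphml",
    "write_edgelist_csv",
]


@dataclass
class AssociationMatrix:
    """Pairwise Spearman correlations with p-values and pair counts.

    ``rho`` and ``p_value`` are symmetric DataFrames; ``n_pairs``
    counts pairwise-complete observations per pair.
    """

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def variables(self) -> list[str]:
        return list(self.rho.columns)


def _spearman_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p via the t approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1.0))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho) | (n < 3), np.nan, p)


def spearman_matrix(
    cohort: pd.DataFrame, variables: tuple[str, ...] | None = None
) -> AssociationMatrix:
    """Spearman correlation matrix on pairwise-complete observations.

    Average ranks are used for ties; a constant variable has undefined
    (NaN) correlations with every partner.
    """
    variables = variables or VARIABLE_NAMES
    data = cohort.loc[:, list(variables)]
    rho = data.corr(method="spearman", min_periods=3)
    notna = data.notna().to_numpy()
    n = notna.T.astype(int) @ notna.astype(int)
    n_pairs = pd.DataFrame(n, index=rho.index, columns=rho.columns)
    p = _spearman_p(rho.to_numpy(), n.astype(float))
    np.fill_diagonal(p, 0.0)
    p_value = pd.DataFrame(p, index=rho.index, columns=rho.columns)
    return AssociationMatrix(rho=rho, p_value=p_value, n_pairs=n_pairs)


def build_physio_network(assoc: AssociationMatrix, alpha: float = 0.001) -> nx.Graph:
    """Gate the association matrix into the physiological network.

    Edge (i, j) present iff p_ij < ``alpha``; weight = rho^2, with the
    signed rho kept as the ``rho`` edge attribute.
    """
    g = nx.Graph()
    g.add_nodes_from(assoc.variables)
    cols = assoc.variables
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            p = assoc.p_value.at[a, b]
            r = assoc.rho.at[a, b]
            if np.isfinite(p) and np.isfinite(r) and p < alpha:
                g.add_edge(a, b, weight=float(r) ** 2, rho=float(r))
    return g


def epsilon_statistic(co_count: int, n_x: int, c_count: int, N: int) -> float:
    """Binomial z-score of co-occurrence of state C among carriers of X.

    With P(c) = c_count/N and P(c|x) = co_count/n_x, returns
    ``N_x (P(c|x) - P(c)) / sqrt(N_x P(c) (1 - P(c)))``.  Undefined
    (NaN) when the baseline prevalence P(c) is 0 or 1, or n_x = 0.
    """
    if not 0 < n_x <= N:
        return math.nan
    p_c = c_count / N
    if p_c <= 0.0 or p_c >= 1.0:
        return math.nan
    p_cx = co_count / n_x
    return n_x * (p_cx - p_c) / math.sqrt(n_x * p_c * (1.0 - p_c))


@dataclass
class EpsilonMatrix:
    """Directed epsilon values: row = conditioning state X, column = target C."""

    epsilon: pd.DataFrame
    n_x: pd.Series
    prevalence: pd.Series


def epsilon_matrix(states: pd.DataFrame) -> EpsilonMatrix:
    """Epsilon for every ordered state pair, on complete-pair bases.

    For each (X, C) the statistic is computed over participants with
    both states non-missing; the diagonal is NaN.  States with zero or
    full prevalence on a pair basis yield NaN and are logged.
    """
    names = list(states.columns)
    k = len(names)
    eps = np.full((k, k), np.nan)
    present = states.notna().to_numpy()
    truth = states.fillna(False).to_numpy(dtype=bool)

    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            both = present[:, i] & present[:, j]
            N = int(both.sum())
            if N == 0:
                continue
            x = truth[:, i] & both
            c = truth[:, j] & both
            e = epsilon_statistic(int((x & c).sum()), int(x.sum()), int(c.sum()), N)
            if math.isnan(e):
                logger.info(
                    "epsilon undefined for %s -> %s (degenerate prevalence)",
                    names[i], names[j],
                )
            eps[i, j] = e
    n_x = pd.Series(truth.sum(axis=0), index=names)
    with np.errstate(invalid="ignore"):
        prevalence = pd.Series(
            truth.sum(axis=0) / np.maximum(present.sum(axis=0), 1), index=names
        )
    return EpsilonMatrix(
        epsilon=pd.DataFrame(eps, index=names, columns=names),
        n_x=n_x,
        prevalence=prevalence,
    )


def build_patho_network(states: pd.DataFrame, threshold: float = 1.96) -> nx.DiGraph:
    """Gate the epsilon matrix into the directed pathological network.

    Arc X -> C present iff epsilon(C|X) > ``threshold`` (default the
    two-sided 95% normal quantile); weight = epsilon.
    """
    em = epsilon_matrix(states)
    g = nx.DiGraph()
    g.add_nodes_from(states.columns)
    for x in states.columns:
        for c in states.columns:
            if x == c:
                continue
            e = em.epsilon.at[x, c]
            if np.isfinite(e) and e > threshold:
                g.add_edge(x, c, weight=float(e))
    return g


def write_graphml(g: nx.Graph, path) -> None:
    """Export a network as GraphML."""
    nx.write_graphml(g, path)


def write_edgelist_csv(g: nx.Graph, path) -> None:
    """Export a network as an edge-list CSV (source, target, weight, rho)."""
    rows = [
        {
            "source": u,
            "target": v,
            "weight": d.get("weight", 1.0),
            "rho": d.get("rho", ""),
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "rho"]).to_csv(
        path, index=False
    )
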
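"""Mass flow graphs and PageRank reaction centrality.

A mass flow graph (MFG) is a weighted directed graph derived from one
steady-state flux vector: nodes are unidirectional reactions (reversible
reactions are split into ``_fwd``/``_rev`` copies carrying nonnegative
flux) and an edge runs from a producer to a consumer of a metabolite,
weighted by the mass flow routed between them.  With p_i(m) the
production rate of metabolite m by node i and c_j(m) the consumption by
node j, the edge weight is

    w(i -> j) = sum_m p_i(m) * c_j(m) / P(m),      P(m) = sum_i p_i(m),

i.e. each producer's output of m is split over consumers proportionally
to their consumption.  Per metabolite and producer, outgoing flows sum
to that producer's production — a conservation property checked in the
test suite.  Reactions are then ranked by weighted PageRank centrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import MetabolicModel, ModelError
from .sampling import FluxSampleSet

__all__ = ["MassFlowGraph", "CentralityRecord", "split_reversible", "build_mfg",
           "pagerank_centrality", "centrality_over_samples"]


@dataclass
class MassFlowGraph:
    """Directed reaction-to-reaction graph for one flux vector."""

    graph: nx.DiGraph
    source_id: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class CentralityRecord:
    node: str
    pagerank: float
    damping: float = 0.85


def split_reversible(model: MetabolicModel, flux_vector: dict[str, float],
                     tol: float = 1e-9) -> dict[str, tuple[str, float]]:
    """Map signed fluxes onto unidirectional nodes.

    Returns reaction id -> (node id, nonnegative flux); zero fluxes (to
    ``tol``) are dropped.  Irreversible-forward reactions keep a
    ``_fwd`` suffix only when the model marks them reversible, so node
    ids are stable across flux vectors.
    """
    out: dict[str, tuple[str, float]] = {}
    for rid, v in flux_vector.items():
        if abs(v) <= tol or not model.has_reaction(rid):
            continue
        rxn = model.reaction(rid)
        if rxn.reversible:
            node = f"{rid}_fwd" if v > 0 else f"{rid}_rev"
        else:
            node = rid
        out[rid] = (node, abs(v))
    return out


def build_mfg(model: MetabolicModel, flux_vector: dict[str, float],
              source_id: str = "", tol: float = 1e-9,
              exclude_metabolites: set[str] | None = None) -> MassFlowGraph:
    """Build the mass flow graph of one steady-state flux vector.

    All metabolites participate by default (currency pools included);
    ``exclude_metabolites`` can drop e.g. protons or water from the flow
    accounting.  Metabolites whose total production is below ``tol`` are
    skipped (sampled vectors carry numerical noise).
    """
    exclude = exclude_metabolites or set()
    nodes = split_reversible(model, flux_vector, tol)
    graph = nx.DiGraph()
    production: dict[str, dict[str, float]] = {}  # met -> node -> rate
    consumption: dict[str, dict[str, float]] = {}
    for rid, (node, v) in nodes.items():
        graph.add_node(node)
        rxn = model.reaction(rid)
        sign = 1.0 if flux_vector[rid] > 0 else -1.0
        for mid, coeff in rxn.stoichiometry.items():
            if mid in exclude:
                continue
            rate = coeff * sign * v
            if rate > tol:
                production.setdefault(mid, {})[node] = production.get(mid, {}).get(node, 0.0) + rate
            elif rate < -tol:
                consumption.setdefault(mid, {})[node] = consumption.get(mid, {}).get(node, 0.0) - rate
    for mid, producers in production.items():
        total = sum(producers.values())
        if total <= tol:
            continue
        consumers = consumption.get(mid, {})
        for i, p in producers.items():
            if p < -tol:
                raise ModelError(f"negative production of {mid} by {i}")  # pragma: no cover
            for j, c in consumers.items():
                w = p * c / total
                if w > 0:
                    graph.add_edge(i, j, weight=graph.get_edge_data(i, j, {"weight": 0.0})["weight"] + w)
    return MassFlowGraph(graph, source_id)


def pagerank_centrality(mfg: MassFlowGraph, damping: float = 0.85,
                        tol: float = 1e-10, max_iter: int = 10000) -> list[CentralityRecord]:
    """Weighted PageRank by power iteration.

    Dangling nodes redistribute uniformly; convergence is declared when
    the L1 change drops below ``tol``.  Scores sum to 1 and are sorted
    descending.
    """
    g = mfg.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ModelError("PageRank on an empty graph")
    index = {u: i for i, u in enumerate(nodes)}
    # column-stochastic transition matrix over out-edge weights
    M = np.zeros((n, n))
    dangling = np.zeros(n, bool)
    for u in nodes:
        out = g.out_edges(u, data=True)
        total = sum(d["weight"] for _, _, d in out)
        if total <= 0:
            dangling[index[u]] = True
            continue
        for _, v, d in out:
            M[index[v], index[u]] = d["weight"] / total
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum()
        new = damping * (M @ p + dangling_mass / n) + (1.0 - damping) / n
        if np.abs(new - p).sum() < tol:
            p = new
            break
        p = new
    else:
        raise ModelError(
            f"PageRank did not converge in {max_iter} iterations "
            f"(residual {np.abs(new - p).sum():.2e})"
        )
    records = [CentralityRecord(u, float(p[index[u]]), damping) for u in nodes]
    records.sort(key=lambda r: r.pagerank, reverse=True)
    return records


def centrality_over_samples(
    model: MetabolicModel,
    sample_set: FluxSampleSet,
    top_k: int = 17,
    damping: float = 0.85,
    exclude_metabolites: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """One MFG + PageRank per sampled flux vector.

    Returns (scores, top_nodes): ``scores`` has one row per sample and
    one column per node ever observed (score 0 when the node carried no
    flux in that sample), and ``top_nodes`` are the ``top_k`` nodes by
    median score.  Per-row failures are recorded as all-NaN rows rather
    than aborting the scan.
    """
    rows: list[dict[str, float]] = []
    for i in range(sample_set.n_samples):
        flux = dict(zip(sample_set.reaction_ids, sample_set.samples[i]))
        try:
            mfg = build_mfg(model, flux, source_id=f"sample_{i}",
                            exclude_metabolites=exclude_metabolites)
            if mfg.graph.number_of_nodes() == 0:
                rows.append({})
                continue
            rows.append({r.node: r.pagerank
                         for r in pagerank_centrality(mfg, damping=damping)})
        except ModelError:
            rows.append({"__failed__": np.nan})
    scores = pd.DataFrame(rows).drop(columns="__failed__", errors="ignore").fillna(0.0)
    medians = scores.median(axis=0).sort_values(ascending=False)
    return scores, medians.index[:top_k].tolist()
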
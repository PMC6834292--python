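"""Collection-level analysis: run the estimator over many pathways and
summarize gene-level evidence across them.

Three per-gene indices pool the per-graph source sets:

* ``relevance`` -- fraction of *all* input graphs whose estimated source set
  contains the gene;
* ``primary_impact`` -- same numerator, but relative to the number of graphs
  in which the gene is annotated;
* ``score`` -- ``-log10`` of the Fisher combination of the per-hypothesis
  permutation p-values of every distinct component (across all graphs) whose
  clique contains the gene; 0 means no significance anywhere.
"""

from __future__ import annotations

import logging
import zlib

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph_engine import PathwayGraph, _key
from .llr_testing import TwoSampleData
from .source_estimator import SourceSetResult, estimate_source_set

logger = logging.getLogger("sourceset")


def _graph_seed(seed: int, graph_id: str) -> int:
    """Stable per-graph seed independent of collection order."""
    return (int(seed) ^ zlib.crc32(graph_id.encode())) % (2**31)


def run_collection(
    data: TwoSampleData,
    graphs: dict[str, PathwayGraph],
    **config,
) -> list[SourceSetResult]:
    """Independent per-graph runs sharing one seed stream.

    Per-graph seeds are derived from the run seed and the graph ID, so the
    output is identical in any order of graphs.  Failing graphs (e.g. no
    overlap with the data) are excluded with a logged warning; an error is
    raised only if every graph fails.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    seed = config.pop("seed", 0)
    results: list[SourceSetResult] = []
    excluded: list[str] = []
    for gid in sorted(graphs, key=_key):
        try:
            results.append(
                estimate_source_set(
                    data, graphs[gid], seed=_graph_seed(seed, gid),
                    graph_id=gid, **config,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-graph isolation
            excluded.append(gid)
            logger.warning("graph %s excluded: %s", gid, exc)
    if excluded:
        logger.warning("%d of %d graphs excluded from the collection",
                       len(excluded), len(graphs))
    if not results:
        raise RuntimeError("all graphs failed; nothing to report")
    return results


def summarize_genes(results: list[SourceSetResult],
                    n_input: int | None = None) -> pd.DataFrame:
    """Per-gene summary table across the analyzed graphs.

    Columns: gene, n_primary, n_secondary, n_graph, score, relevance,
    primary_impact.  ``n_input`` defaults to the number of results and is the
    relevance denominator (total number of input graphs).
    """
    if not results:
        raise ValueError("results must be non-empty")
    if n_input is None:
        n_input = len(results)
    genes: dict = {}
    for res in results:
        for g in res.graph.nodes:
            rec = genes.setdefault(
                g, {"n_primary": 0, "n_secondary": 0, "n_graph": 0, "logps": []}
            )
            rec["n_graph"] += 1
            if g in res.primary:
                rec["n_primary"] += 1
            elif g in res.secondary:
                rec["n_secondary"] += 1
        for t in res.component_table:
            for g in t.clique:
                genes[g]["logps"].append(np.log(t.p_permutation))
    rows = []
    for g in sorted(genes, key=_key):
        rec = genes[g]
        chi = -2.0 * float(np.sum(rec["logps"]))
        p_comb = float(stats.chi2.sf(chi, 2 * len(rec["logps"])))
        score = -np.log10(max(p_comb, np.finfo(float).tiny))
        rows.append(
            {
                "gene": g,
                "n_primary": rec["n_primary"],
                "n_secondary": rec["n_secondary"],
                "n_graph": rec["n_graph"],
                "score": float(score),
                "relevance": rec["n_primary"] / n_input,
                "primary_impact": (rec["n_primary"] / rec["n_graph"]
                                   if rec["n_graph"] else 0.0),
            }
        )
    return pd.DataFrame(rows)


def export_matrix(results: list[SourceSetResult]) -> pd.DataFrame:
    """Genes x graphs matrix coded 2 = primary, 1 = secondary, 0 = annotated
    only, NaN = gene absent from the graph; rows restricted to genes in at
    least one source or secondary set."""
    if not results:
        raise ValueError("results must be non-empty")
    keep = sorted(
        set().union(*(res.primary | res.secondary for res in results)),
        key=_key,
    )
    cols = {}
    for res in results:
        col = {}
        for g in keep:
            if g not in res.graph.nodes:
                col[g] = np.nan
            elif g in res.primary:
                col[g] = 2.0
            elif g in res.secondary:
                col[g] = 1.0
            else:
                col[g] = 0.0
        cols[res.graph_id] = col
    return pd.DataFrame(cols, index=keep)


def export_union_graph(results: list[SourceSetResult],
                       n_input: int | None = None) -> nx.Graph:
    """Undirected union of the subgraphs induced by each primary set.

    Nodes carry ``n_primary``, ``relevance`` and ``score``; each edge carries
    the number of analyzed graphs supporting it.
    """
    if not results:
        raise ValueError("results must be non-empty")
    union = nx.Graph()
    for res in results:
        sub_nodes = res.primary
        union.add_nodes_from(sub_nodes)
        for e in res.graph.edges:
            u, v = sorted(e, key=_key)
            if u in sub_nodes and v in sub_nodes:
                if union.has_edge(u, v):
                    union[u][v]["support"] += 1
                else:
                    union.add_edge(u, v, support=1)
    if union.number_of_nodes() == 0:
        logger.warning("all primary sets are empty: union graph is empty")
        return union
    summary = summarize_genes(results, n_input).set_index("gene")
    for node in union.nodes:
        rec = summary.loc[node]
        union.nodes[node]["n_primary"] = int(rec["n_primary"])
        union.nodes[node]["relevance"] = float(rec["relevance"])
        union.nodes[node]["score"] = float(rec["score"])
    return union
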
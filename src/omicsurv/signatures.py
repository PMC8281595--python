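"""Molecular signatures of the worst-survival subtype and consensus networks.

Three downstream interpretation steps:

* :func:`differential_features` — per omic feature, a two-sided Wilcoxon
  rank-sum test of the worst-survival subtype against all other samples;
  features passing the significance threshold (default p < 0.001) are kept
  with their direction (over/under) and a per-feature univariate Cox p.
* :func:`pan_dataset_rank` — within each dataset, retained features are
  ranked by -log10 Cox p and min-max normalized to [0, 1] (1 = most
  survival-associated); a feature's final score is the sum of its
  normalized ranks across datasets, so recurrently prognostic features
  float to the top.
* :func:`build_coexpression_network` / :func:`consensus_network` — a
  co-expression graph over the top differential genes (edge weight =
  |Spearman correlation|, normalized by the network maximum; Pearson behind
  a flag), summed across datasets into a consensus graph that is trimmed to
  the top nodes, pruned to each node's heaviest edges, and decomposed into
  communities with the walktrap (random-walk) algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy.stats import rankdata, ranksums

from .data_model import OmicsMatrix, SurvivalTable
from .errors import OmicsurvError
from .subtyping import SubtypeLabeling
from .survival_stats import CoxPrep, fit_univariate_coxph

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_TOP_GENES = 1000
DEFAULT_TOP_NODES = 200
DEFAULT_MAX_EDGES = 10


@dataclass
class DifferentialFeature:
    feature_id: str
    direction: str  # "over" | "under" in the worst-survival subtype
    wilcoxon_p: float
    cox_p: float = np.nan


@dataclass
class DifferentialFeatureSet:
    omic_tag: str
    features: list[DifferentialFeature]
    p_threshold: float

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]


@dataclass
class CoexpressionGraph:
    """Undirected weighted graph over features; weights normalized to [0, 1]."""

    nodes: dict[str, float]  # feature id -> node score
    edges: list[tuple[str, str, float]]  # (u, v, weight), u < v, no self-loops
    communities: dict[str, int] | None = None


def differential_features(
    layer: OmicsMatrix,
    labeling: SubtypeLabeling | np.ndarray,
    survival: SurvivalTable | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> DifferentialFeatureSet:
    """Features over/under-expressed in the worst-survival subtype (label 0)
    versus everyone else, two-sided Wilcoxon rank-sum, p < threshold."""
    labels = (
        labeling.ordered_labels
        if isinstance(labeling, SubtypeLabeling)
        else np.asarray(labeling)
    )
    worst = labels == 0
    if worst.sum() < 3 or (~worst).sum() < 3:
        raise OmicsurvError("each comparison group needs >= 3 samples")
    prep = CoxPrep(survival) if survival is not None else None
    out = []
    for i, fid in enumerate(layer.feature_ids):
        row = layer.values[i]
        a, b = row[worst], row[~worst]
        p = float(ranksums(a, b).pvalue)
        if p >= p_threshold:
            continue
        direction = "over" if np.median(a) > np.median(b) else "under"
        cox_p = np.nan
        if prep is not None:
            cox_p = fit_univariate_coxph(row, survival, prep=prep).p_value
        out.append(DifferentialFeature(fid, direction, p, cox_p))
    return DifferentialFeatureSet(layer.omic_tag, out, p_threshold)


def pan_dataset_rank(
    per_dataset: dict[str, DifferentialFeatureSet],
) -> dict[str, float]:
    """Sum of per-dataset normalized Cox ranks; absent features contribute 0.

    Within a dataset, retained features get min-max normalized -log10(Cox p)
    in [0, 1]; a dataset with a single retained feature assigns it rank 1.
    """
    if not per_dataset:
        raise ValueError("at least one dataset required")
    scores: dict[str, float] = {}
    for name, de in per_dataset.items():
        feats = [f for f in de.features if np.isfinite(f.cox_p)]
        if not feats:
            continue
        neglog = np.array([-np.log10(max(f.cox_p, 1e-300)) for f in feats])
        span = neglog.max() - neglog.min()
        if span == 0:
            normalized = np.ones(len(feats))
        else:
            normalized = (neglog - neglog.min()) / span
        for f, r in zip(feats, normalized):
            scores[f.feature_id] = scores.get(f.feature_id, 0.0) + float(r)
    return scores


def build_coexpression_network(
    layer: OmicsMatrix,
    de: DifferentialFeatureSet,
    top_n: int = DEFAULT_TOP_GENES,
    method: str = "spearman",
) -> CoexpressionGraph:
    """Co-expression graph over the ``top_n`` most differential genes.

    Edge weight = |correlation| across samples, normalized by the network
    maximum; node score = sum of incident weights. Constant genes (undefined
    correlation) are dropped with a warning.
    """
    ranked = sorted(de.features, key=lambda f: (f.wilcoxon_p, f.feature_id))
    wanted = [f.feature_id for f in ranked[:top_n]]
    pos = {f: i for i, f in enumerate(layer.feature_ids)}
    idx, names = [], []
    for fid in wanted:
        if fid not in pos:
            continue
        if np.ptp(layer.values[pos[fid]]) == 0:
            logger.warning("dropping constant gene %s from network", fid)
            continue
        idx.append(pos[fid])
        names.append(fid)
    if len(names) < 2:
        raise OmicsurvError("need >= 2 variable retained genes for a network")
    values = layer.values[idx, :]
    if method == "spearman":
        values = rankdata(values, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method '{method}'")
    corr = np.abs(np.corrcoef(values))
    np.fill_diagonal(corr, 0.0)
    max_w = corr.max()
    if max_w == 0:
        raise OmicsurvError("all genes uncorrelated; empty network")
    corr /= max_w
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if corr[i, j] > 0:
                edges.append((names[i], names[j], float(corr[i, j])))
    nodes = {name: float(corr[i].sum()) for i, name in enumerate(names)}
    return CoexpressionGraph(nodes=nodes, edges=edges)


def _prune_edges(
    edges: list[tuple[str, str, float]], max_edges_per_node: int
) -> list[tuple[str, str, float]]:
    """Keep an edge iff it ranks within the ``max_edges_per_node`` heaviest
    incident edges of at least one endpoint (deterministic tie-break by
    weight then edge name)."""
    incident: dict[str, list[tuple[float, tuple[str, str, float]]]] = {}
    for e in edges:
        u, v, w = e
        incident.setdefault(u, []).append((w, e))
        incident.setdefault(v, []).append((w, e))
    keep = set()
    for node, lst in incident.items():
        lst.sort(key=lambda t: (-t[0], t[1][0], t[1][1]))
        for _, e in lst[:max_edges_per_node]:
            keep.add(e)
    return [e for e in edges if e in keep]


def detect_communities(graph: CoexpressionGraph) -> dict[str, int]:
    """Walktrap (short random walks) community membership per node."""
    names = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(names)}
    g = igraph.Graph(
        n=len(names),
        edges=[(index[u], index[v]) for u, v, _ in graph.edges],
    )
    weights = [w for _, _, w in graph.edges]
    clustering = g.community_walktrap(weights=weights or None).as_clustering()
    return {names[i]: int(c) for i, c in enumerate(clustering.membership)}


def consensus_network(
    graphs: list[CoexpressionGraph],
    top_nodes: int = DEFAULT_TOP_NODES,
    max_edges_per_node: int = DEFAULT_MAX_EDGES,
) -> CoexpressionGraph:
    """Sum node and edge weights across networks, keep the ``top_nodes``
    heaviest nodes, prune each node to its heaviest edges, and detect
    walktrap communities on the result."""
    if not graphs:
        raise ValueError("at least one input graph required")
    node_w: dict[str, float] = {}
    edge_w: dict[tuple[str, str], float] = {}
    for g in graphs:
        for n, w in g.nodes.items():
            node_w[n] = node_w.get(n, 0.0) + w
        for u, v, w in g.edges:
            key = (u, v) if u < v else (v, u)
            edge_w[key] = edge_w.get(key, 0.0) + w
    if not node_w:
        raise OmicsurvError("empty consensus graph")
    kept_nodes = set(
        sorted(node_w, key=lambda n: (-node_w[n], n))[:top_nodes]
    )
    edges = [
        (u, v, w)
        for (u, v), w in sorted(edge_w.items())
        if u in kept_nodes and v in kept_nodes
    ]
    edges = _prune_edges(edges, max_edges_per_node)
    result = CoexpressionGraph(
        nodes={n: node_w[n] for n in sorted(kept_nodes)}, edges=edges
    )
    result.communities = detect_communities(result)
    return result


def write_edge_list(graph: CoexpressionGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in graph.edges:
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


def write_communities(graph: CoexpressionGraph, path) -> None:
    if graph.communities is None:
        raise ValueError("graph has no community assignment")
    with open(path, "w") as fh:
        fh.write("feature\tcommunity\n")
        for n in sorted(graph.communities):
            fh.write(f"{n}\t{graph.communities[n]}\n")


def write_scores(scores: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tscore\n")
        for n, s in sorted(scores.items(), key=lambda t: (-t[1], t[0])):
            fh.write(f"{n}\t{s:.6g}\n")
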
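"""Inter-omics Spearman correlation networks and walktrap modules.

Nodes are significant features from one or two omics layers; edges join
feature pairs whose Spearman correlation across shared samples reaches
the threshold (default |rho| >= 0.8), positive and negative alike.
Because Spearman correlation depends only on ranks, the edge set is
invariant under strictly monotone per-feature transforms. Connected
components ("subnetworks") are labelled by size rank; random-walk
(walktrap) community detection partitions each component into modules,
whose per-sample levels are the mean of their member features and whose
class predictability reuses the PLS-DA Q^2 engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import AnalysisConfig, OmicsMatrix
from .pattern_predictor import plsda_q2


@dataclass
class OmicsNetwork:
    graph: ig.Graph
    nodes: pd.DataFrame   # feature_id, layer, subnetwork, module
    edges: pd.DataFrame   # source, target, rho, sign


def build_network(matrix_a: OmicsMatrix, matrix_b: OmicsMatrix | None = None,
                  config: AnalysisConfig | None = None) -> OmicsNetwork:
    """All within- and cross-layer feature pairs with |rho| >= the threshold.

    The two matrices must share a sample set (intersection is used; fewer
    than 4 shared samples is an error since rank correlations are
    unstable there). Components are numbered 1, 2, ... by decreasing size.
    """
    config = config or AnalysisConfig()
    mats = [matrix_a] + ([matrix_b] if matrix_b is not None else [])
    shared = set(mats[0].sample_ids)
    for m in mats[1:]:
        shared &= set(m.sample_ids)
    shared = [s for s in mats[0].sample_ids if s in shared]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples for rank correlations")
    blocks, layers, names = [], [], []
    for m in mats:
        blocks.append(m.values[shared].to_numpy(float))
        layers += [m.layer_tag] * len(m.feature_ids)
        names += m.feature_ids
    X = np.vstack(blocks)
    if len(set(names)) != len(names):
        raise ValueError("feature ids collide across layers")
    rho = stats.spearmanr(X, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    iu = np.triu_indices(len(names), k=1)
    mask = np.abs(rho[iu]) >= config.network_rho
    src, dst = iu[0][mask], iu[1][mask]
    edges = pd.DataFrame({
        "source": [names[i] for i in src],
        "target": [names[j] for j in dst],
        "rho": rho[src, dst],
    })
    edges["sign"] = np.where(edges["rho"] >= 0, "+", "-")
    g = ig.Graph(n=len(names), edges=list(zip(src, dst)))
    g.vs["name"] = names
    g.vs["layer"] = layers
    g.es["rho"] = list(edges["rho"])
    comps = g.connected_components()
    order = np.argsort([-len(c) for c in comps], kind="stable")
    sub_id = np.empty(len(names), int)
    for rank, ci in enumerate(order, start=1):
        for v in comps[int(ci)]:
            sub_id[v] = rank
    g.vs["subnetwork"] = [int(s) for s in sub_id]
    nodes = pd.DataFrame({"feature_id": names, "layer": layers,
                          "subnetwork": sub_id,
                          "module": pd.array([None] * len(names))})
    return OmicsNetwork(graph=g, nodes=nodes.set_index("feature_id"), edges=edges)


def detect_modules(network: OmicsNetwork, config: AnalysisConfig | None = None,
                   steps: int = 4, n_permutations: int = 1000,
                   ) -> pd.DataFrame:
    """Walktrap module detection per subnetwork, with permutation scoring.

    Modules are numbered ``<subnetwork>.<k>``. Each module with >= 3 nodes
    receives a significance p-value from permuting the module labels of
    its subnetwork's nodes and comparing the observed within-module edge
    density to the permuted one (1 + exceed)/(1 + n) rule; singletons and
    tiny components are left unscored. Module assignments are written into
    ``network.nodes``; the returned table has per-module size and p.
    """
    config = config or AnalysisConfig()
    rng = config.rng()
    g = network.graph
    rows = []
    for sub in sorted(set(g.vs["subnetwork"])):
        vs = [v.index for v in g.vs if v["subnetwork"] == sub]
        sg = g.subgraph(vs)
        if sg.vcount() >= 3 and sg.ecount() > 0:
            clustering = sg.community_walktrap(steps=steps).as_clustering()
            membership = np.array(clustering.membership)
        else:
            membership = np.zeros(sg.vcount(), int)
        adj = np.array(sg.get_adjacency().data, dtype=bool)
        for k in sorted(set(membership)):
            module_id = f"{sub}.{k + 1}"
            members = np.where(membership == k)[0]
            for m in members:
                network.nodes.loc[sg.vs[int(m)]["name"], "module"] = module_id
            p = np.nan
            if len(members) >= 3 and sg.vcount() > len(members):
                obs = _within_density(adj, membership == k)
                exceed = 0
                lab = membership == k
                for _ in range(n_permutations):
                    if _within_density(adj, rng.permutation(lab)) >= obs:
                        exceed += 1
                p = (1 + exceed) / (1 + n_permutations)
            rows.append({"module": module_id, "subnetwork": sub,
                         "size": int(len(members)), "p": p})
    return pd.DataFrame(rows).set_index("module")


def _within_density(adj: np.ndarray, mask: np.ndarray) -> float:
    k = int(mask.sum())
    if k < 2:
        return 0.0
    within = adj[np.ix_(mask, mask)].sum() / 2
    return within / (k * (k - 1) / 2)


def module_levels(network: OmicsNetwork, matrix: OmicsMatrix,
                  module_id: str) -> pd.Series:
    """Per-sample module level: arithmetic mean of member-node values."""
    members = list(network.nodes.index[network.nodes["module"] == module_id])
    if not members:
        raise ValueError(f"module {module_id!r} is empty or unknown")
    present = [m for m in members if m in set(matrix.feature_ids)]
    if not present:
        raise ValueError(f"module {module_id!r} has no nodes in the matrix")
    return matrix.values.loc[present].mean(axis=0)


def module_predictability(network: OmicsNetwork, matrix: OmicsMatrix,
                          class_labels: pd.Series,
                          config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-module PLS-DA Q^2 for a sample classification, ranked.

    ``class_labels`` is indexed by sample id. Modules with fewer than two
    features present in the matrix are skipped.
    """
    config = config or AnalysisConfig()
    samples = [s for s in matrix.sample_ids if s in set(class_labels.index)]
    labels = class_labels.loc[samples]
    rows = []
    for module_id in network.nodes["module"].dropna().unique():
        members = list(network.nodes.index[network.nodes["module"] == module_id])
        present = [m for m in members if m in set(matrix.feature_ids)]
        if len(present) < 2:
            continue
        X = matrix.values.loc[present, samples].T
        res = plsda_q2(X, labels, config)
        rows.append({"module": module_id, "n_features": len(present),
                     "q2": res.q2, "n_components": res.q2_n_components})
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("q2", ascending=False).reset_index(drop=True)
    return out
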
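"""Array-level interaction graphs of chromatin condensates.

Condensates are abstracted to graphs whose nodes are array molecules and
whose edges carry the number (``weight_count``) and summed class-weighted
energy (``weight_energy``) of inter-array nucleosome contacts.  The main
observables are the normalised algebraic connectivity (second-smallest
Laplacian eigenvalue relative to a deterministic k-regular reference)
and the digestion percolation curve obtained by randomly deleting
nucleosome-level contacts.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .packing import CondensateModel, ContactCensus, contact_census

__all__ = [
    "DEFAULT_CLASS_WEIGHTS",
    "build_interaction_graph",
    "normalized_algebraic_connectivity",
    "graph_summary",
    "digestion_curve",
    "reference_regular_graph",
]

#: relative contact energies: face-to-face stacking is the most
#: favourable packing geometry, followed by face-to-side and side-to-side
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "face-to-face": 3.0,
    "face-to-side": 2.0,
    "side-to-side": 1.0,
}


def build_interaction_graph(
    m: CondensateModel,
    class_weights: Mapping[str, float] | None = None,
    census: ContactCensus | None = None,
) -> nx.Graph:
    """Graph with arrays as nodes and inter-array contact edges.

    An edge (A, B) exists iff at least one inter-array contact links a
    nucleosome of A with one of B; ``weight_count`` is the number of such
    contacts and ``weight_energy`` the sum of their class weights.
    """
    if not m.array_of:
        raise ValueError("build_interaction_graph requires array assignments")
    unassigned = sorted(set(int(p.id) for p in m.poses) - set(m.array_of))
    if unassigned:
        raise ValueError(f"poses without array assignment: {unassigned[:10]}")
    weights = dict(DEFAULT_CLASS_WEIGHTS if class_weights is None else class_weights)
    if census is None:
        census = contact_census(m)
    g = nx.Graph()
    g.add_nodes_from(sorted(set(m.array_of.values()), key=str))
    records = census.records
    inter = records[records["scope"] == "inter-array"]
    for _, rec in inter.iterrows():
        a = m.array_of[int(rec["pose_i"])]
        b = m.array_of[int(rec["pose_j"])]
        w = weights[rec["geometry_class"]]
        if g.has_edge(a, b):
            g[a][b]["weight_count"] += 1
            g[a][b]["weight_energy"] += w
        else:
            g.add_edge(a, b, weight_count=1, weight_energy=w)
    g.graph["class_weights"] = weights
    return g


def reference_regular_graph(n: int, k: int) -> nx.Graph:
    """Deterministic circulant k-regular graph on n nodes.

    Each node is linked to its k//2 nearest ring neighbours on each side;
    an odd k adds the antipodal link (n must then be even — otherwise the
    degree is rounded down to the nearest even value, with a warning).
    """
    if k >= n:
        k = n - 1
    if k < 1:
        return nx.empty_graph(n)
    offsets = list(range(1, k // 2 + 1))
    if k % 2 == 1:
        if n % 2 == 0:
            offsets.append(n // 2)
        else:
            warnings.warn(
                f"odd degree {k} impossible on {n} (odd) nodes; using k = {k - 1}",
                stacklevel=2,
            )
    return nx.circulant_graph(n, offsets)


def _lambda2(g: nx.Graph) -> float:
    if g.number_of_nodes() < 2:
        raise ValueError("algebraic connectivity needs at least 2 nodes")
    lap = nx.laplacian_matrix(g, weight=None).toarray().astype(float)
    eig = np.linalg.eigvalsh(lap)
    return float(max(eig[1], 0.0))


def normalized_algebraic_connectivity(
    g: nx.Graph, reference_degree: int | str = "auto"
) -> float:
    """lambda_2 of the unweighted Laplacian, normalised to [0, 1].

    The reference is the deterministic circulant k-regular graph on the
    same node count, with k the requested degree (``"auto"`` uses the
    maximum degree found in ``g``); 0 means no connections, 1 means the
    graph is as cohesive as the k-regular reference.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    lam2 = _lambda2(g)
    if lam2 == 0.0 and g.number_of_edges() > 0:
        warnings.warn("graph is disconnected: lambda_2 = 0", stacklevel=2)
    if g.number_of_edges() == 0:
        return 0.0
    k = max(dict(g.degree).values()) if reference_degree == "auto" else int(reference_degree)
    ref = reference_regular_graph(n, k)
    lam2_ref = _lambda2(ref)
    if lam2_ref <= 0:
        warnings.warn("reference graph is disconnected; returning unnormalised 0",
                      stacklevel=2)
        return 0.0
    return float(np.clip(lam2 / lam2_ref, 0.0, 1.0))


def graph_summary(g: nx.Graph) -> dict:
    """Mean degree, mean edge weights and the degree distribution."""
    n = g.number_of_nodes()
    degrees = [d for _, d in g.degree]
    dist: dict[int, int] = {}
    for d in degrees:
        dist[d] = dist.get(d, 0) + 1
    counts = [d.get("weight_count", 1) for _, _, d in g.edges(data=True)]
    energies = [d.get("weight_energy", np.nan) for _, _, d in g.edges(data=True)]
    return {
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
        "mean_weight_count": float(np.mean(counts)) if counts else np.nan,
        "mean_weight_energy": float(np.mean(energies)) if energies else np.nan,
        "degree_distribution": dict(sorted(dist.items())),
    }


def digestion_curve(
    m: CondensateModel,
    removal_fractions: Sequence[float],
    replicates: int = 50,
    seed: int = 0,
    census: ContactCensus | None = None,
) -> pd.DataFrame:
    """Largest-component fraction under random contact removal.

    Emulates progressive tail digestion as a reduction of the number of
    potential nucleosome-nucleosome interactions: each nucleosome-level
    inter-array contact is deleted independently with probability p, the
    array graph is rebuilt from the survivors, and the size of the
    largest connected component (as a fraction of all arrays) is
    averaged over replicates.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates to report an SD")
    if not m.array_of:
        raise ValueError("digestion_curve requires array assignments")
    if census is None:
        census = contact_census(m)
    records = census.records
    inter = records[records["scope"] == "inter-array"]
    edges = np.array(
        [
            (m.array_of[int(r["pose_i"])], m.array_of[int(r["pose_j"])])
            for _, r in inter.iterrows()
        ],
        dtype=object,
    )
    nodes = sorted(set(m.array_of.values()), key=str)
    n_nodes = len(nodes)
    rng = np.random.default_rng(seed)
    rows = []
    for p in removal_fractions:
        if not 0.0 <= p <= 1.0:
            raise ValueError("removal fractions must lie in [0, 1]")
        fracs = np.empty(replicates)
        for r in range(replicates):
            keep = rng.random(len(edges)) >= p if len(edges) else np.array([], bool)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges[keep])
            largest = max((len(c) for c in nx.connected_components(g)), default=0)
            fracs[r] = largest / n_nodes
        rows.append(
            {
                "fraction_removed": p,
                "largest_cc_fraction_mean": float(fracs.mean()),
                "largest_cc_fraction_sd": float(fracs.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)
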
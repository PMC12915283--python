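"""Connectome construction, Leiden partitioning and HITS hub/authority analysis.

The network of activated regions is a weighted directed graph whose edge
weights are normalized anatomical connection densities; self-connections
are removed at construction.  Communities are found with the Leiden
algorithm on directed modularity; node roles are scored with HITS (hubs
broadcast to good authorities, authorities receive from good hubs; each
score vector is normalized to sum to 1).  Significance of a region's hub or
authority score is assessed against a node-sampling bootstrap: random
networks of the same size, always containing the target region, are induced
from the full connectivity table, and the observed score is compared with
the bootstrap distribution via a z-score and a one-tailed normal p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EcokitError, InputError


@dataclass
class Connectome:
    """Weighted directed graph over named regions with node annotations."""

    graph: nx.DiGraph
    removed_self_loops: int = 0

    @property
    def regions(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, weight="weight")


def build_network(regions, edges, annotations: dict | None = None) -> Connectome:
    """Build a weighted directed graph from an edge list.

    ``edges`` yields ``(source, target, weight)``.  Self-connections are
    dropped (and counted); isolated regions are retained with degree 0;
    ``annotations`` maps region -> activation class (e.g. ``"OBS-only"``,
    ``"shared"``, ``"other"``) stored as the ``activated_in`` node attribute.
    """
    regions = list(regions)
    known = set(regions)
    annotations = annotations or {}
    g = nx.DiGraph()
    for r in regions:
        g.add_node(r, activated_in=annotations.get(r, "other"))
    removed = 0
    for src, dst, w in edges:
        if src not in known or dst not in known:
            raise InputError(f"edge endpoint outside region list: ({src}, {dst})")
        if w < 0:
            raise InputError(f"negative weight on edge ({src}, {dst})")
        if src == dst:
            removed += 1
            continue
        g.add_edge(src, dst, weight=float(w))
    return Connectome(graph=g, removed_self_loops=removed)


@dataclass
class Partition:
    """A Leiden community assignment and its quality (modularity)."""

    membership: dict  # node -> community id
    quality: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list:
        out: dict = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def partition_leiden(
    connectome: Connectome, resolution: float = 1.0, seed: int = 0
) -> Partition:
    """Leiden community detection (directed modularity, seed-controlled)."""
    g = connectome.graph
    if g.number_of_nodes() == 0:
        raise InputError("cannot partition an empty graph")
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g.edges[u, v]["weight"] for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges, directed=True)
    part = leidenalg.find_partition(
        h,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = {n: int(part.membership[index[n]]) for n in nodes}
    return Partition(membership=membership, quality=float(part.quality()))


def hits_scores(
    connectome: Connectome, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[dict, dict]:
    """Converged HITS hub and authority scores, each normalized to sum to 1."""
    g = connectome.graph
    if g.number_of_edges() == 0:
        raise InputError("HITS undefined on a graph with no edges")
    try:
        hubs, authorities = nx.hits(g, max_iter=max_iter, tol=tol, normalized=True)
    except nx.PowerIterationFailedConvergence as err:
        raise EcokitError(f"HITS did not converge within {max_iter} iterations") from err
    return hubs, authorities


def _hits_matrix(w: np.ndarray, tol: float = 1e-12, max_iter: int = 1000):
    """HITS fixed point on an adjacency matrix (rows: sources), L1-normalized.

    A graph with no edges has zero hub and authority vectors by convention
    (used for degenerate bootstrap subnetworks).
    """
    n = w.shape[0]
    if not w.any():
        return np.zeros(n), np.zeros(n)
    h = np.full(n, 1.0 / n)
    a = np.zeros(n)
    for _ in range(max_iter):
        a_new = w.T @ h
        a_new /= a_new.sum() or 1.0
        h_new = w @ a_new
        h_new /= h_new.sum() or 1.0
        if np.abs(h_new - h).sum() + np.abs(a_new - a).sum() < tol:
            return h_new, a_new
        h, a = h_new, a_new
    return h, a


def _hits_matrix_batch(w: np.ndarray, tol: float = 1e-12, max_iter: int = 1000):
    """Batched HITS on a stack of adjacency matrices; returns the target's
    (column 0) hub and authority scores per matrix.

    Same fixed point and L1 normalization as ``_hits_matrix``; edgeless
    matrices yield zero scores.
    """
    n_iter, k, _ = w.shape
    wt = np.swapaxes(w, 1, 2)
    h = np.full((n_iter, k), 1.0 / k)
    a = np.zeros((n_iter, k))
    live = w.reshape(n_iter, -1).any(axis=1)
    h[~live] = 0.0
    for _ in range(max_iter):
        a_new = np.einsum("nij,nj->ni", wt, h)
        norm = a_new.sum(axis=1, keepdims=True)
        np.divide(a_new, norm, out=a_new, where=norm > 0)
        h_new = np.einsum("nij,nj->ni", w, a_new)
        norm = h_new.sum(axis=1, keepdims=True)
        np.divide(h_new, norm, out=h_new, where=norm > 0)
        delta = np.abs(h_new - h).sum(axis=1) + np.abs(a_new - a).sum(axis=1)
        h, a = h_new, a_new
        if delta.max() < tol:
            break
    return h[:, 0], a[:, 0]


@dataclass
class HITSSignificance:
    """Bootstrap significance of one region's hub and authority scores."""

    region: str
    hub: float
    authority: float
    hub_boot_mean: float
    hub_boot_sd: float
    authority_boot_mean: float
    authority_boot_sd: float
    z_hub: float
    z_authority: float
    p_hub: float
    p_authority: float
    n_iter: int
    sd_degenerate: bool = False


def _one_tailed_p(z: float) -> float:
    from scipy.stats import norm

    return float(norm.sf(z))


def bootstrap_hits(
    target: str,
    pool_regions,
    network_regions,
    edges,
    n_iter: int = 1000,
    seed: int = 0,
    two_tailed: bool = False,
) -> HITSSignificance:
    """Node-sampling bootstrap significance of one region's HITS scores.

    Each of the ``n_iter`` iterations samples a node set of the same size as
    the observed network — always containing ``target`` — from
    ``pool_regions``, induces the subgraph from the full ``edges`` table
    (self-connections removed), and records the target's hub and authority
    scores.  ``z = (observed - bootstrap mean) / bootstrap sd`` and the
    p-value is the upper tail of the standard normal (one-tailed by
    default).  Zero bootstrap sd is reported explicitly, never hidden.
    """
    pool = list(dict.fromkeys(pool_regions))
    observed_set = list(dict.fromkeys(network_regions))
    if target not in observed_set:
        raise InputError("target must belong to the observed network")
    if target not in pool:
        raise InputError("target must belong to the sampling pool")
    if len(pool) <= len(observed_set):
        raise InputError("pool must be strictly larger than the observed network")

    index = {r: i for i, r in enumerate(pool)}
    w_full = np.zeros((len(pool), len(pool)))
    for src, dst, w in edges:
        if src == dst or src not in index or dst not in index:
            continue
        w_full[index[src], index[dst]] = w

    obs_idx = np.array([index[r] for r in observed_set])
    t_local = observed_set.index(target)
    h, a = _hits_matrix(w_full[np.ix_(obs_idx, obs_idx)])
    obs_hub, obs_auth = float(h[t_local]), float(a[t_local])

    rng = np.random.default_rng(seed)
    others = np.array([i for i in range(len(pool)) if i != index[target]])
    k = len(observed_set)
    # sample k-1 companions per iteration without replacement (random keys)
    keys = rng.random((n_iter, others.size))
    sampled = others[np.argpartition(keys, k - 1, axis=1)[:, : k - 1]]
    nodes = np.concatenate(
        (np.full((n_iter, 1), index[target]), sampled), axis=1
    )  # (n_iter, k), target in column 0
    w_boot = w_full[nodes[:, :, None], nodes[:, None, :]]  # (n_iter, k, k)
    boot_h, boot_a = _hits_matrix_batch(w_boot)

    mh, sh = float(boot_h.mean()), float(boot_h.std(ddof=1))
    ma, sa = float(boot_a.mean()), float(boot_a.std(ddof=1))
    degenerate = sh == 0 or sa == 0
    z_h = (obs_hub - mh) / sh if sh > 0 else math.nan
    z_a = (obs_auth - ma) / sa if sa > 0 else math.nan
    p_h = _one_tailed_p(z_h) if sh > 0 else math.nan
    p_a = _one_tailed_p(z_a) if sa > 0 else math.nan
    if two_tailed:
        p_h = min(1.0, 2 * min(p_h, 1 - p_h)) if sh > 0 else math.nan
        p_a = min(1.0, 2 * min(p_a, 1 - p_a)) if sa > 0 else math.nan
    return HITSSignificance(
        region=target,
        hub=obs_hub,
        authority=obs_auth,
        hub_boot_mean=mh,
        hub_boot_sd=sh,
        authority_boot_mean=ma,
        authority_boot_sd=sa,
        z_hub=z_h,
        z_authority=z_a,
        p_hub=p_h,
        p_authority=p_a,
        n_iter=n_iter,
        sd_degenerate=degenerate,
    )


def bootstrap_hits_table(
    network_regions, pool_regions, edges, n_iter: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap significance for every region of the observed network."""
    rng = np.random.default_rng(seed)
    rows = []
    for target in network_regions:
        res = bootstrap_hits(
            target,
            pool_regions,
            network_regions,
            edges,
            n_iter=n_iter,
            seed=int(rng.integers(2**31)),
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)


def top_edge_filter(connectome: Connectome, fraction: float = 0.05) -> list:
    """The ceil(fraction * E) largest-weight edges (display only).

    Ties at the cutoff weight are broken deterministically by the graph's
    edge-iteration order (edges grouped by source node, targets in
    insertion order).
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must lie in (0, 1]")
    edges = [(u, v, d["weight"]) for u, v, d in connectome.graph.edges(data=True)]
    if not edges:
        raise InputError("graph has no edges")
    keep = math.ceil(fraction * len(edges))
    weights = np.array([w for _, _, w in edges])
    order = np.argsort(-weights, kind="stable")[:keep]
    return [edges[i] for i in sorted(order)]
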
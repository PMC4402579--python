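"""Seed-gene network expansion over a protein-protein interaction graph.

Each seed gene is scored by its number of direct connections to other
seeds, and that count is compared with the same statistic under a
topology-conserving null: node labels are permuted within exact-degree
bins (singleton bins merged with the nearest degree class), so every
permuted network keeps the original edge structure and, bin-exactness
permitting, every node's degree.  Permutation p-values use the add-one
estimator and are BH-corrected across seeds; PPI edges incident to a
significant seed form the expansion.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from minet.eqtl import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 1000
DEFAULT_ALPHA = 0.05


def direct_network(seeds: set[str], net: nx.Graph) -> set[frozenset]:
    """All PPI edges whose both endpoints are seed genes."""
    present = set(seeds) & set(net.nodes)
    dropped = len(set(seeds)) - len(present)
    if dropped:
        logger.info("dropped %d seed(s) absent from the PPI universe", dropped)
    return {
        frozenset((a, b)) for a, b in net.edges() if a in present and b in present
    }


def _degree_bins(net: nx.Graph) -> list[list]:
    """Group nodes into label-exchangeable bins.

    Exact-degree bins; a bin with a single node is merged with the bin
    of the nearest degree so no node is trivially fixed (the merged bin
    conserves degree only approximately).
    """
    by_degree: dict[int, list] = {}
    for node, degree in net.degree():
        by_degree.setdefault(degree, []).append(node)
    degrees = sorted(by_degree)
    bins = [list(by_degree[d]) for d in degrees]
    i = 0
    while i < len(bins):
        if len(bins[i]) == 1 and len(bins) > 1:
            # merge with the adjacent bin of nearest degree
            if i == 0:
                j = 1
            elif i == len(bins) - 1:
                j = i - 1
            else:
                below, above = degrees[i] - degrees[i - 1], degrees[i + 1] - degrees[i]
                j = i - 1 if below <= above else i + 1
            bins[min(i, j)].extend(bins[max(i, j)])
            del bins[max(i, j)]
            del degrees[max(i, j)]
        else:
            i += 1
    return bins


def _permutation_mapping(
    bins: list[list], rng: np.random.Generator
) -> dict:
    mapping = {}
    for bin_nodes in bins:
        shuffled = [bin_nodes[i] for i in rng.permutation(len(bin_nodes))]
        mapping.update(zip(bin_nodes, shuffled))
    return mapping


def permute_network(net: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Topology-conserving null draw: relabel nodes within degree bins.

    The edge structure is copied verbatim under a label permutation, so
    the degree sequence is identical and each node keeps its own degree
    exactly whenever its bin holds a single degree class.
    """
    mapping = _permutation_mapping(_degree_bins(net), rng)
    permuted = nx.relabel_nodes(net, mapping, copy=True)
    permuted.add_nodes_from(net.nodes)  # keep isolated nodes in the universe
    return permuted


def score_seeds(
    seeds: set[str],
    net: nx.Graph,
    n_perm: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation significance of per-seed direct connectivity.

    For each seed, ``p_perm = (1 + #{permutations with statistic >=
    observed}) / (1 + n_perm)`` where the statistic is the seed's number
    of direct connections within the permuted seed set; ``p_corrected``
    is BH across seeds.  Seeds absent from the network are dropped.

    Returns columns: gene_id, direct_connections, p_perm, p_corrected.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    seed_list = sorted(set(seeds) & set(net.nodes))
    dropped = len(set(seeds)) - len(seed_list)
    if dropped:
        logger.info("dropped %d seed(s) absent from the PPI universe", dropped)
    if not seed_list:
        return pd.DataFrame(
            columns=["gene_id", "direct_connections", "p_perm", "p_corrected"]
        )

    adjacency = {node: set(net[node]) for node in net.nodes}
    seed_set = set(seed_list)
    observed = np.array(
        [len(adjacency[s] & seed_set) for s in seed_list], dtype=int
    )

    bins = _degree_bins(net)
    exceed = np.zeros(len(seed_list), dtype=int)
    for _ in range(n_perm):
        mapping = _permutation_mapping(bins, rng)
        inverse = {v: k for k, v in mapping.items()}
        permuted_seeds = {inverse[s] for s in seed_list}
        stat = np.array(
            [len(adjacency[inverse[s]] & permuted_seeds) for s in seed_list]
        )
        exceed += stat >= observed

    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "gene_id": seed_list,
            "direct_connections": observed,
            "p_perm": p_perm,
            "p_corrected": bh_fdr(p_perm),
        }
    )


def expand(
    seeds: set[str],
    net: nx.Graph,
    scores: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> list[tuple[str, str]]:
    """PPI edges incident to at least one significant seed.

    Edges are ranked by the significance (p_corrected, then p_perm) of
    their most significant incident seed, bringing first-neighbour nodes
    into the network; each undirected edge appears once.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    significant = scores[scores["p_corrected"] <= alpha]
    ranked_seeds = significant.sort_values(
        ["p_corrected", "p_perm", "gene_id"], kind="stable"
    )["gene_id"]
    present = [s for s in ranked_seeds if s in net and s in set(seeds)]
    edges: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    for seed in present:
        for neighbour in sorted(net[seed]):
            key = frozenset((seed, neighbour))
            if key not in seen:
                seen.add(key)
                edges.append((seed, neighbour))
    return edges
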
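"""Independent brute-force oracles for the topology and statistics layers.

Everything here is deliberately naive — exhaustive shortest-path
enumeration via networkx, explicit double loops, materialized Walsh
averages, full permutation enumeration — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def brute_sigma(g: nx.Graph, s, t) -> int:
    """Number of distinct shortest s-t paths by exhaustive enumeration."""
    if s == t:
        return 1
    if not nx.has_path(g, s, t):
        return 0
    return len(list(nx.all_shortest_paths(g, s, t)))


def brute_betweenness_stress(g: nx.Graph):
    """Raw betweenness and stress per node over unordered pairs."""
    betw = {v: 0.0 for v in g}
    stress = {v: 0 for v in g}
    nodes = list(g)
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            if on:
                betw[v] += on / len(paths)
                stress[v] += on
    return betw, stress


def brute_path_indices(g: nx.Graph):
    """ecc, asp, closeness, radiality per node via networkx distances."""
    ecc, asp, clo, rad = {}, {}, {}, {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            v = next(iter(comp))
            ecc[v] = asp[v] = clo[v] = rad[v] = 0.0
            continue
        dists = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            dv = dists[v]
            ecc[v] = float(max(dv.values()))
            asp[v] = float(np.mean([d for u, d in dv.items() if u != v]))
            clo[v] = 1.0 / asp[v]
            rad[v] = (diam + 1.0 - asp[v]) / diam
    return ecc, asp, clo, rad


def brute_local_indices(g: nx.Graph):
    """clustering, neighborhood connectivity, topological coefficient."""
    clus, nc, tc = {}, {}, {}
    for v in g:
        nbrs = set(g[v])
        k = len(nbrs)
        nc[v] = float(np.mean([g.degree(u) for u in nbrs])) if nbrs else 0.0
        if k < 2:
            clus[v] = 0.0
        else:
            e = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
            clus[v] = 2.0 * e / (k * (k - 1))
        if k < 2:
            tc[v] = 0.0
            continue
        js = []
        for m in g:
            if m == v:
                continue
            shared = len(nbrs & set(g[m]))
            if shared == 0:
                continue
            js.append((shared + (1 if g.has_edge(v, m) else 0)) / k)
        tc[v] = float(np.mean(js)) if js else 0.0
    return clus, nc, tc


def brute_pseudomedian(x) -> float:
    x = np.asarray(x, dtype=float)
    ws = [(x[i] + x[j]) / 2.0 for i in range(len(x)) for j in range(i, len(x))]
    return float(np.median(ws))


def permanova_f(D: np.ndarray, labels) -> float:
    """Pseudo-F from the squared-dissimilarity partition, written plainly."""
    labels = np.asarray(labels)
    N = len(labels)
    groups = list(dict.fromkeys(labels.tolist()))
    a = len(groups)
    D2 = D**2
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for glab in groups:
        idx = np.flatnonzero(labels == glab)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (N - a))


def brute_permanova_p(D: np.ndarray, labels) -> float:
    """Exact permutation p by enumerating every relabeling (N <= 8)."""
    labels = list(labels)
    f_obs = permanova_f(D, labels)
    hits = total = 0
    for perm in itertools.permutations(range(len(labels))):
        lab = [labels[i] for i in perm]
        total += 1
        if permanova_f(D, lab) >= f_obs - 1e-12:
            hits += 1
    return hits / total
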
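"""Network and gene-group input/output.

Reads undirected protein-protein interaction (PPI) networks from SIF or
two-column TSV edge lists, reads seed gene lists and gene-group tables,
and constructs the analysis network by expanding a seed list to its
primary and secondary interaction neighbors.

Networks are held as :class:`networkx.Graph` objects whose nodes are
protein/gene identifier strings. Simple-graph semantics are enforced on
read: self-loops and duplicate edges are dropped (with counts logged),
never raised as errors, because public PPI exports routinely contain
both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GeneGroup",
    "NetworkParseError",
    "read_network",
    "write_network",
    "read_seed_list",
    "expand_seed_neighborhood",
    "read_groups",
    "write_groups",
    "assign_groups",
]

log = logging.getLogger(__name__)

NONENRICHED_LABEL = "NONENRICHED"


class NetworkParseError(ValueError):
    """Raised for malformed network, seed or group files."""


@dataclass
class GeneGroup:
    """A named set of network nodes (e.g. a treatment-enriched gene set).

    Parameters
    ----------
    label : str
        Group name, e.g. ``"CBZ"`` or ``"NONENRICHED"``.
    members : set of str
        Node identifiers belonging to the group. After mapping onto a
        network, ``members`` is a subset of the network's node set.
    n_unmapped : int
        Number of input identifiers that were absent from the network
        when the group was mapped (kept so silent data loss is visible).
    """

    label: str
    members: set[str] = field(default_factory=set)
    n_unmapped: int = 0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.members)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"sif", "tsv"}:
            raise ValueError(f"unknown network format {fmt!r} (expected 'sif' or 'tsv')")
        return fmt
    return "sif" if path.suffix.lower() == ".sif" else "tsv"


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read an undirected network from a SIF or 2-column TSV edge list.

    SIF lines are ``source <relation> target [target ...]`` (>= 3
    whitespace-separated tokens; one-to-many rows are expanded into one
    edge per target). TSV lines are ``source<TAB>target``. Edge
    direction in the file is ignored. Self-loops and duplicate edges are
    dropped silently (counts logged at INFO level).

    Raises
    ------
    NetworkParseError
        On a line with the wrong token count (the message names the line
        number) or on an empty file.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    net: nx.Graph = nx.Graph()
    n_self, n_dup, n_edges_in = 0, 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if fmt == "sif":
                tokens = line.split()
                if len(tokens) < 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: SIF line has {len(tokens)} token(s), "
                        "expected 'source relation target...'"
                    )
                src, targets = tokens[0], tokens[2:]
            else:
                tokens = [t.strip() for t in line.split("\t")]
                if len(tokens) != 2 or not all(tokens):
                    raise NetworkParseError(
                        f"{path}:{lineno}: TSV edge line must have exactly two "
                        f"tab-separated identifiers, got {line!r}"
                    )
                src, targets = tokens[0], [tokens[1]]
            src = src.strip()
            for tgt in targets:
                tgt = tgt.strip()
                n_edges_in += 1
                if src == tgt:
                    n_self += 1
                    net.add_node(src)
                    continue
                if net.has_edge(src, tgt):
                    n_dup += 1
                    continue
                net.add_edge(src, tgt)
    if net.number_of_nodes() == 0:
        raise NetworkParseError(f"{path}: no interactions found (empty file?)")
    if n_self or n_dup:
        log.info(
            "read_network(%s): dropped %d self-loop(s) and %d duplicate edge(s) "
            "out of %d input rows",
            path, n_self, n_dup, n_edges_in,
        )
    return net


def write_network(net: nx.Graph, path: str | Path, fmt: str | None = None,
                  relation: str = "pp") -> None:
    """Write a network as SIF or 2-column TSV (edges sorted for determinism)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    edges = sorted(tuple(sorted(e)) for e in net.edges())
    isolated = sorted(n for n in net.nodes() if net.degree(n) == 0)
    with open(path, "w") as fh:
        if fmt == "sif":
            for a, b in edges:
                fh.write(f"{a} {relation} {b}\n")
        else:
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        if isolated and fmt == "sif":
            # SIF has no single-node rows under the >=3-token convention
            # used here; isolated nodes are recorded as a comment.
            fh.write("# isolated: " + " ".join(isolated) + "\n")


def read_seed_list(path: str | Path, case_insensitive: bool = False) -> list[str]:
    """Read a seed gene list: one identifier per line, ``#`` comments allowed.

    Returns the identifiers in file order with duplicates removed (the
    first occurrence wins). With ``case_insensitive`` the duplicate check
    is done on upper-cased identifiers.
    """
    seeds: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            ident = raw.split("#", 1)[0].strip()
            if not ident:
                continue
            key = ident.upper() if case_insensitive else ident
            if key in seen:
                continue
            seen.add(key)
            seeds.append(ident)
    if not seeds:
        raise NetworkParseError(f"{path}: no seed identifiers found")
    return seeds


def _match_seeds(net: nx.Graph, seeds: Sequence[str],
                 case_insensitive: bool) -> tuple[list[str], list[str]]:
    """Map seed identifiers onto network nodes; returns (mapped, unmapped)."""
    if case_insensitive:
        lookup: dict[str, str] = {}
        for node in net.nodes():
            lookup.setdefault(node.upper(), node)
        mapped, unmapped = [], []
        for s in seeds:
            node = lookup.get(s.strip().upper())
            (mapped if node is not None else unmapped).append(node or s)
        return mapped, unmapped
    mapped = [s.strip() for s in seeds if s.strip() in net]
    unmapped = [s.strip() for s in seeds if s.strip() not in net]
    return mapped, unmapped


def expand_seed_neighborhood(net: nx.Graph, seeds: Sequence[str], order: int = 2,
                             case_insensitive: bool = False,
                             induced: bool = True) -> nx.Graph:
    """Subnetwork of all nodes within ``order`` hops of any seed.

    ``order=1`` keeps seeds plus primary neighbors, ``order=2`` adds
    secondary neighbors (neighbors of neighbors). By default the
    *induced* subgraph is returned (every edge of the parent network
    between two retained nodes is kept); with ``induced=False`` only
    edges linking consecutive BFS shells (and seed-seed edges) are kept.

    Shell sizes are recorded in ``result.graph["shell_counts"]`` as a
    dict ``{distance: n_nodes}``.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"order must be 0, 1 or 2, got {order}")
    mapped, unmapped = _match_seeds(net, seeds, case_insensitive)
    if not mapped:
        raise ValueError(
            "no seed identifier maps to the network; unmapped seeds: "
            + ", ".join(sorted(unmapped))
        )
    if unmapped:
        log.info("expand_seed_neighborhood: %d seed(s) not in network", len(unmapped))
    # multi-source BFS distance from the seed set
    dist: dict[str, int] = {}
    frontier = list(dict.fromkeys(mapped))
    for s in frontier:
        dist[s] = 0
    d = 0
    while frontier and d < order:
        nxt = []
        for u in frontier:
            for v in net[u]:
                if v not in dist:
                    dist[v] = d + 1
                    nxt.append(v)
        frontier = nxt
        d += 1
    keep = set(dist)
    if induced:
        sub = net.subgraph(keep).copy()
    else:
        sub = nx.Graph()
        sub.add_nodes_from(keep)
        for u, v in net.edges(keep):
            if u in dist and v in dist and abs(dist[u] - dist[v]) == 1:
                sub.add_edge(u, v)
            elif u in dist and v in dist and dist[u] == dist[v] == 0:
                sub.add_edge(u, v)  # seed-seed edges always kept
    shells = {k: sum(1 for v in dist.values() if v == k) for k in range(order + 1)}
    sub.graph["shell_counts"] = shells
    log.info("expand_seed_neighborhood: shell sizes %s", shells)
    return sub


def read_groups(path: str | Path, net: nx.Graph | None = None) -> list[GeneGroup]:
    """Read gene groups from a TSV with columns ``identifier``, ``group_label``.

    A header row with those column names is optional. One
    :class:`GeneGroup` is returned per distinct label, in order of first
    appearance; duplicate (identifier, label) rows collapse to a single
    membership. When ``net`` is given, identifiers absent from the
    network are removed from the member sets and counted in
    ``n_unmapped`` instead of being silently lost.
    """
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = [t.strip() for t in line.split("\t")]
            if len(tokens) != 2 or not all(tokens):
                raise NetworkParseError(
                    f"{path}:{lineno}: group line must be "
                    f"'identifier<TAB>group_label', got {line!r}"
                )
            ident, label = tokens
            if lineno == 1 and (ident.lower(), label.lower()) == ("identifier", "group_label"):
                continue
            groups.setdefault(label, set()).add(ident)
    if not groups:
        raise NetworkParseError(f"{path}: no group assignments found")
    out = []
    for label, members in groups.items():
        n_unmapped = 0
        if net is not None:
            mapped = {m for m in members if m in net}
            n_unmapped = len(members) - len(mapped)
            members = mapped
            if not members:
                log.warning("read_groups: group %s has 0 members after mapping", label)
        out.append(GeneGroup(label=label, members=members, n_unmapped=n_unmapped))
    return out


def write_groups(groups: Iterable[GeneGroup], path: str | Path) -> None:
    """Write groups as an ``identifier<TAB>group_label`` TSV (sorted)."""
    with open(path, "w") as fh:
        fh.write("identifier\tgroup_label\n")
        for g in groups:
            for m in sorted(g.members):
                fh.write(f"{m}\t{g.label}\n")


def assign_groups(groups: Sequence[GeneGroup], net: nx.Graph,
                  exclude_overlap: bool = True) -> tuple[list[GeneGroup], GeneGroup]:
    """Finalize treatment groups on a network and derive the background group.

    Members outside the network are dropped (added to ``n_unmapped``).
    With ``exclude_overlap`` (the default), any node belonging to two or
    more treatment groups is removed from *all* of them, so the groups
    entering any statistical comparison are pairwise disjoint. The second
    return value is the NONENRICHED group: every network node that was in
    no treatment group (excluded overlap nodes belong to neither side).
    """
    mapped: list[GeneGroup] = []
    for g in groups:
        members = {m for m in g.members if m in net}
        mapped.append(GeneGroup(
            label=g.label, members=members,
            n_unmapped=g.n_unmapped + (len(g.members) - len(members)),
        ))
    membership_count: dict[str, int] = {}
    for g in mapped:
        for m in g.members:
            membership_count[m] = membership_count.get(m, 0) + 1
    overlap = {m for m, c in membership_count.items() if c > 1}
    if exclude_overlap and overlap:
        log.info("assign_groups: excluding %d node(s) present in >1 group", len(overlap))
        for g in mapped:
            g.members -= overlap
    ever_grouped = set(membership_count)
    nonenriched = GeneGroup(
        label=NONENRICHED_LABEL,
        members=set(net.nodes()) - ever_grouped,
    )
    return mapped, nonenriched
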
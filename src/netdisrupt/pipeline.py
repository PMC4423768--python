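"""End-to-end analysis pipeline.

Orchestrates: read network (optionally expanding a seed list to its
primary/secondary neighborhood) -> ten-index node table -> univariate
layer (pseudomedian + bootstrap SE per group/index, upper-tailed
Wilcoxon of each group against the background pseudomedian, BDM omnibus
across treatment groups with protected Holm-adjusted pairwise tests) ->
multivariate layer (Steinhaus dissimilarity over the index columns,
PERMANOVA omnibus over treatment groups + non-enriched background,
protected pairwise PERMANOVA, NMDS best-of-n restarts, per-variable
vector fits). All outputs are TSVs plus a markdown report; a fixed seed
makes the whole run byte-reproducible.

Two distinct backgrounds exist on purpose: the Wilcoxon reference is the
*whole network* pseudomedian (a group is asked whether it sits higher
than the network at large), while the multivariate contrast uses the
*non-enriched* nodes as an explicit factor level. Both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, netio, topology, robust_stats, ordination
from .netio import GeneGroup

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize_network"]

log = logging.getLogger(__name__)

DEFAULT_UNIVARIATE = ("degree", "closenessCentrality", "betweennessCentrality", "stress")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    ``background`` controls the Wilcoxon reference location:
    ``whole_network`` (default), ``nonenriched``, or a path to an
    explicit node-list file. ``multivariate_background_size`` optionally
    subsamples the non-enriched nodes entering the PERMANOVA/NMDS layer
    (0 = use all of them).
    """

    network: str = ""
    network_format: str | None = None
    seeds: str | None = None
    groups: str = ""
    expansion_order: int = 2
    univariate_indices: tuple = DEFAULT_UNIVARIATE
    multivariate_indices: tuple = topology.INDEX_COLUMNS
    alpha: float = 0.05
    n_perm: int = 10_000
    bootstrap_B: int = 1000
    nmds_k: int = 2
    nmds_starts: int = 20
    background: str = "whole_network"
    multivariate_background_size: int = 0
    standardize_columns: bool = False
    exclude_overlap: bool = True
    bdm_mode: str = "permutation"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        self.univariate_indices = tuple(self.univariate_indices)
        self.multivariate_indices = tuple(self.multivariate_indices)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    """All results of one run, plus a provenance block."""

    network_summary: dict
    group_sizes: dict
    locations: list = field(default_factory=list)
    univariate_tests: list = field(default_factory=list)
    bdm_omnibus: list = field(default_factory=list)
    bdm_pairwise: list = field(default_factory=list)
    permanova_omnibus: object = None
    permanova_pairwise: list = field(default_factory=list)
    nmds: object = None
    vector_fits: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def summarize_network(net, compute_diameter: bool | None = None) -> dict:
    """Node/edge counts, mean and median degree, components, diameter.

    Diameter (of the largest component) costs one BFS per node, so by
    default it is skipped for networks above 3000 nodes
    (``compute_diameter=None``); pass True/False to force.
    """
    import networkx as nx

    n, e = net.number_of_nodes(), net.number_of_edges()
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    comps = list(nx.connected_components(net))
    if compute_diameter is None:
        compute_diameter = n <= 3000
    diameter = None
    if compute_diameter and comps:
        largest = max(comps, key=len)
        if len(largest) > 1:
            diameter = nx.diameter(net.subgraph(largest))
        else:
            diameter = 0
    return {
        "n_nodes": n,
        "n_edges": e,
        "mean_degree": float(2.0 * e / n) if n else 0.0,
        "median_degree": float(np.median(degrees)) if n else 0.0,
        "n_components": len(comps),
        "diameter_largest_component": diameter,
    }


def _derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage sub-seed below 2^31 (crc32: reproducible across runs)."""
    import zlib

    h = np.random.SeedSequence([seed, zlib.crc32(tag.encode())])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def _background_values(cfg: PipelineConfig, table: pd.DataFrame,
                       nonenriched: GeneGroup, col: str) -> np.ndarray:
    if cfg.background == "whole_network":
        return table[col].to_numpy()
    if cfg.background == "nonenriched":
        return table.loc[sorted(nonenriched.members), col].to_numpy()
    nodes = netio.read_seed_list(cfg.background)
    present = [v for v in nodes if v in table.index]
    if not present:
        raise ValueError(f"background file {cfg.background}: no node maps to the network")
    return table.loc[present, col].to_numpy()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> RunReport:
    """Run the full analysis described by ``cfg``; write outputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: network ---------------------------------------------------
    try:
        net = netio.read_network(cfg.network, cfg.network_format)
        if cfg.seeds:
            seeds = netio.read_seed_list(cfg.seeds)
            net = netio.expand_seed_neighborhood(net, seeds, cfg.expansion_order)
        summary = summarize_network(net)
        log.info("network: %(n_nodes)d nodes, %(n_edges)d edges", summary)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'network': {err}") from err

    # --- stage: groups ----------------------------------------------------
    try:
        raw_groups = netio.read_groups(cfg.groups, net=net)
        groups, nonenriched = netio.assign_groups(raw_groups, net,
                                                  exclude_overlap=cfg.exclude_overlap)
        group_sizes = {g.label: len(g.members) for g in groups}
        group_sizes[nonenriched.label] = len(nonenriched.members)
        log.info("groups: %s", group_sizes)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'groups': {err}") from err

    # --- stage: topology --------------------------------------------------
    try:
        table = topology.compute_index_table(net)
        table = table.sort_index()
        topology.write_index_table(table, outdir / "node_indices.tsv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'topology': {err}") from err

    report = RunReport(network_summary=summary, group_sizes=group_sizes)
    report.provenance = {"config": asdict(cfg), "seed": cfg.seed,
                         "software": f"netdisrupt {__version__}"}

    # --- stage: univariate ------------------------------------------------
    testable = [g for g in groups if len(g.members) >= 2]
    for g in groups:
        if len(g.members) < 2:
            log.warning("univariate: skipping group %s (n=%d)", g.label, len(g.members))
    try:
        for col in cfg.univariate_indices:
            bg = _background_values(cfg, table, nonenriched, col)
            mu0 = robust_stats.pseudomedian(bg)
            report.locations.append(robust_stats.LocationSummary(
                label=f"{cfg.background}:{col}", n=len(bg), pseudomedian=mu0))
            for g in testable:
                x = table.loc[sorted(g.members), col].to_numpy()
                loc = robust_stats.location_summary(
                    x, label=f"{g.label}:{col}", B=cfg.bootstrap_B,
                    seed=_derive_seed(cfg.seed, f"boot:{g.label}:{col}"))
                report.locations.append(loc)
                report.univariate_tests.append(robust_stats.wilcoxon_one_sample_upper(
                    x, mu0, comparison=f"{g.label} vs {cfg.background} ({col})"))
            if len(testable) >= 2:
                samples = {g.label: table.loc[sorted(g.members), col].to_numpy()
                           for g in testable}
                omni, pairs = robust_stats.protected_pairwise_bdm(
                    samples, alpha=cfg.alpha, mode=cfg.bdm_mode,
                    n_perm=cfg.n_perm, seed=_derive_seed(cfg.seed, f"bdm:{col}"))
                omni.comparison = f"treatment groups ({col})"
                for r in pairs:
                    r.comparison += f" ({col})"
                report.bdm_omnibus.append(omni)
                report.bdm_pairwise.extend(pairs)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'univariate': {err}") from err

    # --- stage: multivariate ----------------------------------------------
    try:
        bg_nodes = sorted(nonenriched.members)
        if cfg.multivariate_background_size and \
                cfg.multivariate_background_size < len(bg_nodes):
            rng = np.random.default_rng(_derive_seed(cfg.seed, "mv-bg"))
            pick = rng.choice(len(bg_nodes), cfg.multivariate_background_size,
                              replace=False)
            bg_nodes = [bg_nodes[i] for i in sorted(pick)]
        cases, labels = [], []
        for g in testable:
            for v in sorted(g.members):
                cases.append(v)
                labels.append(g.label)
        cases += bg_nodes
        labels += [nonenriched.label] * len(bg_nodes)
        X = table.loc[cases, list(cfg.multivariate_indices)].to_numpy()
        if cfg.standardize_columns:
            rng_ = X.max(axis=0) - X.min(axis=0)
            X = (X - X.min(axis=0)) / np.where(rng_ > 0, rng_, 1.0)
        dm = ordination.steinhaus_dissimilarity(
            X, labels=cases, variable_names=list(cfg.multivariate_indices))
        omni, pairs = ordination.pairwise_permanova(
            dm, labels, n_perm=cfg.n_perm, alpha=cfg.alpha,
            seed=_derive_seed(cfg.seed, "permanova"))
        report.permanova_omnibus = omni
        report.permanova_pairwise = pairs
        ord_res = ordination.nmds(dm, k=cfg.nmds_k, n_starts=cfg.nmds_starts,
                                  seed=_derive_seed(cfg.seed, "nmds"))
        report.nmds = ord_res
        report.vector_fits = ordination.fit_vectors(
            ord_res.scores.to_numpy(), X,
            variable_names=list(cfg.multivariate_indices))
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'multivariate': {err}") from err

    _write_outputs(report, labels, outdir)
    return report


# ---------------------------------------------------------------------------
# output writers

def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.10g}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _write_outputs(report: RunReport, mv_labels: list, outdir: Path) -> None:
    s = report.network_summary
    _write_tsv(outdir / "network_summary.tsv", list(s), [list(s.values())])

    _write_tsv(outdir / "location_summaries.tsv",
               ["label", "n", "pseudomedian", "bootstrap_se", "B", "seed"],
               [[l.label, l.n, l.pseudomedian, l.bootstrap_se, l.B, l.seed]
                for l in report.locations])

    tcols = ["method", "comparison", "statistic", "df1", "df2",
             "p_raw", "p_adjusted", "alternative", "n_perm", "seed"]

    def _trow(t):
        df1, df2 = (t.df if t.df else (None, None))
        return [t.method, t.comparison, t.statistic, df1, df2,
                t.p_raw, t.p_adjusted, t.alternative, t.n_perm, t.seed]

    _write_tsv(outdir / "univariate_tests.tsv", tcols,
               [_trow(t) for t in report.univariate_tests + report.bdm_omnibus])
    _write_tsv(outdir / "bdm_pairwise.tsv", tcols,
               [_trow(t) for t in report.bdm_pairwise])

    prows = []
    for r in ([report.permanova_omnibus] if report.permanova_omnibus else []) \
            + list(report.permanova_pairwise):
        prows.append([r.comparison, r.statistic, r.df_between, r.df_within,
                      r.ss_among, r.ss_within, r.ss_total, r.p, r.p_adjusted,
                      r.n_perm, r.seed])
    _write_tsv(outdir / "permanova.tsv",
               ["comparison", "pseudo_F", "df_between", "df_within", "ss_among",
                "ss_within", "ss_total", "p", "p_adjusted", "n_perm", "seed"],
               prows)

    if report.nmds is not None:
        scores = report.nmds.scores.copy()
        scores.insert(0, "group", mv_labels)
        scores.to_csv(outdir / "nmds_scores.tsv", sep="\t", float_format="%.10g")
        _write_tsv(outdir / "vector_fits.tsv",
                   ["variable", "r2"] + [f"dir{i+1}" for i in
                                         range(report.nmds.scores.shape[1])],
                   [[f.variable, f.r2, *f.direction] for f in report.vector_fits])

    with open(outdir / "run_report.md", "w") as fh:
        fh.write("# netdisrupt run report\n\n## Network\n\n")
        for k, v in s.items():
            fh.write(f"- {k}: {_fmt(v)}\n")
        fh.write("\n## Groups\n\n")
        for k, v in report.group_sizes.items():
            fh.write(f"- {k}: {v} nodes\n")
        if report.permanova_omnibus:
            r = report.permanova_omnibus
            fh.write(f"\n## PERMANOVA omnibus\n\npseudo-F({r.df_between},"
                     f"{r.df_within}) = {r.statistic:.4g}, p = {r.p:.4g} "
                     f"({r.n_perm} permutations)\n")
        if report.nmds is not None:
            fh.write(f"\n## NMDS\n\nKruskal stress-1 = {report.nmds.stress:.4g} "
                     f"(best of {report.nmds.n_starts} starts)\n")
        fh.write("\n## Provenance\n\n```yaml\n")
        fh.write(yaml.safe_dump(report.provenance, sort_keys=True))
        fh.write("```\n")
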
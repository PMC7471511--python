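"""Sparsified co-expression network and module detection.

The network keeps, for every gene, only its ``retained_per_gene`` (default 3)
most positively Spearman-correlated partners; the union of these directed
picks is symmetrised into an undirected weighted graph.  Modules are the
best-modularity partition over repeated seeded runs of Leiden community
detection, with a per-gene stability score recording how consistently each
gene co-clusters with its final module across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SparseNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns gene_a, gene_b, weight (gene_a < gene_b)
    retained_per_gene: int = 3

    def __post_init__(self) -> None:
        e = self.edges
        swapped = e["gene_a"] > e["gene_b"]
        if swapped.any():
            a = e["gene_a"].where(~swapped, e["gene_b"])
            b = e["gene_b"].where(~swapped, e["gene_a"])
            e = e.assign(gene_a=a, gene_b=b)
        e = e.drop_duplicates(subset=["gene_a", "gene_b"])
        self.edges = e.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def degree(self) -> pd.Series:
        return (
            pd.concat([self.edges["gene_a"], self.edges["gene_b"]])
            .value_counts()
            .reindex(self.nodes, fill_value=0)
        )


@dataclass
class ModulePartition:
    """Gene -> module assignment with stability scores and module metadata."""

    assignment: pd.Series  # gene id -> module id (int, 1-based)
    stability: pd.Series
    module_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_iterations: int = 0
    best_modularity: float = float("nan")

    def __post_init__(self) -> None:
        if not self.stability.between(0, 1).all():
            raise ValueError("stabilities must lie in [0, 1]")
        if len(self.module_meta) == 0:
            sizes = self.assignment.value_counts().sort_index()
            self.module_meta = pd.DataFrame(
                {"size": sizes, "name": [f"M{m}" for m in sizes.index]}
            )

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.assignment.unique())

    def genes_in(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])

    def as_sets(self) -> dict[int, set[str]]:
        return {m: set(self.genes_in(m)) for m in self.module_ids}


def select_informative_genes(
    em: ExpressionMatrix, fraction: float | None = 0.5, n: int | None = None
) -> list[str]:
    """Rank genes by variance across samples and keep the most variable.

    Either a fraction in (0, 1] or an absolute count may be given.  Ties are
    broken by gene id so the selection is deterministic.
    """
    if em.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank genes by variance")
    var = em.values.var(axis=1, ddof=1)
    ranked = var.sort_index().sort_values(ascending=False, kind="mergesort")
    if n is None:
        if fraction is None or not (0 < fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        n = max(1, int(round(fraction * len(ranked))))
    return list(ranked.index[:n])


def build_network(em: ExpressionMatrix, retained_per_gene: int = 3) -> SparseNetwork:
    """Top-k signed Spearman network.

    For every gene the ``retained_per_gene`` partners with the highest signed
    correlation are kept; the union of picks is symmetrised.  Zero-variance
    genes are excluded with a warning (their rank correlation is undefined).
    Ties in the per-gene ranking break on lexicographic partner id.
    """
    if len(em.gene_ids) < 3:
        raise ValueError("need at least 3 genes to build a network")
    values = em.values
    var = values.var(axis=1, ddof=0)
    constant = var.index[var == 0]
    if len(constant):
        log.warning("excluding %d zero-variance genes from network", len(constant))
        values = values.drop(index=constant)
    genes = list(values.index)
    # ranks over samples per gene, then Pearson on ranks == Spearman
    ranks = values.rank(axis=1).to_numpy()
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norm, norm)
    np.fill_diagonal(rho, -np.inf)

    k = min(retained_per_gene, len(genes) - 1)
    rows = []
    gene_arr = np.array(genes)
    for i in range(len(genes)):
        # sort by (-rho, partner id): stable, deterministic tie-break
        order = np.lexsort((gene_arr, -rho[i]))
        for j in order[:k]:
            rows.append((genes[i], genes[j], rho[i, j]))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    return SparseNetwork(nodes=genes, edges=edges, retained_per_gene=retained_per_gene)


def _modularity_weights(weights: np.ndarray) -> np.ndarray:
    # Newman modularity needs non-negative weights; negative correlations
    # (possible when a gene has <k positive partners) contribute no pull.
    return np.clip(weights, 0.0, None)


def detect_modules(
    net: SparseNetwork, n_iterations: int = 100, seed: int = 0
) -> ModulePartition:
    """Repeated seeded Leiden runs; the best-modularity partition wins.

    Per-gene stability is the fraction of runs in which the gene lands in the
    same community as the plurality of its final module's members.  Modules
    are relabelled 1..m by decreasing size (ties by smallest member gene id).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    g = ig.Graph()
    g.add_vertices(net.nodes)
    idx = {gid: i for i, gid in enumerate(net.nodes)}
    pairs = [(idx[a], idx[b]) for a, b in zip(net.edges["gene_a"], net.edges["gene_b"])]
    g.add_edges(pairs)
    w = _modularity_weights(net.edges["weight"].to_numpy())

    memberships = []
    qualities = []
    for it in range(n_iterations):
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights=list(w),
            seed=seed + it,
            n_iterations=2,
        )
        memberships.append(np.asarray(part.membership))
        qualities.append(g.modularity(part.membership, weights=list(w)))
    best = int(np.argmax(qualities))
    final = memberships[best]

    # relabel by size desc, ties by smallest gene id in the module
    labels = np.unique(final)
    order = sorted(
        labels,
        key=lambda c: (-int((final == c).sum()), min(np.array(net.nodes)[final == c])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    module_ids = np.array([relabel[c] for c in final])

    stable_counts = np.zeros(len(net.nodes))
    for m in memberships:
        for mod in np.unique(module_ids):
            members = module_ids == mod
            # community holding the plurality of this final module in run m
            labs, counts = np.unique(m[members], return_counts=True)
            plural = labs[np.argmax(counts)]
            stable_counts[members & (m == plural)] += 1
    stability = stable_counts / n_iterations

    assignment = pd.Series(module_ids, index=net.nodes, name="module")
    return ModulePartition(
        assignment=assignment,
        stability=pd.Series(stability, index=net.nodes, name="stability"),
        n_iterations=n_iterations,
        best_modularity=float(qualities[best]),
    )


KINETIC_CLASSES = ("early-off", "transient", "late-on")


def zscore_genes(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-score across all time-course samples.

    Constant genes (undefined z) are excluded with a warning.
    """
    mu = em.values.mean(axis=1)
    sd = em.values.std(axis=1, ddof=0)
    constant = sd.index[sd == 0]
    if len(constant):
        log.warning("excluding %d constant genes from z-scoring", len(constant))
    vals = em.values.drop(index=constant)
    return vals.sub(mu.drop(constant), axis=0).div(sd.drop(constant), axis=0)


def module_expression_summary(
    partition: ModulePartition, em: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median z per (module, time point) plus a kinetic class per module.

    The kinetic class follows the position of the profile maximum: first time
    point -> early-off, last -> late-on, anything between -> transient.
    Returns (summary_profile, z_matrix); the summary is also written into
    ``partition.module_meta``.
    """
    z = zscore_genes(em)
    tps = em.time_points
    rows = {}
    for mod in partition.module_ids:
        genes = [g for g in partition.genes_in(mod) if g in z.index]
        profile = []
        for tp in tps:
            samples = em.sample_meta.index[em.sample_meta["time_point"] == tp]
            profile.append(float(np.median(z.loc[genes, samples].to_numpy())))
        rows[mod] = profile
    summary = pd.DataFrame.from_dict(rows, orient="index", columns=tps)
    summary.index.name = "module"

    peak = summary.to_numpy().argmax(axis=1)
    kinetic = np.where(
        peak == 0, "early-off", np.where(peak == len(tps) - 1, "late-on", "transient")
    )
    partition.module_meta = partition.module_meta.reindex(summary.index)
    partition.module_meta["kinetic_class"] = kinetic
    for tp in tps:
        partition.module_meta[f"median_z.{tp}"] = summary[tp]
    return summary, z


def modularity(net: SparseNetwork, assignment: pd.Series) -> float:
    """Newman modularity of a partition on the (clipped-weight) network."""
    g = ig.Graph()
    g.add_vertices(net.nodes)
    idx = {gid: i for i, gid in enumerate(net.nodes)}
    g.add_edges(
        [(idx[a], idx[b]) for a, b in zip(net.edges["gene_a"], net.edges["gene_b"])]
    )
    w = _modularity_weights(net.edges["weight"].to_numpy())
    membership = [int(assignment[gid]) for gid in net.nodes]
    return float(g.modularity(membership, weights=list(w)))


def partition_table(
    partition: ModulePartition, em: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Long-form module table: module id, name, gene, stability, then the
    per-sample expression values when an expression matrix is supplied."""
    meta = partition.module_meta
    rows = []
    for gene, mod in partition.assignment.sort_values(kind="mergesort").items():
        rows.append(
            {
                "module": mod,
                "module_name": meta.loc[mod, "name"] if "name" in meta else f"M{mod}",
                "gene": gene,
                "stability": partition.stability[gene],
            }
        )
    table = pd.DataFrame(rows)
    if em is not None:
        expr = em.values.reindex(table["gene"]).reset_index(drop=True)
        table = pd.concat([table, expr], axis=1)
    return table
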
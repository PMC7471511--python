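"""Hypergeometric enrichment / depletion of gene signatures in modules.

For a universe of N network genes, a signature of K genes (after intersection
with the universe) and a module of n genes with observed overlap k:

    E  = n K / N
    SD = sqrt(n (K/N) (1 - K/N) (N - n) / (N - 1))
    z  = (k - E) / SD

The reported probability is the one-sided hypergeometric tail on the observed
side — P(X >= k) when k >= E, P(X <= k) otherwise — so a negative z flags
significant depletion.  Benjamini-Hochberg correction is applied across all
(set, module) rows of a run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import cluster as sp_cluster
from scipy import stats
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io_formats import SignatureCollection
from .network import ModulePartition

#: Table S2-style column order for the enrichment output.
ENRICHMENT_COLUMNS = [
    "set_name",
    "set_source",
    "module_id",
    "k",
    "K",
    "n",
    "N",
    "expected",
    "sd",
    "pct_overlap",
    "enriched",
    "z",
    "p",
    "fdr",
    "degenerate",
    "overlap_genes",
]


def hypergeom_stats(N: int, K: int, n: int, k: int) -> tuple[float, float, float, float]:
    """(expected, sd, z, p) for overlap k under Hypergeometric(N, K, n).

    Degenerate cases (K=0, K=N, n=0 or n=N, where the overlap is
    deterministic) return z = 0 and p = 1.
    """
    expected = n * K / N if N else 0.0
    if N <= 1 or K in (0, N) or n in (0, N):
        return expected, 0.0, 0.0, 1.0
    sd = float(np.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1)))
    z = (k - expected) / sd
    if k >= expected:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    else:
        p = float(stats.hypergeom.cdf(k, N, K, n))
    return expected, sd, float(z), min(p, 1.0)


def enrich(
    signatures: SignatureCollection,
    partition: ModulePartition,
    universe: list[str] | set[str] | None = None,
) -> pd.DataFrame:
    """One row per (signature set, module) with overlap statistics.

    The universe defaults to all genes carried by the partition (the network
    genes); signatures are intersected with the universe before K is counted.
    """
    if universe is None:
        universe = list(partition.assignment.index)
    universe_set = {str(g).upper() for g in universe}
    N = len(universe_set)
    module_sets = {
        m: {g.upper() for g in genes} & universe_set
        for m, genes in partition.as_sets().items()
    }
    rows = []
    for set_name in sorted(signatures.sets):
        sig = set(signatures.sets[set_name]) & universe_set
        K = len(sig)
        for m in sorted(module_sets):
            mod = module_sets[m]
            n = len(mod)
            overlap = sorted(sig & mod)
            k = len(overlap)
            expected, sd, z, p = hypergeom_stats(N, K, n, k)
            rows.append(
                {
                    "set_name": set_name,
                    "set_source": signatures.source,
                    "module_id": m,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "expected": expected,
                    "sd": sd,
                    "pct_overlap": 100.0 * k / K if K else 0.0,
                    "enriched": int(k > expected),
                    "z": z,
                    "p": p,
                    "degenerate": sd == 0.0,
                    "overlap_genes": ",".join(overlap),
                }
            )
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table[ENRICHMENT_COLUMNS]


def filter_for_heatmap(
    table: pd.DataFrame,
    fdr_max: float = 0.05,
    min_size: int = 5,
    max_size: int = 1000,
    top_per_module: int = 15,
) -> pd.DataFrame:
    """Heat-map filtering: FDR < fdr_max, signature size within bounds, then
    the ``top_per_module`` smallest-p rows per module.

    Ties break on ascending p, then descending ``|z|``, then set name, so the
    selection is deterministic.
    """
    keep = table[
        (table["fdr"] < fdr_max)
        & (table["K"] >= min_size)
        & (table["K"] <= max_size)
    ].copy()
    keep["_absz"] = keep["z"].abs()
    keep = (
        keep.sort_values(
            ["module_id", "p", "_absz", "set_name"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .groupby("module_id", group_keys=False)
        .head(top_per_module)
        .drop(columns="_absz")
        .reset_index(drop=True)
    )
    return keep


def enrichment_heatmap_matrix(
    filtered: pd.DataFrame, full_table: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list, list]:
    """Modules x surviving-sets z matrix plus hierarchical-clustering orders.

    The columns are the union of sets surviving the filter; z values for
    (module, set) pairs absent from the filtered table are filled from the
    full table when given, otherwise set to 0.
    """
    modules = sorted(filtered["module_id"].unique())
    sets = sorted(filtered["set_name"].unique())
    source = full_table if full_table is not None else filtered
    mat = pd.DataFrame(0.0, index=modules, columns=sets)
    sub = source[source["set_name"].isin(sets) & source["module_id"].isin(modules)]
    for _, row in sub.iterrows():
        mat.loc[row["module_id"], row["set_name"]] = row["z"]
    row_order = _cluster_order(mat.to_numpy())
    col_order = _cluster_order(mat.to_numpy().T)
    return mat, [modules[i] for i in row_order], [sets[j] for j in col_order]


def _cluster_order(rows: np.ndarray) -> list[int]:
    if len(rows) < 3:
        return list(range(len(rows)))
    d = pdist(rows)
    if not np.isfinite(d).all() or d.max() == 0:
        return list(range(len(rows)))
    link = sp_cluster.hierarchy.linkage(d, method="average")
    return list(sp_cluster.hierarchy.leaves_list(link))


def plot_enrichment_heatmap(matrix: pd.DataFrame, path, vmax: float = 10.0) -> None:
    """Red/blue z heat map of the filtered enrichment matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * matrix.shape[1]), max(3, 0.3 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index])
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns], rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="z")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
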
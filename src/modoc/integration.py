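"""Module x occupancy integration and differential-expression analyses.

Occupancy gene sets (one per factor overall and one per regulatory K-cluster)
are tested for enrichment against the expression modules with the same
hypergeometric machinery used for curated signatures, with the universe
restricted to the network genes.  The resulting z matrix is displayed with
non-significant cells zeroed and values clipped to ±5 (raw values retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import _cluster_order, enrich
from .io_formats import ExpressionMatrix, GenomeAnnotation, PeakSet, SignatureCollection
from .network import ModulePartition
from .peaks import assign_peaks_to_genes
from .regclusters import RegulatoryClustering

log = logging.getLogger(__name__)

FC_LADDER = (1.2, 1.4, 1.6, 1.8, 2.0)


def occupancy_gene_sets(
    tf_peak_sets: dict[str, PeakSet],
    ann: GenomeAnnotation,
    clustering: RegulatoryClustering | None = None,
    union_regions: pd.DataFrame | None = None,
    max_dist: int = 10000,
    prefix: str = "U",
) -> SignatureCollection:
    """Gene sets from promoter-proximal occupancy.

    Per factor: ``<TF>.All`` = genes with at least one assigned peak.  When a
    regulatory clustering over union regions is given, ``<prefix>.K<i>`` =
    genes assigned to a region in K-means cluster i, and ``<prefix>.All`` is
    their union.  Empty sets are dropped with a warning.
    """
    sets: dict[str, list[str]] = {}
    for name in sorted(tf_peak_sets):
        _, bound = assign_peaks_to_genes(tf_peak_sets[name], ann, max_dist=max_dist)
        if not bound:
            log.warning("factor %s has no promoter-proximal genes; set dropped", name)
            continue
        sets[f"{name}.All"] = sorted(bound)
    if clustering is not None:
        regions = clustering.regions if union_regions is None else union_regions
        region_ps = PeakSet(
            "union",
            pd.DataFrame(
                {
                    "chrom": regions["chrom"],
                    "start": regions["centre"],
                    "end": regions["centre"] + 1,
                }
            ),
        )
        assigned, _ = assign_peaks_to_genes(region_ps, ann, max_dist=max_dist)
        # PeakSet re-sorts rows; map sorted rows back to the input regions
        order = (
            regions.assign(_row=np.arange(len(regions)))
            .sort_values(["chrom", "centre"], kind="mergesort")["_row"]
            .to_numpy()
        )
        all_genes: set[str] = set()
        for c in range(1, clustering.k + 1):
            genes: set[str] = set()
            for sorted_i, orig_i in enumerate(order):
                if clustering.labels[orig_i] == c:
                    genes.update(assigned[sorted_i])
            if genes:
                sets[f"{prefix}.K{c}"] = sorted(genes)
                all_genes |= genes
            else:
                log.warning("cluster %s.K%d has no assigned genes; set dropped", prefix, c)
        if all_genes:
            sets[f"{prefix}.All"] = sorted(all_genes)
    return SignatureCollection(sets, source="occupancy")


@dataclass
class ModuleOccupancyMatrix:
    """Modules x occupancy-sets z matrix with display conventions applied."""

    raw_z: pd.DataFrame
    displayed_z: pd.DataFrame  # zeroed where non-significant, clipped to ±ceiling
    p: pd.DataFrame
    table: pd.DataFrame  # full enrichment rows
    row_order: list
    col_order: list
    p_threshold: float = 0.05
    ceiling: float = 5.0


def module_occupancy_enrichment(
    occ_sets: SignatureCollection,
    partition: ModulePartition,
    universe: list[str] | None = None,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
    ceiling: float = 5.0,
) -> ModuleOccupancyMatrix:
    """Hypergeometric association of occupancy sets with expression modules.

    z values whose (raw, or BH-adjusted when ``use_fdr``) probability exceeds
    ``p_threshold`` are set to 0 in the displayed matrix; displayed values
    are clipped to ±``ceiling``.  Rows follow the module kinetic ordering
    when present in ``partition.module_meta``; columns are ordered by
    hierarchical clustering of the displayed matrix.
    """
    table = enrich(occ_sets, partition, universe=universe)
    raw = table.pivot(index="module_id", columns="set_name", values="z")
    pcol = "fdr" if use_fdr else "p"
    pmat = table.pivot(index="module_id", columns="set_name", values=pcol)
    displayed = raw.where(pmat <= p_threshold, 0.0).clip(-ceiling, ceiling)

    meta = partition.module_meta
    if "kinetic_class" in meta.columns:
        order_key = {"early-off": 0, "transient": 1, "late-on": 2}
        row_order = sorted(
            raw.index, key=lambda m: (order_key.get(meta.loc[m, "kinetic_class"], 3), m)
        )
    else:
        row_order = list(raw.index)
    col_idx = _cluster_order(displayed.to_numpy().T)
    col_order = [displayed.columns[i] for i in col_idx]
    return ModuleOccupancyMatrix(
        raw_z=raw,
        displayed_z=displayed,
        p=pmat,
        table=table,
        row_order=row_order,
        col_order=col_order,
        p_threshold=p_threshold,
        ceiling=ceiling,
    )


def differential_expression(
    em: ExpressionMatrix,
    condition_pair: tuple[str, str],
    time_point: str | None = None,
    paired_by: str = "donor",
    fdr_max: float = 0.05,
    fc_ladder: tuple[float, ...] = FC_LADDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired differential expression between two conditions.

    Samples are matched on (time point, donor); each gene gets the mean
    paired log2 difference (condition a minus b), a two-sided paired t test
    and a BH-adjusted FDR.  The ladder table counts genes per direction at
    each fold-change threshold with FDR < ``fdr_max``; a gene passing a
    higher rung passes every lower one by construction.
    """
    cond_a, cond_b = condition_pair
    meta = em.sample_meta
    if time_point is not None:
        meta = meta[meta["time_point"] == time_point]
    a = meta[meta["condition"] == cond_a]
    b = meta[meta["condition"] == cond_b]
    key_a = {(r["time_point"], r[paired_by]): s for s, r in a.iterrows()}
    key_b = {(r["time_point"], r[paired_by]): s for s, r in b.iterrows()}
    shared = sorted(set(key_a) & set(key_b))
    if len(shared) < 2:
        raise ValueError("need at least 2 paired replicates")
    sa = [key_a[k] for k in shared]
    sb = [key_b[k] for k in shared]
    diffs = em.values[sa].to_numpy() - em.values[sb].to_numpy()
    log2fc = diffs.mean(axis=1)
    t, p = stats.ttest_rel(em.values[sa], em.values[sb], axis=1)
    # zero-variance paired differences: identical data -> p=1, a constant
    # nonzero shift -> limiting case of infinite evidence
    zero_var = diffs.std(axis=1) == 0
    p = np.where(np.isnan(p) & zero_var & (log2fc != 0), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": em.gene_ids,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        }
    ).set_index("gene")
    # tiny tolerance so a planted exact k-fold change is not lost to
    # floating-point rounding at its own rung
    eps = 1e-9
    for thr in fc_ladder:
        table[f"fc{thr}"] = (np.abs(log2fc) >= np.log2(thr) - eps) & (fdr < fdr_max)

    ladder_rows = []
    for thr in fc_ladder:
        sig = (fdr < fdr_max) & (np.abs(log2fc) >= np.log2(thr) - eps)
        ladder_rows.append(
            {
                "threshold": thr,
                "up": int((sig & (log2fc > 0)).sum()),
                "down": int((sig & (log2fc < 0)).sum()),
            }
        )
    ladder = pd.DataFrame(ladder_rows).set_index("threshold")
    return table, ladder


def de_gene_sets(
    de_table: pd.DataFrame, fc_threshold: float = 2.0, fdr_max: float = 0.05
) -> tuple[list[str], list[str]]:
    """(up, down) gene lists at a fold-change rung with FDR < fdr_max."""
    sig = (de_table["fdr"] < fdr_max) & (
        de_table["log2fc"].abs() >= np.log2(fc_threshold) - 1e-9
    )
    up = sorted(de_table.index[sig & (de_table["log2fc"] > 0)])
    down = sorted(de_table.index[sig & (de_table["log2fc"] < 0)])
    return up, down


def de_module_dumbbell(
    de_table: pd.DataFrame,
    partition: ModulePartition,
    fc_threshold: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Per-module enrichment z for the up- and down-regulated gene lists.

    Two enrichment runs (up set, down set) against the modules; modules are
    ranked by z_up - z_down, the ordering used for dumbbell displays, and
    each side carries its FDR-significance flag.
    """
    up, down = de_gene_sets(de_table, fc_threshold=fc_threshold, fdr_max=fdr_max)
    sc = SignatureCollection(
        {name: genes for name, genes in (("up", up), ("down", down)) if genes},
        source="differential-expression",
    )
    modules = sorted(partition.module_ids)
    if not len(sc):
        return pd.DataFrame(
            {
                "z_up": 0.0,
                "z_down": 0.0,
                "fdr_up": 1.0,
                "fdr_down": 1.0,
            },
            index=pd.Index(modules, name="module_id"),
        )
    table = enrich(sc, partition)
    out = pd.DataFrame(index=pd.Index(modules, name="module_id"))
    for side in ("up", "down"):
        sub = table[table["set_name"] == side].set_index("module_id")
        out[f"z_{side}"] = sub["z"] if len(sub) else 0.0
        out[f"fdr_{side}"] = sub["fdr"] if len(sub) else 1.0
    out = out.fillna({"z_up": 0.0, "z_down": 0.0, "fdr_up": 1.0, "fdr_down": 1.0})
    rank = (out["z_up"] - out["z_down"]).sort_values(ascending=False, kind="mergesort")
    return out.loc[rank.index]
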
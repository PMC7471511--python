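"""End-to-end orchestration: synthesise inputs, build the module network,
run signature enrichment, peak analyses, regulatory K-means clusters and the
module x occupancy integration, writing TSV outputs plus a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichment, integration, network, peaks, regclusters, synthetic
from .io_formats import (
    write_annotation,
    write_bed,
    write_bedgraph,
    write_expression,
    write_gmt,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters for a pipeline run; defaults follow the published
    analysis settings (3 retained edges per gene, 250-bp overlap clustering,
    10-kb promoter assignment, k=6 regulatory clusters, ±1,000-bp windows,
    FDR 0.05)."""

    out_dir: str = "modoc_run"
    seed: int = 1
    # synthetic stage
    n_genes: int = 2000
    n_modules: int = 8
    noise_sd: float = 0.5
    # network stage
    informative_fraction: float = 0.5
    retained_per_gene: int = 3
    iterations: int = 100
    # enrichment / integration
    fdr: float = 0.05
    n_signature_sets: int = 30
    signature_jaccard: float = 0.5
    # peaks / clusters
    cluster_threshold: int = 250
    assign_max_dist: int = 10000
    k: int = 6
    half_width: int = 1000
    bin_size: int = 50
    fc_ladder: tuple[float, ...] = integration.FC_LADDER

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic bundle; returns a result dictionary and
    writes TSVs, ground truth and a manifest under ``config.out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    scfg = synthetic.SyntheticConfig(
        n_genes=config.n_genes, n_modules=config.n_modules,
        noise_sd=config.noise_sd, rng_seed=config.seed,
    )
    em, truth = synthetic.simulate_expression(scfg)
    write_expression(em, out / "expression.tsv")
    truth.assignment.rename("module").to_csv(out / "truth" / "modules.tsv", sep="\t")

    signatures = synthetic.simulate_signatures(
        truth, scfg, n_sets=config.n_signature_sets,
        jaccard_with_truth=config.signature_jaccard,
    )
    write_gmt(signatures, out / "signatures.gmt")

    ann = synthetic.simulate_genome(scfg)
    write_annotation(ann, out / "genes.bed")
    tf_sets, tf_targets = synthetic.simulate_peaks(scfg, truth, ann)
    for name, ps in tf_sets.items():
        write_bed(ps, out / f"peaks_{name}.bed")
    with open(out / "truth" / "tf_targets.json", "w") as fh:
        json.dump(tf_targets, fh, indent=1)

    # network + modules
    informative = network.select_informative_genes(em, fraction=config.informative_fraction)
    net = network.build_network(
        em.subset_genes(informative), retained_per_gene=config.retained_per_gene
    )
    partition = network.detect_modules(
        net, n_iterations=config.iterations, seed=config.seed
    )
    summary, _ = network.module_expression_summary(partition, em)
    net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    network.partition_table(partition, em).to_csv(
        out / "modules.tsv", sep="\t", index=False
    )
    summary.to_csv(out / "module_profiles.tsv", sep="\t")

    # signature enrichment
    enr = enrichment.enrich(signatures, partition)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    filtered = enrichment.filter_for_heatmap(enr, fdr_max=config.fdr)
    heat, row_order, col_order = enrichment.enrichment_heatmap_matrix(filtered, enr)
    heat.to_csv(out / "enrichment_heatmap.tsv", sep="\t")

    # peak analyses
    tf_list = [tf_sets[n] for n in sorted(tf_sets)]
    venn = peaks.venn_counts(tf_list, threshold=config.cluster_threshold)
    venn_df = pd.DataFrame(
        [
            {"signature": "+".join(sorted(sig)), "clusters": c}
            for sig, c in sorted(venn.counts.items(), key=lambda kv: sorted(kv[0]))
        ]
    )
    venn_df.to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    annotations = {}
    for name in sorted(tf_sets):
        tab = peaks.annotation_table(
            tf_sets[name], ann, max_dist=config.assign_max_dist
        )
        tab.to_csv(out / f"peak_annotation_{name}.tsv", sep="\t", index=False)
        annotations[name] = tab

    # regulatory clusters
    regions = regclusters.build_union_regions(
        tf_list, threshold=config.cluster_threshold
    )
    tracks, arch_truth = synthetic.simulate_tracks(
        scfg, regions, half_width=config.half_width, bin_size=config.bin_size
    )
    for name, track in tracks.items():
        write_bedgraph(track, out / f"track_{name}.bedgraph")
    arch_truth.rename_axis("region_id").to_csv(out / "truth" / "archetypes.tsv", sep="\t")
    sm = regclusters.build_signal_matrix(
        regions, tracks, half_width=config.half_width, bin_size=config.bin_size
    )
    k = min(config.k, len(sm.regions))
    clustering = regclusters.kmeans_clusters(sm, k=k, seed=config.seed)
    regions.assign(cluster=clustering.label_names()).to_csv(
        out / "region_clusters.tsv", sep="\t", index=False
    )
    occ_frac = regclusters.cluster_occupancy_fractions(clustering, sorted(tf_sets))
    occ_frac.to_csv(out / "cluster_occupancy.tsv", sep="\t")

    # integration
    occ_sets = integration.occupancy_gene_sets(
        tf_sets, ann, clustering=clustering, max_dist=config.assign_max_dist
    )
    mom = integration.module_occupancy_enrichment(occ_sets, partition)
    mom.displayed_z.to_csv(out / "module_occupancy_z.tsv", sep="\t")
    mom.table.to_csv(out / "module_occupancy_table.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "n_network_genes": len(net.nodes),
        "n_modules_detected": len(partition.module_ids),
        "best_modularity": partition.best_modularity,
        "n_union_regions": int(len(regions)),
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "config": config,
        "expression": em,
        "truth": truth,
        "signatures": signatures,
        "annotation": ann,
        "tf_sets": tf_sets,
        "tf_targets": tf_targets,
        "network": net,
        "partition": partition,
        "module_summary": summary,
        "enrichment": enr,
        "venn": venn,
        "regions": regions,
        "tracks": tracks,
        "archetype_truth": arch_truth,
        "signal_matrix": sm,
        "clustering": clustering,
        "occupancy_sets": occ_sets,
        "module_occupancy": mom,
        "manifest": manifest,
    }
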
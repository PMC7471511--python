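"""Peak-centre overlap clustering, Venn partitions, genomic-location
classification and promoter-proximal peak-to-gene assignment.

Co-occupancy is called on peak *centres*: all peaks (pooled across factors
and sorted by centre) whose centre lies within ``threshold`` bp of the
cluster's index peak centre form one overlapping cluster.  The distance is
anchored at the index (first) peak, not chained to the last absorbed peak, so
clusters cannot grow without bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, PeakSet

log = logging.getLogger(__name__)


@dataclass
class PeakCluster:
    cluster_id: int
    chrom: str
    members: list[tuple[str, int]]  # (peak set name, row index within that set)
    centres: list[int]

    @property
    def consensus_centre(self) -> int:
        return int(np.median(self.centres))

    @property
    def occupancy_signature(self) -> frozenset[str]:
        return frozenset(name for name, _ in self.members)


def cluster_peaks(peak_sets: list[PeakSet], threshold: int = 250) -> list[PeakCluster]:
    """Greedy single-pass clustering of pooled peak centres per chromosome.

    The first unassigned peak opens a cluster and becomes its index;
    subsequent peaks are absorbed while ``centre - index_centre < threshold``.
    Nearby peaks of a single set end up merged into one cluster, so per-set
    member totals can differ slightly from raw peak counts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pooled = []
    for ps in peak_sets:
        for i, row in ps.peaks.iterrows():
            pooled.append((row["chrom"], int(row["centre"]), ps.name, i))
    pooled.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    clusters: list[PeakCluster] = []
    current: PeakCluster | None = None
    index_centre = None
    for chrom, centre, name, i in pooled:
        if (
            current is None
            or chrom != current.chrom
            or centre - index_centre >= threshold
        ):
            current = PeakCluster(len(clusters), chrom, [], [])
            clusters.append(current)
            index_centre = centre
        current.members.append((name, i))
        current.centres.append(centre)
    return clusters


@dataclass
class VennResult:
    counts: dict[frozenset, int]  # occupancy signature -> number of clusters
    set_totals: dict[str, int]  # raw peak counts per set
    merged_discrepancy: dict[str, int]  # raw peaks - clusters containing the set

    def shared_clusters(self, name: str) -> int:
        return sum(
            c for sig, c in self.counts.items() if name in sig and len(sig) > 1
        )

    def shared_fraction_pct(self, name: str) -> float:
        """Shared clusters as a percentage of the set's raw peak count."""
        return 100.0 * self.shared_clusters(name) / self.set_totals[name]


def shared_fraction_pct(shared: int, total: int, ndigits: int = 1) -> float:
    """Percentage of a factor's peaks shared with another occupancy set."""
    return round(100.0 * shared / total, ndigits)


def venn_counts(peak_sets: list[PeakSet], threshold: int = 250) -> VennResult:
    """Partition counts of overlap clusters by occupancy signature."""
    clusters = cluster_peaks(peak_sets, threshold=threshold)
    counts: Counter = Counter(c.occupancy_signature for c in clusters)
    totals = {ps.name: len(ps) for ps in peak_sets}
    containing = {
        ps.name: sum(1 for c in clusters if ps.name in c.occupancy_signature)
        for ps in peak_sets
    }
    discrepancy = {name: totals[name] - containing[name] for name in totals}
    for name, d in discrepancy.items():
        if d:
            log.info("set %s: %d peaks merged into shared clusters", name, d)
    return VennResult(dict(counts), totals, discrepancy)


LOCATION_CLASSES = ("Promoter", "TTS", "Genic", "Intergenic")


def _windows(ann: GenomeAnnotation) -> pd.DataFrame:
    """Strand-aware promoter / terminator windows per gene (closed, on the
    centre coordinate): promoter −1 kb…+100 bp around the TSS, terminator
    −100 bp…+1 kb around the TES, both mirrored on the minus strand."""
    g = ann.genes
    plus = g["strand"] == "+"
    tss = g["tss"].to_numpy()
    tes = np.where(plus, g["end"] - 1, g["start"])
    prom_lo = np.where(plus, tss - 1000, tss - 100)
    prom_hi = np.where(plus, tss + 100, tss + 1000)
    tts_lo = np.where(plus, tes - 100, tes - 1000)
    tts_hi = np.where(plus, tes + 1000, tes + 100)
    return pd.DataFrame(
        {
            "gene_id": g["gene_id"],
            "chrom": g["chrom"],
            "start": g["start"],
            "end": g["end"],
            "tss": tss,
            "prom_lo": prom_lo,
            "prom_hi": prom_hi,
            "tts_lo": tts_lo,
            "tts_hi": tts_hi,
        }
    )


def classify_location(ps: PeakSet, ann: GenomeAnnotation) -> pd.DataFrame:
    """Mutually exclusive location class per peak centre.

    Precedence: Promoter > TTS > Genic > Intergenic.  Also reports the
    nearest gene by TSS distance and the absolute distance of the peak centre
    from that nearest promoter.
    """
    win = _windows(ann)
    by_chrom = {chrom: grp for chrom, grp in win.groupby("chrom")}
    rows = []
    for _, peak in ps.peaks.iterrows():
        centre = int(peak["centre"])
        grp = by_chrom.get(peak["chrom"])
        if grp is None:
            rows.append(("Intergenic", None, np.nan))
            continue
        tss_dist = np.abs(grp["tss"].to_numpy() - centre)
        nearest = int(np.argmin(tss_dist))
        nearest_gene = grp["gene_id"].iloc[nearest]
        nearest_dist = int(tss_dist[nearest])
        in_prom = (grp["prom_lo"] <= centre) & (centre <= grp["prom_hi"])
        in_tts = (grp["tts_lo"] <= centre) & (centre <= grp["tts_hi"])
        in_gene = (grp["start"] <= centre) & (centre < grp["end"])
        if in_prom.any():
            cls = "Promoter"
        elif in_tts.any():
            cls = "TTS"
        elif in_gene.any():
            cls = "Genic"
        else:
            cls = "Intergenic"
        rows.append((cls, nearest_gene, nearest_dist))
    out = ps.peaks[["chrom", "start", "end", "centre"]].copy()
    out[["location_class", "nearest_gene", "distance_to_nearest_promoter"]] = pd.DataFrame(
        rows, index=out.index
    )
    return out


def location_proportions(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of peaks per location class (sums to 1)."""
    props = annotated["location_class"].value_counts(normalize=True)
    return props.reindex(LOCATION_CLASSES, fill_value=0.0)


def assign_peaks_to_genes(
    ps: PeakSet, ann: GenomeAnnotation, max_dist: int = 10000
) -> tuple[list[list[str]], set[str]]:
    """Promoter-proximity rule: a peak is assigned to gene g iff the peak
    centre lies within ``max_dist`` of g's TSS and no other TSS falls
    strictly between the centre and that TSS.

    Only the nearest TSS on each side of the centre can qualify (anything
    further is blocked by an intervening TSS); genes whose TSSs coincide at
    the nearest position are all retained.  Returns the per-peak assigned
    gene lists plus the union bound-gene set.
    """
    if "tss" not in ann.genes.columns:
        raise ValueError("annotation lacks TSS positions")
    per_chrom = {}
    for chrom, grp in ann.genes.groupby("chrom"):
        grp = grp.sort_values(["tss", "gene_id"], kind="mergesort")
        per_chrom[chrom] = (grp["tss"].to_numpy(), grp["gene_id"].to_numpy())

    assigned: list[list[str]] = []
    for _, peak in ps.peaks.iterrows():
        centre = int(peak["centre"])
        hits: list[str] = []
        data = per_chrom.get(peak["chrom"])
        if data is not None:
            tss, gids = data
            right = int(np.searchsorted(tss, centre, side="left"))
            # nearest TSS at or above the centre
            if right < len(tss) and tss[right] - centre <= max_dist:
                pos = tss[right]
                hits.extend(gids[tss == pos])
            # nearest TSS strictly below the centre
            left = int(np.searchsorted(tss, centre, side="left")) - 1
            if left >= 0 and centre - tss[left] <= max_dist and tss[left] != centre:
                pos = tss[left]
                hits.extend(gids[tss == pos])
        assigned.append(sorted(set(hits)))
    bound = set().union(*assigned) if assigned else set()
    return assigned, bound


def bound_fraction(gene_list, bound_gene_set) -> tuple[int, int, int]:
    """(k, n, percentage) of genes in ``gene_list`` present in the bound set.

    The percentage is rounded to the nearest integer, the resolution at which
    such fractions are quoted.
    """
    genes = list(dict.fromkeys(gene_list))
    n = len(genes)
    k = sum(1 for g in genes if g in bound_gene_set)
    pct = int(round(100.0 * k / n)) if n else 0
    return k, n, pct


def annotation_table(
    ps: PeakSet, ann: GenomeAnnotation, max_dist: int = 10000
) -> pd.DataFrame:
    """Per-peak annotation table: location class, promoter flag, nearest gene,
    distance and any further promoter-assigned genes."""
    loc = classify_location(ps, ann)
    assigned, _ = assign_peaks_to_genes(ps, ann, max_dist=max_dist)
    loc["promoter"] = (loc["location_class"] == "Promoter").astype(int)
    loc["assigned_genes"] = [",".join(a) for a in assigned]
    return loc
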
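"""deepTools-style region x bin signal matrices and K-means regulatory
clusters.

Regions are consensus centres of peak-overlap clusters (for a multi-factor
union) or single-factor peak centres.  Around each centre, mean coverage is
computed in fixed-width bins over ±``half_width`` bp per track; the
per-region profiles across all tracks are concatenated and K-means-clustered.
Cluster labels are re-ordered by decreasing total mean raw signal so that K1
is always the most active cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io_formats import CoverageTrack, PeakSet
from .peaks import PeakCluster, cluster_peaks

log = logging.getLogger(__name__)


def build_union_regions(
    peak_sets: list[PeakSet], threshold: int = 250
) -> pd.DataFrame:
    """Collapse peak-overlap clusters to consensus-centre regions.

    Columns: region_id, chrom, centre, occupancy (comma-joined factor names).
    """
    clusters = cluster_peaks(peak_sets, threshold=threshold)
    rows = [
        {
            "region_id": c.cluster_id,
            "chrom": c.chrom,
            "centre": c.consensus_centre,
            "occupancy": ",".join(sorted(c.occupancy_signature)),
        }
        for c in clusters
    ]
    return pd.DataFrame(rows)


@dataclass
class SignalMatrix:
    regions: pd.DataFrame
    tracks: list[str]
    values: dict[str, np.ndarray]  # track -> (n_regions, n_bins) raw means
    bin_size: int
    half_width: int
    normalization: str = "mass"

    @property
    def n_bins(self) -> int:
        return 2 * self.half_width // self.bin_size

    def concatenated(self, z_scale: bool = True) -> np.ndarray:
        """Row vectors for clustering: per-track matrices z-scaled (so tracks
        with different dynamic range contribute comparably) and concatenated."""
        blocks = []
        for t in self.tracks:
            block = self.values[t]
            if z_scale:
                mu, sd = block.mean(), block.std()
                block = (block - mu) / sd if sd > 0 else block - mu
            blocks.append(block)
        return np.hstack(blocks)


def build_signal_matrix(
    regions: pd.DataFrame,
    tracks: dict[str, CoverageTrack],
    half_width: int = 1000,
    bin_size: int = 50,
    normalization: str | None = "mass",
) -> SignalMatrix:
    """Mean track signal per bin over ±half_width around each region centre.

    ``normalization="mass"`` rescales each track to a fixed total genomic
    mass (1e6 signal·bp, a counts-per-million-style normalisation) before
    binning so tracks are comparable; ``None`` keeps raw values.  Windows
    running off a chromosome end contribute zero-filled bins with a warning.
    """
    if (2 * half_width) % bin_size:
        raise ValueError("bin_size must divide 2*half_width")
    n_bins = 2 * half_width // bin_size
    values = {}
    clipped = 0
    for name in tracks:
        track = tracks[name]
        scale = 1.0
        if normalization == "mass":
            mass = track.total_mass()
            scale = 1e6 / mass if mass > 0 else 1.0
        mat = np.zeros((len(regions), n_bins))
        for i, row in regions.reset_index(drop=True).iterrows():
            start = int(row["centre"]) - half_width
            end = int(row["centre"]) + half_width
            if start < 0:
                clipped += 1
                lo_bins = (-start + bin_size - 1) // bin_size
                means = np.zeros(n_bins)
                means[lo_bins:] = track.bin_means(
                    row["chrom"], start + lo_bins * bin_size, end, n_bins - lo_bins
                )
            else:
                means = track.bin_means(row["chrom"], start, end, n_bins)
            mat[i] = means * scale
        values[name] = mat
    if clipped:
        log.warning("%d region windows clipped at a chromosome edge", clipped)
    return SignalMatrix(
        regions=regions.reset_index(drop=True),
        tracks=sorted(tracks),
        values=values,
        bin_size=bin_size,
        half_width=half_width,
        normalization=normalization or "none",
    )


@dataclass
class RegulatoryClustering:
    k: int
    labels: np.ndarray  # region index -> 1..k (K1 = most active)
    centroids: np.ndarray
    regions: pd.DataFrame
    prefix: str = "U"

    def label_names(self) -> list[str]:
        return [f"{self.prefix}.K{l}" for l in self.labels]


def kmeans_clusters(
    sm: SignalMatrix, k: int = 6, seed: int = 0, n_init: int = 10, prefix: str = "U"
) -> RegulatoryClustering:
    """K-means over concatenated per-track profiles.

    Clusters are relabelled 1..k in decreasing order of total mean raw signal
    so that K1 is the most active archetype and ordering is comparable across
    seeds.
    """
    if k > len(sm.regions):
        raise ValueError("k exceeds number of regions")
    X = sm.concatenated(z_scale=True)
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw_labels = km.fit_predict(X)
    raw_total = np.hstack([sm.values[t] for t in sm.tracks])
    activity = np.array(
        [raw_total[raw_labels == c].mean() if (raw_labels == c).any() else -np.inf
         for c in range(k)]
    )
    order = np.argsort(-activity, kind="mergesort")
    relabel = {int(c): i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw_labels])
    centroids = km.cluster_centers_[order]
    return RegulatoryClustering(
        k=k, labels=labels, centroids=centroids, regions=sm.regions, prefix=prefix
    )


def cluster_occupancy_fractions(
    clustering: RegulatoryClustering, tf_names: list[str]
) -> pd.DataFrame:
    """Percentage of each factor's union regions falling in each cluster.

    For (cluster c, factor t): 100 x (regions in c whose overlap cluster
    contains a t peak) / (t's total regions in the union).  Columns therefore
    sum to 100 for every factor present in the union.
    """
    occ = clustering.regions["occupancy"].str.split(",")
    out = pd.DataFrame(
        0.0, index=[f"K{c}" for c in range(1, clustering.k + 1)], columns=tf_names
    )
    for t in tf_names:
        has = np.array([t in o for o in occ])
        total = has.sum()
        if total == 0:
            continue
        for c in range(1, clustering.k + 1):
            out.loc[f"K{c}", t] = 100.0 * (has & (clustering.labels == c)).sum() / total
    return out


def archetype_recovery_ari(clustering: RegulatoryClustering, truth: pd.Series) -> float:
    """Adjusted Rand Index between K-means labels and planted archetypes."""
    truth = truth.reindex(clustering.regions["region_id"])
    return float(adjusted_rand_score(truth.to_numpy(), clustering.labels))


def plot_signal_heatmap(sm: SignalMatrix, clustering: RegulatoryClustering, path) -> None:
    """deepTools-like heat map: one panel per track, rows sorted by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(clustering.labels, kind="mergesort")
    fig, axes = plt.subplots(
        1, len(sm.tracks), figsize=(2.2 * len(sm.tracks), 6), squeeze=False
    )
    for ax, t in zip(axes[0], sm.tracks):
        block = sm.values[t][order]
        ax.imshow(block, aspect="auto", cmap="Blues", vmin=0,
                  vmax=np.percentile(block, 99) or 1)
        ax.set_title(t, fontsize=8)
        ax.set_xticks([0, sm.n_bins // 2, sm.n_bins - 1],
                      [f"-{sm.half_width}", "0", f"+{sm.half_width}"], fontsize=6)
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
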
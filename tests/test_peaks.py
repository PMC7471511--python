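import numpy as np
import pandas as pd
import pytest

from modoc.io_formats import GenomeAnnotation, PeakSet
from modoc.peaks import (
    annotation_table,
    assign_peaks_to_genes,
    bound_fraction,
    classify_location,
    cluster_peaks,
    location_proportions,
    shared_fraction_pct,
    venn_counts,
)

from _oracles import brute_force_clusters


def peakset(name, centres, chrom="chr1"):
    centres = list(centres)
    return PeakSet(
        name,
        pd.DataFrame(
            {
                "chrom": [chrom] * len(centres),
                "start": [c - 50 for c in centres],
                "end": [c + 50 for c in centres],
            }
        ),
    )


def annotation(genes):
    """genes: list of (gene_id, chrom, start, end, strand)."""
    df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    sizes = {c: int(df[df["chrom"] == c]["end"].max() + 100000) for c in df["chrom"]}
    return GenomeAnnotation(df, sizes)


class TestClusterPeaks:
    def test_rule_application(self):
        clusters = cluster_peaks([peakset("A", [100, 300, 600])], threshold=250)
        groups = [sorted(c.centres) for c in clusters]
        assert groups == [[100, 300], [600]]

    def test_index_anchored_not_chained(self):
        # 400 is < 250 from 200 but >= 250 from the index peak at 0
        clusters = cluster_peaks([peakset("A", [0, 200, 400])], threshold=250)
        assert [sorted(c.centres) for c in clusters] == [[0, 200], [400]]

    def test_identical_sets_fully_co_occupied(self):
        a = peakset("A", [100, 5000, 9000])
        b = peakset("B", [100, 5000, 9000])
        clusters = cluster_peaks([a, b])
        assert all(c.occupancy_signature == {"A", "B"} for c in clusters)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            cluster_peaks([peakset("A", [100])], threshold=0)

    def test_consensus_centre_is_median(self):
        clusters = cluster_peaks([peakset("A", [100, 140, 260])], threshold=250)
        assert clusters[0].consensus_centre == 140

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        pooled = {}
        for name in ("A", "B", "C")[: rng.integers(1, 4)]:
            n = int(rng.integers(1, 80))
            centres = sorted(rng.integers(0, 20000, size=n).tolist())
            sets.append(peakset(name, centres))
        for ps in sets:
            for i, row in ps.peaks.iterrows():
                pooled.setdefault(row["chrom"], []).append(
                    (int(row["centre"]), (ps.name, i))
                )
        got = sorted(
            sorted((name, i) for name, i in c.members) for c in cluster_peaks(sets)
        )
        want = sorted(sorted(tags) for tags in brute_force_clusters(pooled, 250))
        assert got == [list(w) for w in want]


class TestVenn:
    def test_two_close_peaks_share_one_cluster(self):
        res = venn_counts([peakset("A", [150]), peakset("B", [200])])
        assert res.counts == {frozenset({"A", "B"}): 1}

    def test_disjoint_chromosomes_never_shared(self):
        res = venn_counts(
            [peakset("A", [100], chrom="chr1"), peakset("B", [100], chrom="chr2")]
        )
        assert frozenset({"A", "B"}) not in res.counts
        assert res.shared_clusters("A") == 0

    def test_partition_counts_sum_to_total_clusters(self):
        rng = np.random.default_rng(3)
        sets = [
            peakset(name, sorted(rng.integers(0, 50000, size=60).tolist()))
            for name in ("A", "B")
        ]
        res = venn_counts(sets)
        assert sum(res.counts.values()) == len(cluster_peaks(sets))

    def test_shared_fraction_percentage_arithmetic(self):
        assert shared_fraction_pct(2483, 18271) == 13.6
        assert round(shared_fraction_pct(2483, 9512, ndigits=3)) == 26


class TestClassifyLocation:
    def test_plus_strand_promoter_window(self):
        ann = annotation([("g1", "chr1", 10000, 15000, "+")])
        out = classify_location(peakset("A", [9500]), ann)
        assert out.loc[0, "location_class"] == "Promoter"
        assert out.loc[0, "distance_to_nearest_promoter"] == 500

    def test_minus_strand_windows_mirrored(self):
        # "-" gene: TSS at end-1; promoter extends 1 kb downstream in genome
        # coordinates, so a centre 500 bp above the TSS is Promoter,
        # 1500 bp above is not
        ann = annotation([("g1", "chr1", 10000, 15000, "-")])
        tss = 14999
        out = classify_location(peakset("A", [tss + 500, tss + 1500]), ann)
        assert list(out["location_class"]) == ["Promoter", "Intergenic"]

    def test_far_peak_is_intergenic(self):
        ann = annotation([("g1", "chr1", 10000, 15000, "+")])
        out = classify_location(peakset("A", [20000]), ann)
        assert out.loc[0, "location_class"] == "Intergenic"

    def test_tts_and_genic(self):
        ann = annotation([("g1", "chr1", 10000, 20000, "+")])
        out = classify_location(peakset("A", [15000, 19950]), ann)
        assert list(out["location_class"]) == ["Genic", "TTS"]

    def test_promoter_precedence_over_tts_for_short_gene(self):
        ann = annotation([("g1", "chr1", 10000, 10500, "+")])
        out = classify_location(peakset("A", [10050]), ann)
        assert out.loc[0, "location_class"] == "Promoter"

    def test_proportions_partition_every_peak(self):
        ann = annotation([("g1", "chr1", 10000, 20000, "+")])
        out = classify_location(peakset("A", [9500, 15000, 19990, 40000]), ann)
        props = location_proportions(out)
        assert props.sum() == pytest.approx(1.0)
        assert (props > 0).sum() == 4


class TestAssignPeaksToGenes:
    def test_single_tss_within_10kb_assigned(self):
        ann = annotation([("g1", "chr1", 14000, 20000, "+")])
        assigned, bound = assign_peaks_to_genes(peakset("A", [10000]), ann)
        assert assigned == [["g1"]] and bound == {"g1"}

    def test_intervening_tss_blocks_distal_gene(self):
        # both TSSs on the same side of the peak; gB (3 kb) blocks gA (8 kb)
        ann = annotation(
            [("gA", "chr1", 58000, 60000, "+"), ("gB", "chr1", 53000, 56000, "+")]
        )
        assigned, _ = assign_peaks_to_genes(peakset("A", [50000]), ann)
        assert assigned == [["gB"]]

    def test_distance_bound(self):
        ann = annotation([("g1", "chr1", 22000, 30000, "+")])
        assigned, bound = assign_peaks_to_genes(peakset("A", [10000]), ann)
        assert assigned == [[]] and bound == set()

    def test_one_gene_per_side(self):
        ann = annotation(
            [("gL", "chr1", 2000, 6000, "-"), ("gR", "chr1", 14000, 20000, "+")]
        )
        assigned, _ = assign_peaks_to_genes(peakset("A", [10000]), ann)
        assert assigned == [["gL", "gR"]]

    def test_missing_tss_errors(self):
        ann = annotation([("g1", "chr1", 10000, 20000, "+")])
        ann.genes = ann.genes.drop(columns="tss")
        with pytest.raises(ValueError, match="TSS"):
            assign_peaks_to_genes(peakset("A", [10000]), ann)


class TestBoundFraction:
    @pytest.mark.parametrize(
        "k,n,pct", [(14, 32, 44), (3, 19, 16), (0, 7, 0), (7, 7, 100)]
    )
    def test_rounded_percentages(self, k, n, pct):
        genes = [f"g{i}" for i in range(n)]
        bound = set(genes[:k])
        assert bound_fraction(genes, bound) == (k, n, pct)


class TestAnnotationTable:
    def test_columns_and_promoter_flag(self):
        ann = annotation([("g1", "chr1", 10000, 20000, "+")])
        out = annotation_table(peakset("A", [9500, 40000]), ann)
        assert out.loc[0, "promoter"] == 1 and out.loc[1, "promoter"] == 0
        assert out.loc[0, "assigned_genes"] == "g1"
        assert {"location_class", "nearest_gene", "distance_to_nearest_promoter"} <= set(
            out.columns
        )


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    centres=st.lists(st.integers(0, 5000), min_size=1, max_size=60),
    threshold=st.integers(1, 600),
)
def test_clustering_property_matches_brute_force(centres, threshold):
    """For arbitrary centre multisets and thresholds, the single-pass scan
    equals the definitional brute-force clustering, and every member lies
    within the threshold of its cluster's index peak."""
    ps = peakset("A", sorted(centres))
    clusters = cluster_peaks([ps], threshold=threshold)
    pooled = {"chr1": [(int(c), i) for i, c in enumerate(sorted(centres))]}
    want = sorted(sorted(tags) for tags in brute_force_clusters(pooled, threshold))
    got = sorted(sorted(i for _, i in c.members) for c in clusters)
    assert got == [list(w) for w in want]
    for c in clusters:
        index_centre = min(c.centres)
        assert all(x - index_centre < threshold for x in c.centres)
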
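"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a 3-donor, 8-time-point differentiation series:
resting cells at D0, activation at D3, then samples 3, 6, 12, 24, 48 and
72 h after the transition (labels D3.3h … D6).  Planted co-expression
modules follow one of three kinetic classes — early-off (high at D0,
silenced across the transition), transient (peaking mid-course) and late-on
(induced at the final time points).  Downstream stages get gene signatures
overlapping the planted modules at a chosen Jaccard, per-factor peak sets
with planted promoter proximity to target modules, and coverage tracks whose
regions reproduce planted archetype profiles (active promoter, CTCF-bound,
inactive).

Each artefact draws from its own RNG stream derived from the master seed, so
regenerating one component does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTrack,
    ExpressionMatrix,
    GenomeAnnotation,
    PeakSet,
    SignatureCollection,
)
from .network import ModulePartition

DEFAULT_TIME_POINTS = ("D0", "D3", "D3.3h", "D3.6h", "D3.12h", "D3.24h", "D5", "D6")

#: Latent temporal templates per kinetic class (unit amplitude, 8 points).
KINETIC_TEMPLATES = {
    "early-off": np.array([1.0, 0.95, 0.8, 0.6, 0.4, 0.2, 0.05, 0.0]),
    "transient": np.array([0.0, 0.25, 0.6, 0.95, 1.0, 0.7, 0.3, 0.05]),
    "late-on": np.array([0.0, 0.02, 0.05, 0.12, 0.3, 0.55, 0.85, 1.0]),
}


@dataclass
class TFSpec:
    """Planted occupancy design for one factor."""

    n_peaks: int = 300
    target_modules: tuple[int, ...] = ()
    promoter_fraction: float = 0.6
    co_occupancy: dict[str, float] = field(default_factory=dict)


@dataclass
class TrackArchetype:
    """Per-track bin-profile templates (unit scale) for one region class."""

    profiles: dict[str, np.ndarray]
    weight: float = 1.0


def _default_archetypes(n_bins: int = 40) -> dict[str, TrackArchetype]:
    x = np.linspace(-1, 1, n_bins)
    bimodal = np.exp(-((np.abs(x) - 0.35) ** 2) / 0.04)
    sharp = np.exp(-(x**2) / 0.01)
    broad = np.exp(-(x**2) / 0.18)
    flat_low = np.full(n_bins, 0.05)
    return {
        "active_promoter": TrackArchetype(
            {"H3K4me3": 8.0 * bimodal, "H3K27ac": 6.0 * broad, "CTCF": 0.3 * broad},
            weight=0.4,
        ),
        "ctcf_bound": TrackArchetype(
            {"H3K4me3": 0.4 * broad, "H3K27ac": 0.4 * broad, "CTCF": 8.0 * sharp},
            weight=0.3,
        ),
        "inactive": TrackArchetype(
            {"H3K4me3": flat_low, "H3K27ac": flat_low, "CTCF": flat_low},
            weight=0.3,
        ),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated differentiation experiment."""

    n_genes: int = 2000
    n_modules: int = 8
    module_sizes: tuple[int, ...] | None = None  # default: 100 genes each
    kinetic_classes: tuple[str, ...] | None = None  # default: cycle 3 classes
    n_donors: int = 3
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    amplitude: float = 3.0  # log2 dynamic range of module profiles
    noise_sd: float = 0.5
    donor_effect_sd: float = 0.2
    profile_jitter_sd: float = 0.25  # separates same-class modules
    rng_seed: int = 0
    # genome layout
    n_chroms: int = 4
    gene_spacing: int = 40000
    gene_length_range: tuple[int, int] = (2000, 8000)
    # occupancy design
    tf_specs: dict[str, TFSpec] | None = None
    track_archetypes: dict[str, TrackArchetype] | None = None
    track_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = tuple([100] * self.n_modules)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes must sum to at most n_genes")
        if self.kinetic_classes is None:
            cycle = list(KINETIC_TEMPLATES)
            self.kinetic_classes = tuple(
                cycle[i % len(cycle)] for i in range(self.n_modules)
            )
        unknown = set(self.kinetic_classes) - set(KINETIC_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown kinetic classes: {unknown}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tf_specs is None:
            self.tf_specs = self._default_tf_specs()
        for name, spec in self.tf_specs.items():
            for m in spec.target_modules:
                if not (1 <= m <= self.n_modules):
                    raise ValueError(f"{name}: target module {m} does not exist")
            if not (0 <= spec.promoter_fraction <= 1):
                raise ValueError(f"{name}: promoter_fraction outside [0,1]")
            for other, frac in spec.co_occupancy.items():
                if not (0 <= frac <= 1):
                    raise ValueError(f"{name}->{other}: co-occupancy outside [0,1]")
        if self.track_archetypes is None:
            self.track_archetypes = _default_archetypes()

    def _default_tf_specs(self) -> dict[str, "TFSpec"]:
        """Three factors with disjoint target modules plus an untargeted
        CTCF-style set; peak counts scale with the target pool so 60% of a
        factor's peaks sit at promoters of 90% of its target genes."""

        def clip(mods):
            mods = tuple(m for m in mods if m <= self.n_modules)
            return mods or (1,)

        def spec(mods, **kw):
            pool = sum(self.module_sizes[m - 1] for m in mods)
            return TFSpec(int(round(1.5 * pool)), mods, 0.6, **kw)

        return {
            "BLIMP1": spec(clip((1, 2))),
            "IRF4": spec(clip((3, 4)), co_occupancy={"CTCF": 0.3}),
            "XBP1": spec(clip((5, 6))),
            "CTCF": TFSpec(250, (), 0.0),
        }

    def stream(self, artefact: str) -> np.random.Generator:
        """Independent RNG stream per artefact, derived from the master seed."""
        import zlib

        key = zlib.crc32(artefact.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ModulePartition]:
    """Planted-module expression series plus the ground-truth partition.

    Every module draws a latent profile (its kinetic-class template plus a
    module-specific jitter so same-class modules stay separable); member
    genes share that profile up to a gene-level amplitude scaling, a
    gene-level baseline, a per-(gene, donor) offset and i.i.d. Gaussian
    noise.  Background genes are pure baseline noise.
    """
    rng = config.stream("expression")
    genes = _gene_ids(config.n_genes)
    tps = list(config.time_points)
    samples, meta = [], {}
    for tp in tps:
        for d in range(1, config.n_donors + 1):
            name = f"{tp}.{d}"
            samples.append(name)
            meta[name] = {"time_point": tp, "donor": d, "condition": "standard"}

    values = np.empty((config.n_genes, len(samples)))
    assignment = {}
    cursor = 0
    module_profiles = {}
    for m, (size, kin) in enumerate(
        zip(config.module_sizes, config.kinetic_classes), start=1
    ):
        template = KINETIC_TEMPLATES[kin]
        profile = template + rng.normal(0, config.profile_jitter_sd, len(tps))
        module_profiles[m] = (kin, profile)
        member = genes[cursor : cursor + size]
        offset = cursor
        cursor += size
        for g_local, gene in enumerate(member):
            assignment[gene] = m
            scale = rng.uniform(0.7, 1.3) * config.amplitude
            baseline = rng.normal(7.0, 1.0)
            donor_off = rng.normal(0, config.donor_effect_sd, config.n_donors)
            row = np.empty(len(samples))
            for s, name in enumerate(samples):
                t = tps.index(meta[name]["time_point"])
                d = meta[name]["donor"] - 1
                row[s] = baseline + scale * profile[t] + donor_off[d]
            values[offset + g_local] = row
    # background genes: uncorrelated baseline noise
    for gi in range(cursor, config.n_genes):
        values[gi] = rng.normal(7.0, 1.0) * np.ones(len(samples))
    values += rng.normal(0, config.noise_sd, values.shape) if config.noise_sd else 0.0

    em = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        pd.DataFrame.from_dict(meta, orient="index").rename_axis("sample"),
    )
    assign = pd.Series(assignment, name="module")
    meta_rows = pd.DataFrame(
        {
            "size": pd.Series(config.module_sizes, index=range(1, config.n_modules + 1)),
            "name": [f"M{m}" for m in range(1, config.n_modules + 1)],
            "kinetic_class": list(config.kinetic_classes),
        }
    )
    truth = ModulePartition(
        assignment=assign,
        stability=pd.Series(1.0, index=assign.index),
        module_meta=meta_rows,
        n_iterations=0,
    )
    return em, truth


def simulate_signatures(
    truth: ModulePartition,
    config: SyntheticConfig,
    n_sets: int = 30,
    jaccard_with_truth: float = 0.5,
    decoy_size_range: tuple[int, int] = (20, 300),
) -> SignatureCollection:
    """Signatures overlapping the planted modules at a requested Jaccard,
    padded with uniformly drawn decoy sets.

    A planted signature for a module of m genes keeps size m with overlap
    o = round(2 m j / (1 + j)), which yields Jaccard j against the module.
    Decoy sizes are log-uniform over ``decoy_size_range``.
    """
    rng = config.stream("signatures")
    universe = np.array(_gene_ids(config.n_genes))
    sets: dict[str, list[str]] = {}
    module_sets = truth.as_sets()
    for m in sorted(module_sets):
        mod = sorted(module_sets[m])
        size = len(mod)
        j = jaccard_with_truth
        o = int(round(2 * size * j / (1 + j))) if j > 0 else 0
        o = min(o, size)
        inside = list(rng.choice(mod, size=o, replace=False))
        outside_pool = np.array(sorted(set(universe) - set(mod)))
        outside = list(rng.choice(outside_pool, size=size - o, replace=False))
        sets[f"SIG_M{m}"] = inside + outside
    n_decoys = max(0, n_sets - len(sets))
    lo, hi = decoy_size_range
    for i in range(n_decoys):
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        sets[f"DECOY_{i:03d}"] = list(rng.choice(universe, size=size, replace=False))
    return SignatureCollection(sets, source="synthetic")


def simulate_genome(config: SyntheticConfig) -> GenomeAnnotation:
    """Genes laid out at fixed spacing across ``n_chroms`` chromosomes,
    alternating strand, with lengths well below the spacing so that
    intergenic midpoints sit > 10 kb from every TSS."""
    rng = config.stream("genome")
    genes = _gene_ids(config.n_genes)
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    rows = []
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = 10000 + slot * config.gene_spacing
        length = int(rng.integers(*config.gene_length_range))
        strand = "+" if i % 2 == 0 else "-"
        end = start + length
        rows.append(
            {
                "gene_id": gene,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": start if strand == "+" else end - 1,
            }
        )
    df = pd.DataFrame(rows)
    chrom_sizes = {
        chrom: int(grp["end"].max() + config.gene_spacing)
        for chrom, grp in df.groupby("chrom")
    }
    return GenomeAnnotation(df, chrom_sizes)


def simulate_peaks(
    config: SyntheticConfig, truth: ModulePartition, ann: GenomeAnnotation
) -> tuple[dict[str, PeakSet], dict[str, list[str]]]:
    """Per-factor peak sets with planted promoter proximity.

    For each factor, ``promoter_fraction`` of its peaks land inside the
    promoter window of genes sampled from its target modules (at most one
    peak per gene, so the 10-kb/no-intervening-TSS rule assigns each peak to
    its planted gene); the remainder sit at intergenic midpoints > 10 kb from
    any TSS.  Co-occupancy adds, for a fraction of a factor's peaks, a peak
    of the partner factor within ±100 bp of the same centre.  Returns the
    peak sets plus the planted target genes per factor.
    """
    rng = config.stream("peaks")
    gene_rows = ann.genes.set_index("gene_id")
    module_sets = truth.as_sets()
    peak_rows: dict[str, list[tuple[str, int, int]]] = {
        name: [] for name in config.tf_specs
    }
    targets: dict[str, list[str]] = {}
    intergenic_pool = []
    for chrom, grp in ann.genes.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        for a, b in zip(starts[:-1], starts[1:]):
            # midpoint of consecutive gene starts: with genes much shorter
            # than the spacing this stays > 10 kb from every TSS even after
            # the placement jitter below
            intergenic_pool.append((chrom, (a + b) // 2))

    for name in sorted(config.tf_specs):
        spec = config.tf_specs[name]
        n_prom = int(round(spec.promoter_fraction * spec.n_peaks))
        pool = sorted(set().union(*(module_sets[m] for m in spec.target_modules))) if spec.target_modules else []
        if n_prom > len(pool):
            raise ValueError(
                f"{name}: {n_prom} promoter peaks requested but only "
                f"{len(pool)} target-module genes available"
            )
        chosen = list(rng.choice(pool, size=n_prom, replace=False)) if n_prom else []
        targets[name] = chosen
        for gene in chosen:
            row = gene_rows.loc[gene]
            off = int(rng.integers(-500, 50))
            centre = int(row["tss"]) + (off if row["strand"] == "+" else -off)
            peak_rows[name].append((row["chrom"], centre - 100, centre + 100))
        n_inter = spec.n_peaks - n_prom
        idx = rng.choice(len(intergenic_pool), size=n_inter, replace=False)
        for i in idx:
            chrom, mid = intergenic_pool[int(i)]
            centre = int(mid + rng.integers(-1500, 1500))
            peak_rows[name].append((chrom, centre - 100, centre + 100))

    # co-occupancy: partner peaks within the overlap-cluster distance
    for name in sorted(config.tf_specs):
        spec = config.tf_specs[name]
        for other, frac in sorted(spec.co_occupancy.items()):
            if other not in peak_rows:
                raise ValueError(f"{name}: co-occupancy partner {other} unknown")
            n_co = int(round(frac * len(peak_rows[name])))
            idx = rng.choice(len(peak_rows[name]), size=n_co, replace=False)
            for i in idx:
                chrom, s, e = peak_rows[name][int(i)]
                centre = (s + e) // 2 + int(rng.integers(-100, 101))
                peak_rows[other].append((chrom, centre - 100, centre + 100))

    peak_sets = {
        name: PeakSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        for name, rows in peak_rows.items()
    }
    return peak_sets, targets


def simulate_tracks(
    config: SyntheticConfig,
    regions: pd.DataFrame,
    half_width: int = 1000,
    bin_size: int = 50,
) -> tuple[dict[str, CoverageTrack], pd.Series]:
    """Coverage tracks reproducing planted archetype profiles at each region.

    Each region is assigned an archetype by the configured weights; around
    its centre every track gets the archetype's bin-profile template plus
    truncated Gaussian noise, written as stepwise bedGraph-style coverage.
    Returns the tracks and the ground-truth region -> archetype labels.
    """
    rng = config.stream("tracks")
    n_bins = 2 * half_width // bin_size
    arch_names = sorted(config.track_archetypes)
    weights = np.array([config.track_archetypes[a].weight for a in arch_names])
    weights = weights / weights.sum()
    labels = rng.choice(arch_names, size=len(regions), p=weights)

    track_names = sorted(
        {t for a in config.track_archetypes.values() for t in a.profiles}
    )
    # rasterize per track on a bin grid, resolving overlaps by max
    grids: dict[str, dict[str, dict[int, float]]] = {t: {} for t in track_names}
    for (_, row), arch in zip(regions.iterrows(), labels):
        chrom, centre = row["chrom"], int(row["centre"])
        start = centre - half_width
        for t in track_names:
            template = config.track_archetypes[arch].profiles[t]
            if len(template) != n_bins:
                template = np.interp(
                    np.linspace(0, 1, n_bins), np.linspace(0, 1, len(template)), template
                )
            vals = np.clip(
                template + rng.normal(0, config.track_noise_sd, n_bins), 0, None
            )
            grid = grids[t].setdefault(chrom, {})
            for b in range(n_bins):
                # snap to a global grid so bins from nearby regions align
                pos = (start + b * bin_size) // bin_size * bin_size
                if pos < 0:
                    continue
                grid[pos] = max(grid.get(pos, 0.0), float(vals[b]))
    tracks = {}
    for t in track_names:
        intervals = {}
        for chrom, grid in grids[t].items():
            pos = np.array(sorted(grid))
            starts = pos
            ends = pos + bin_size
            values = np.array([grid[p] for p in pos])
            keep = values > 0
            intervals[chrom] = (starts[keep], ends[keep], values[keep])
        tracks[t] = CoverageTrack(intervals)
    truth = pd.Series(labels, index=regions["region_id"].to_numpy(), name="archetype")
    return tracks, truth
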
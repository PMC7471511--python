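"""Readers, writers and validated containers for the external formats the
pipeline touches.

All genomic intervals are 0-based half-open (BED convention) throughout the
package; anything 1-based is converted at the boundary.  Peak centres of
even-length intervals are the floor of the midpoint, so all centre arithmetic
stays in integers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Column headers of an expression TSV encode sample metadata as
# TIMEPOINT.DONOR[.CONDITION], where the time point is a day label optionally
# followed by an hour offset, e.g. "D3.12h.2" or "D6.1.DMSO".
_SAMPLE_RE = re.compile(r"^(D\d+(?:\.\d+h)?)\.(\d+)(?:\.([A-Za-z0-9_\-]+))?$")


def _time_key(label: str) -> tuple[float, float]:
    """Sort key for time-point labels like D0, D3, D3.12h, D6."""
    m = re.match(r"^D(\d+)(?:\.(\d+)h)?$", label)
    if m is None:
        raise ValueError(f"unparseable time-point label: {label!r}")
    return float(m.group(1)), float(m.group(2) or 0)


@dataclass
class ExpressionMatrix:
    """Log2 intensities per (gene, sample) with time-course sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.
    sample_meta
        DataFrame indexed by sample name with columns ``time_point``,
        ``donor`` and ``condition``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene id: {dup[0]}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("time_point", "donor"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
            if self.sample_meta[col].isna().any():
                raise ValueError(f"sample_meta column {col!r} has missing values")
        if "condition" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(condition="standard")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite")
        all_missing = self.values.index[np.isnan(arr).all(axis=1)]
        if len(all_missing):
            log.warning("dropping %d genes with all-missing values", len(all_missing))
            self.values = self.values.drop(index=all_missing)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def time_points(self) -> list[str]:
        """Unique time-point labels in temporal order."""
        return sorted(self.sample_meta["time_point"].unique(), key=_time_key)

    @property
    def donors(self) -> list:
        return sorted(self.sample_meta["donor"].unique())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.sample_meta.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples].copy(), self.sample_meta.loc[samples].copy()
        )


def parse_sample_label(label: str) -> tuple[str, int, str]:
    """Split TIMEPOINT.DONOR[.CONDITION] into its parts."""
    m = _SAMPLE_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable sample header: {label!r}")
    return m.group(1), int(m.group(2)), m.group(3) or "standard"


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample TSV whose header encodes sample metadata.

    The first column holds gene ids; remaining columns are named
    ``TIMEPOINT.DONOR[.CONDITION]``.  Genes with all values missing are
    dropped with a warning; a duplicated gene id is a hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    meta = {}
    for col in df.columns:
        tp, donor, cond = parse_sample_label(col)
        meta[col] = {"time_point": tp, "donor": donor, "condition": cond}
    sample_meta = pd.DataFrame.from_dict(meta, orient="index")
    sample_meta.index.name = "sample"
    return ExpressionMatrix(df.astype(float), sample_meta)


def write_expression(em: ExpressionMatrix, path) -> None:
    out = em.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


@dataclass
class GenomeAnnotation:
    """Gene bodies with strand-aware TSS positions plus chromosome sizes.

    ``genes`` columns: gene_id, chrom, start, end, strand, tss.  Intervals are
    0-based half-open; the TSS is ``start`` on "+" and ``end - 1`` on "-".
    """

    genes: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(g.columns):
            raise ValueError(f"annotation missing columns {required - set(g.columns)}")
        if "tss" not in g.columns:
            g = g.assign(tss=np.where(g["strand"] == "+", g["start"], g["end"] - 1))
        expected = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        if not (g["tss"].to_numpy() == expected).all():
            raise ValueError("tss inconsistent with start/end/strand")
        if (g["start"] >= g["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        for _, row in g.iterrows():
            size = self.chrom_sizes.get(row["chrom"])
            if size is None:
                raise ValueError(f"gene {row['gene_id']} on unknown chrom {row['chrom']}")
            if not (0 <= row["tss"] < size):
                raise ValueError(f"tss of {row['gene_id']} outside chrom bounds")
        self.genes = g.reset_index(drop=True)

    def tss_by_chrom(self) -> dict[str, pd.DataFrame]:
        """Genes per chromosome sorted by TSS position."""
        return {
            chrom: grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
            for chrom, grp in self.genes.groupby("chrom")
        }


def read_annotation(path, chrom_sizes: dict[str, int]) -> GenomeAnnotation:
    """Read a BED6-like gene annotation: chrom start end gene_id score strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = df[["gene_id", "chrom", "start", "end", "strand"]]
    return GenomeAnnotation(genes, dict(chrom_sizes))


def write_annotation(ann: GenomeAnnotation, path) -> None:
    g = ann.genes
    out = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": g["start"],
            "end": g["end"],
            "gene_id": g["gene_id"],
            "score": 0,
            "strand": g["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class PeakSet:
    """A named set of genomic intervals with integer centres.

    ``peaks`` columns: chrom, start, end, centre and optionally score.
    Sorted by (chrom, centre); the centre is floor((start + end) / 2).
    """

    name: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.peaks
        if not {"chrom", "start", "end"}.issubset(p.columns):
            raise ValueError("peaks need chrom/start/end columns")
        if (p["start"] >= p["end"]).any():
            bad = p.index[(p["start"] >= p["end"])][0]
            raise ValueError(f"peak {bad}: start >= end")
        if "centre" not in p.columns:
            p = p.assign(centre=(p["start"] + p["end"]) // 2)
        p = p.sort_values(["chrom", "centre"], kind="mergesort").reset_index(drop=True)
        self.peaks = p

    def __len__(self) -> int:
        return len(self.peaks)


def read_bed(path, name: str | None = None, chrom_sizes: dict[str, int] | None = None) -> PeakSet:
    """Read a BED3+ file into a PeakSet; malformed intervals name the line."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: expected at least 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{i}: start >= end ({start} >= {end})")
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is None or end > size:
                    raise ValueError(f"{path}:{i}: interval outside chrom bounds")
            score = float(parts[4]) if len(parts) >= 5 else np.nan
            rows.append((chrom, start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if df["score"].isna().all():
        df = df.drop(columns="score")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return PeakSet(name, df)


def write_bed(ps: PeakSet, path) -> None:
    p = ps.peaks
    cols = [p["chrom"], p["start"], p["end"]]
    if "score" in p.columns:
        cols += [pd.Series([ps.name] * len(p)), p["score"]]
    pd.concat(cols, axis=1).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SignatureCollection:
    """Named gene sets (GMT-style), gene ids uppercased."""

    sets: dict[str, list[str]]
    source: str = "unknown"

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            up = [str(g).upper() for g in genes]
            seen: dict[str, None] = {}
            for g in up:
                if g in seen:
                    log.warning("set %s: duplicate gene %s deduplicated", name, g)
                seen[g] = None
            if not seen:
                log.warning("dropping empty signature set %s", name)
                continue
            clean[name] = list(seen)
        self.sets = clean

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: str | None = None) -> SignatureCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if source is None:
        import os

        source = os.path.splitext(os.path.basename(str(path)))[0]
    return SignatureCollection(sets, source=source)


def write_gmt(sc: SignatureCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sc.sets.items():
            fh.write("\t".join([name, sc.source] + list(genes)) + "\n")


class CoverageTrack:
    """Stepwise coverage (bedGraph semantics): sorted non-overlapping
    intervals per chromosome; anything uncovered has value 0.

    Interval means are computed from a cumulative integral per chromosome,
    so any window query is O(log n).
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="mergesort")
            starts, ends, values = starts[order], ends[order], values[order]
            if (starts >= ends).any():
                raise ValueError(f"{chrom}: empty or inverted interval")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping intervals")
            # cumulative integral evaluated at interval starts
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def total_mass(self) -> float:
        """Integral of the track over the whole genome (signal x bp)."""
        return float(sum(d[3][-1] for d in self._data.values()))

    def _integral_to(self, chrom: str, pos: int) -> float:
        starts, ends, values, cum = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return 0.0
        inside = min(max(pos - starts[i], 0), ends[i] - starts[i])
        return float(cum[i] + values[i] * inside)

    def integral(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self._data or end <= start:
            return 0.0
        return self._integral_to(chrom, end) - self._integral_to(chrom, start)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end); uncovered bases count as 0."""
        if end <= start:
            return 0.0
        return self.integral(chrom, start, end) / (end - start)

    def bin_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        edges = np.linspace(start, end, n_bins + 1).astype(np.int64)
        if chrom not in self._data:
            return np.zeros(n_bins)
        ints = np.array([self._integral_to(chrom, int(e)) for e in edges])
        widths = np.diff(edges)
        return np.diff(ints) / widths


def read_bedgraph(path) -> CoverageTrack:
    """Read a sorted bedGraph; overlapping intervals are a hard error."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    intervals = {
        chrom: (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(),
        )
        for chrom, grp in df.groupby("chrom")
    }
    return CoverageTrack(intervals)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values, _ = track._data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
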
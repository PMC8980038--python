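"""Fragment records, Tn5 fragment-length classes, and read-extremity binning.

In ATAC-seq the two termini of each sequenced fragment mark positions where
the transposase could insert, i.e. accessible DNA.  This module reads
paired-end fragment records (BED3+ or coordinate-sorted BAM/SAM), classifies
them by length into subnucleosomal (<=140 bp), nucleosomal (141-280 bp) and
poly-nucleosomal (>=281 bp) classes, and counts fragment extremities over a
fixed-width tiling of the genome (default 100 bp).

Coordinates are 0-based half-open throughout.  Each fragment contributes
exactly two extremities, at positions ``start`` and ``end - 1``; no Tn5
+4/-5 offset is applied by default (``tn5_shift`` enables it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Longest fragment (bp) still called subnucleosomal.
SUBNUCLEOSOMAL_MAX = 140
#: Longest fragment (bp) still called nucleosomal; longer is poly-nucleosomal.
NUCLEOSOMAL_MAX = 280

LENGTH_CLASSES = ("subnucleosomal", "nucleosomal", "polynucleosomal")


def classify_length(length: int) -> str:
    """Assign a fragment length (bp) to its nucleosome-occupancy class.

    Subnucleosomal fragments (<=140 bp) arise from two insertions in open
    DNA, nucleosomal fragments (141-280 bp) span one nucleosome, and
    poly-nucleosomal fragments (>=281 bp) span two or more.

    Raises
    ------
    ValueError
        If ``length`` < 1 (a fragment has at least one base).
    """
    if length < 1:
        raise ValueError(f"fragment length must be >= 1, got {length}")
    if length <= SUBNUCLEOSOMAL_MAX:
        return "subnucleosomal"
    if length <= NUCLEOSOMAL_MAX:
        return "nucleosomal"
    return "polynucleosomal"


def classify_lengths(lengths: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_length`; returns an array of class names."""
    lengths = np.asarray(lengths)
    if lengths.size and lengths.min() < 1:
        raise ValueError("fragment lengths must be >= 1")
    out = np.where(
        lengths <= SUBNUCLEOSOMAL_MAX,
        "subnucleosomal",
        np.where(lengths <= NUCLEOSOMAL_MAX, "nucleosomal", "polynucleosomal"),
    )
    return out


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment: chrom, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid fragment {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_class(self) -> str:
        return classify_length(self.length)


class GenomeBinning:
    """Fixed-width tiling of a genome into contiguous half-open bins.

    Bins on each chromosome are ``[i*w, (i+1)*w)`` with the last bin
    truncated at the chromosome end, so every genomic position belongs to
    exactly one bin and the total bin count is ``sum(ceil(len/w))``.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.  Order is preserved and
        defines the global bin index.
    bin_width
        Bin width in bp (default 100).
    """

    def __init__(self, chrom_sizes: Mapping[str, int], bin_width: int = 100):
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if not chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        for name, size in chrom_sizes.items():
            if size < 1:
                raise ValueError(f"chromosome {name!r} has non-positive size {size}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.bin_width = int(bin_width)
        self._chrom_bins: dict[str, int] = {
            c: -(-size // self.bin_width) for c, size in self.chrom_sizes.items()
        }
        self._offsets: dict[str, int] = {}
        off = 0
        for c, nb in self._chrom_bins.items():
            self._offsets[c] = off
            off += nb
        self.n_bins: int = off
        self._chroms = list(self.chrom_sizes)
        self._offset_array = np.array(
            [self._offsets[c] for c in self._chroms] + [self.n_bins]
        )

    @classmethod
    def from_chrom_sizes_file(cls, path: str | Path, bin_width: int = 100) -> "GenomeBinning":
        """Build from a UCSC chrom.sizes file (``name<TAB>length``)."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name length'")
                sizes[parts[0]] = int(parts[1])
        return cls(sizes, bin_width=bin_width)

    def n_bins_chrom(self, chrom: str) -> int:
        return self._chrom_bins[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of position ``pos`` on ``chrom``."""
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < size):
            raise ValueError(f"position {pos} outside {chrom} [0,{size})")
        return self._offsets[chrom] + pos // self.bin_width

    def bin_indices(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_index` for positions on one chromosome."""
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        positions = np.asarray(positions)
        if positions.size and (positions.min() < 0 or positions.max() >= size):
            raise ValueError(f"positions outside {chrom} [0,{size})")
        return self._offsets[chrom] + positions // self.bin_width

    def bin_coords(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index."""
        if not (0 <= index < self.n_bins):
            raise IndexError(index)
        ci = int(np.searchsorted(self._offset_array, index, side="right")) - 1
        chrom = self._chroms[ci]
        local = index - self._offsets[chrom]
        start = local * self.bin_width
        end = min(start + self.bin_width, self.chrom_sizes[chrom])
        return chrom, start, end

    def bin_table(self, indices: np.ndarray) -> pd.DataFrame:
        """DataFrame (chrom, start, end) for an array of global bin indices."""
        indices = np.asarray(indices)
        ci = np.searchsorted(self._offset_array, indices, side="right") - 1
        chroms = np.array(self._chroms, dtype=object)[ci]
        local = indices - self._offset_array[ci]
        start = local * self.bin_width
        end = np.minimum(
            start + self.bin_width,
            np.array([self.chrom_sizes[c] for c in self._chroms])[ci],
        )
        return pd.DataFrame({"chrom": chroms, "start": start, "end": end})


@dataclass
class ReadReport:
    """Tally of records seen while reading a fragment file."""

    n_read: int = 0
    n_dropped_unknown_chrom: int = 0
    n_rejected: int = 0
    class_counts: dict = field(default_factory=lambda: {c: 0 for c in LENGTH_CLASSES})


def _iter_bed(path: str | Path) -> Iterator[tuple[int, str, str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            yield lineno, parts[0], parts[1], parts[2]


def _iter_bam(path: str | Path) -> Iterator[FragmentRecord]:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
            ):
                continue
            # Count each template once, from the leftmost mate.
            if read.template_length <= 0:
                continue
            start = read.reference_start
            end = start + read.template_length
            yield FragmentRecord(read.reference_name, start, end)


def read_fragments(
    path: str | Path,
    binning: GenomeBinning,
    report: ReadReport | None = None,
) -> Iterator[FragmentRecord]:
    """Stream validated :class:`FragmentRecord` from a BED3+ or BAM/SAM file.

    Fragments on chromosomes absent from ``binning`` are dropped (tallied in
    ``report``); zero-length or inverted records are rejected and logged.
    Malformed BED lines raise :class:`ValueError` with the line number.
    """
    if report is None:
        report = ReadReport()
    path = Path(path)
    if path.suffix in {".bam", ".sam", ".cram"}:
        source: Iterable = ((None, rec) for rec in _iter_bam(path))
        for _, rec in source:
            report.n_read += 1
            if rec.chrom not in binning.chrom_sizes:
                report.n_dropped_unknown_chrom += 1
                continue
            if rec.end > binning.chrom_sizes[rec.chrom]:
                report.n_rejected += 1
                logger.warning("fragment beyond chromosome end rejected: %s", rec)
                continue
            report.class_counts[rec.length_class] += 1
            yield rec
        return
    for lineno, chrom, s, e in _iter_bed(path):
        report.n_read += 1
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if chrom not in binning.chrom_sizes:
            report.n_dropped_unknown_chrom += 1
            continue
        if end <= start or start < 0 or end > binning.chrom_sizes[chrom]:
            report.n_rejected += 1
            logger.warning("%s:%d: invalid interval [%d,%d) rejected", path, lineno, start, end)
            continue
        rec = FragmentRecord(chrom, start, end)
        report.class_counts[rec.length_class] += 1
        yield rec


def load_fragment_table(path: str | Path, binning: GenomeBinning) -> pd.DataFrame:
    """Load a fragment file into a DataFrame (chrom, start, end, length).

    Applies the same validation and dropping rules as :func:`read_fragments`;
    for BED input this is a vectorized fast path.
    """
    path = Path(path)
    if path.suffix in {".bam", ".sam", ".cram"}:
        recs = list(read_fragments(path, binning))
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in recs],
                "start": np.array([r.start for r in recs], dtype=np.int64),
                "end": np.array([r.end for r in recs], dtype=np.int64),
                "length": np.array([r.length for r in recs], dtype=np.int64),
            }
        )
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    known = df["chrom"].map(binning.chrom_sizes)
    keep = known.notna()
    n_unknown = int((~keep).sum())
    if n_unknown:
        logger.info("%s: dropped %d fragments on unknown chromosomes", path, n_unknown)
    df = df[keep].copy()
    sizes = df["chrom"].map(binning.chrom_sizes).to_numpy()
    valid = (df["start"].to_numpy() >= 0) & (df["end"].to_numpy() > df["start"].to_numpy()) & (
        df["end"].to_numpy() <= sizes
    )
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%s: rejected %d invalid fragment records", path, n_bad)
    df = df[valid].reset_index(drop=True)
    df["length"] = df["end"] - df["start"]
    return df


def count_extremities(
    fragments: Iterable[FragmentRecord] | pd.DataFrame,
    binning: GenomeBinning,
    class_filter: str | None = "subnucleosomal",
    tn5_shift: bool = False,
) -> np.ndarray:
    """Count fragment extremities per genome bin for one library.

    Each fragment contributes two extremities, at ``start`` and ``end - 1``.
    ``class_filter`` restricts to one length class (default subnucleosomal,
    the class carrying the sharpest accessibility signal); ``None`` keeps all
    fragments.  With ``tn5_shift`` the canonical +4/-5 transposase offset is
    applied (clipped at chromosome ends); off by default.

    Returns a dense ``int64`` vector of length ``binning.n_bins`` whose sum
    is exactly twice the number of counted fragments.
    """
    if class_filter is not None and class_filter not in LENGTH_CLASSES:
        raise ValueError(f"unknown length class {class_filter!r}")
    counts = np.zeros(binning.n_bins, dtype=np.int64)
    if isinstance(fragments, pd.DataFrame):
        df = fragments
        if class_filter is not None:
            df = df[classify_lengths(df["length"].to_numpy()) == class_filter]
        for chrom, sub in df.groupby("chrom", sort=False):
            size = binning.chrom_sizes[chrom]
            left = sub["start"].to_numpy()
            right = sub["end"].to_numpy() - 1
            if tn5_shift:
                left = np.minimum(left + 4, size - 1)
                right = np.maximum(right - 5, 0)
            idx = np.concatenate(
                [binning.bin_indices(chrom, left), binning.bin_indices(chrom, right)]
            )
            counts += np.bincount(idx, minlength=binning.n_bins)
        return counts
    for rec in fragments:
        if class_filter is not None and rec.length_class != class_filter:
            continue
        size = binning.chrom_sizes[rec.chrom]
        left, right = rec.start, rec.end - 1
        if tn5_shift:
            left = min(left + 4, size - 1)
            right = max(right - 5, 0)
        counts[binning.bin_index(rec.chrom, left)] += 1
        counts[binning.bin_index(rec.chrom, right)] += 1
    return counts


def write_counts_tsv(counts: np.ndarray, binning: GenomeBinning, path: str | Path) -> None:
    """Write non-zero bins as ``chrom  bin_start  bin_end  count``."""
    nz = np.flatnonzero(counts)
    table = binning.bin_table(nz)
    table["count"] = counts[nz]
    table.to_csv(path, sep="\t", header=False, index=False)


def read_counts_tsv(path: str | Path, binning: GenomeBinning) -> np.ndarray:
    """Read a sparse counts TSV back into a dense per-bin vector."""
    counts = np.zeros(binning.n_bins, dtype=np.int64)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "count"])
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = binning.bin_indices(chrom, sub["start"].to_numpy())
        counts[idx] += sub["count"].to_numpy()
    return counts
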
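"""Overlap of accessibility intervals with genes, 20-kb gene flanks and cCREs.

Intervals are 0-based half-open everywhere; two intervals overlap when they
share at least one base, so touching intervals do not overlap.  The summary
reports both query-side fractions (how many query intervals hit a feature
category) and feature-side counts (how many features are hit), plus a
mutually-exclusive gene / flank / intergenic breakdown where the gene
category takes precedence over flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Named set of genomic intervals (chrom, start, end[, name])."""

    name: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.intervals.columns):
            raise ValueError(f"feature set {self.name!r} needs columns {need}")
        bad = self.intervals["end"] <= self.intervals["start"]
        if bad.any():
            raise ValueError(f"feature set {self.name!r} has empty/inverted intervals")

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            t = IntervalTree()
            for i, (s, e) in enumerate(zip(sub["start"], sub["end"])):
                t.addi(int(s), int(e), sub.index[i])
            out[chrom] = t
        return out

    def total_bp(self) -> int:
        """Bases covered by the union of the intervals."""
        total = 0
        for _, sub in self.intervals.groupby("chrom", sort=False):
            merged = merge_intervals(sub[["start", "end"]].to_numpy())
            total += int((merged[:, 1] - merged[:, 0]).sum())
        return total


def read_bed_features(path: str | Path, name: str) -> FeatureSet:
    """Read a BED3+ file into a FeatureSet (4th column kept as feature name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"c{i}" for i in range(3, df.shape[1])]
    df.columns = cols
    keep = ["chrom", "start", "end"]
    if "c3" in df.columns:
        df = df.rename(columns={"c3": "name"})
        keep.append("name")
    return FeatureSet(name, df[keep])


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> FeatureSet:
    """Extract gene intervals from a GFF3 file (1-based closed -> half-open)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True)
    rows = []
    for feat in db.features_of_type(feature_type):
        rows.append(
            {
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "name": feat.id,
            }
        )
    return FeatureSet("genes", pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching half-open intervals; returns sorted (n,2)."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=int)
    arr = arr[np.argsort(arr[:, 0])]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=int)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Pieces of half-open interval ``a=(s,e)`` not covered by merged set ``b``."""
    s, e = a
    pieces = []
    cur = s
    for bs, be in b:
        if be <= cur or bs >= e:
            continue
        if bs > cur:
            pieces.append((cur, min(bs, e)))
        cur = max(cur, be)
        if cur >= e:
            break
    if cur < e:
        pieces.append((cur, e))
    return pieces


def make_flanks(
    genes: FeatureSet,
    flank: int = 20000,
    chrom_sizes: dict[str, int] | None = None,
    exclusive: bool = True,
) -> FeatureSet:
    """Build the 20-kb (default) upstream/downstream flanks of each gene.

    Flanks are ``[start - flank, start)`` and ``[end, end + flank)``, clipped
    at chromosome ends when ``chrom_sizes`` is given.  With ``exclusive``
    (default) any part of a flank covered by a gene body is trimmed away, so
    flank intervals never overlap genes — required for the
    mutually-exclusive gene/flank/intergenic summary.
    """
    merged_genes = {
        chrom: merge_intervals(sub[["start", "end"]].to_numpy())
        for chrom, sub in genes.intervals.groupby("chrom", sort=False)
    }
    rows = []
    for _, g in genes.intervals.iterrows():
        chrom = g["chrom"]
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        cands = [
            (max(0, g["start"] - flank), g["start"]),
            (g["end"], g["end"] + flank if size is None else min(size, g["end"] + flank)),
        ]
        for s, e in cands:
            if e <= s:
                continue
            if exclusive:
                for ps, pe in subtract_intervals((s, e), merged_genes[chrom]):
                    rows.append({"chrom": chrom, "start": ps, "end": pe})
            else:
                rows.append({"chrom": chrom, "start": s, "end": e})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FeatureSet("flanks", df)


@dataclass
class OverlapSummary:
    """Query-side and feature-side overlap statistics."""

    n_query: int
    per_set: pd.DataFrame  # name, n_query_overlapping, frac_query, n_features_hit, n_features, genome_bp
    exclusive_fractions: dict = field(default_factory=dict)  # gene/flank/intergenic
    query_flags: pd.DataFrame | None = None  # per-query boolean columns


def overlap_any(query: pd.DataFrame, features: FeatureSet) -> tuple[np.ndarray, set]:
    """Per-query any-overlap flag plus the set of feature row-ids hit."""
    trees = features.trees()
    flags = np.zeros(len(query), dtype=bool)
    hit_ids: set = set()
    for i, (chrom, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        t = trees.get(chrom)
        if t is None:
            continue
        hits = t.overlap(int(s), int(e))
        if hits:
            flags[i] = True
            hit_ids.update(h.data for h in hits)
    return flags, hit_ids


def overlap_summary(
    query: pd.DataFrame,
    feature_sets: list[FeatureSet],
    chrom_sizes: dict[str, int] | None = None,
) -> OverlapSummary:
    """Overlap each query interval against every feature set.

    Raises if query chromosomes are absent from every feature set's namespace
    and from ``chrom_sizes`` (a likely naming mismatch).  When feature sets
    named "genes" and "flanks" are present, a mutually-exclusive
    gene/flank/intergenic breakdown is added, gene taking precedence.
    """
    need = {"chrom", "start", "end"}
    if not need.issubset(query.columns):
        raise ValueError(f"query needs columns {need}")
    known: set[str] = set()
    for fs in feature_sets:
        known |= set(fs.intervals["chrom"])
    if chrom_sizes:
        known |= set(chrom_sizes)
    unknown = sorted(set(query["chrom"]) - known)
    if unknown:
        raise ValueError(f"query chromosomes not in any feature namespace: {unknown}")

    flags = {}
    rows = []
    for fs in feature_sets:
        f, hit_ids = overlap_any(query, fs)
        flags[fs.name] = f
        genome_bp = fs.total_bp()
        rows.append(
            {
                "name": fs.name,
                "n_query_overlapping": int(f.sum()),
                "frac_query": f.mean() if len(query) else 0.0,
                "n_features_hit": len(hit_ids),
                "n_features": len(fs.intervals),
                "feature_bp": genome_bp,
                "genome_frac": (genome_bp / sum(chrom_sizes.values())) if chrom_sizes else np.nan,
            }
        )
    per_set = pd.DataFrame(rows)
    exclusive: dict[str, float] = {}
    if "genes" in flags and "flanks" in flags and len(query):
        in_gene = flags["genes"]
        in_flank = flags["flanks"] & ~in_gene  # gene takes precedence
        exclusive = {
            "gene": float(in_gene.mean()),
            "flank": float(in_flank.mean()),
            "intergenic": float((~in_gene & ~in_flank).mean()),
        }
    query_flags = pd.DataFrame(flags, index=query.index) if flags else None
    return OverlapSummary(
        n_query=len(query),
        per_set=per_set,
        exclusive_fractions=exclusive,
        query_flags=query_flags,
    )
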
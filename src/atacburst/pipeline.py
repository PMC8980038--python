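"""End-to-end orchestration: counting -> differential testing -> ratio curve
-> annotation, with a reproducible run manifest.

`PipelineConfig` is the single home of every tunable threshold; defaults are
the analysis constants of the study design (100-bp bins, subnucleosomal
fragments, mean >= 5 retention, windows of 1000 ranked intervals with step 1,
ratio cutoff 0.60, 20-kb flanks, 80/160 ms burst rule, 60/45/300 s metric
windows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import FeatureSet, make_flanks, overlap_summary, read_bed_features
from .diffaccess import (
    DifferentialResult,
    LibraryProfile,
    differential_analysis,
    exclude_low_count_libraries,
)
from .fragments import GenomeBinning, classify_lengths, count_extremities, load_fragment_table
from .ratio_curve import RatioCurve, RatioSelection, build_ratio_curve, select_by_ratio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, each appearing exactly once."""

    bin_width: int = 100
    class_filter: str = "subnucleosomal"  # length classes: <=140 / 141-280 / >=281 bp
    tn5_shift: bool = False
    min_reads: float = 1.0e7  # library exclusion threshold (fragments)
    min_mean: float = 5.0  # interval retention: mean raw extremities >= 5
    window: int = 1000  # ratio-curve window of p-ranked intervals
    step: int = 1
    ratio_cutoff: float = 0.60
    selection_mode: str = "prefix"
    flank_bp: int = 20_000
    burst_onset_s: float = 0.080
    burst_offset_s: float = 0.160
    metrics_window_s: float = 60.0
    metrics_overlap_s: float = 45.0
    epoch_s: float = 300.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class PipelineResult:
    binning: GenomeBinning
    profiles: list[LibraryProfile]
    excluded: list[LibraryProfile]
    diff: DifferentialResult
    curve: RatioCurve
    selection: RatioSelection
    annotation: object | None = None


def count_library(
    path: str | Path, binning: GenomeBinning, config: PipelineConfig
) -> tuple[np.ndarray, int]:
    """Count class-filtered extremities for one fragment file.

    Returns the per-bin count vector and the number of class-filtered
    fragments (the library's depth for QC purposes).
    """
    df = load_fragment_table(path, binning)
    cls = classify_lengths(df["length"].to_numpy()) if len(df) else np.array([])
    n_class = int((cls == config.class_filter).sum())
    counts = count_extremities(df, binning, config.class_filter, tn5_shift=config.tn5_shift)
    return counts, n_class


def analyze_counts(
    counts: np.ndarray,
    profiles: Sequence[LibraryProfile],
    binning: GenomeBinning,
    config: PipelineConfig,
) -> tuple[DifferentialResult, RatioCurve, RatioSelection]:
    """Differential testing, ratio curve and cutoff selection on a count matrix."""
    diff = differential_analysis(counts, profiles, binning, min_mean=config.min_mean)
    curve = build_ratio_curve(diff.stats, window=config.window, step=config.step)
    selection = select_by_ratio(
        curve, diff.stats, cutoff=config.ratio_cutoff, mode=config.selection_mode
    )
    return diff, curve, selection


def run_pipeline(
    library_table: pd.DataFrame,
    chrom_sizes_path: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
    genes_path: str | Path | None = None,
    ccres_path: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full accessibility pipeline and write TSV outputs + manifest.

    ``library_table`` needs columns library_id, group, path (one fragment
    BED/BAM per library).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for col in ("library_id", "group", "path"):
        if col not in library_table.columns:
            raise ValueError(f"library table misses column {col!r}")
    for p in library_table["path"]:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")
    binning = GenomeBinning.from_chrom_sizes_file(chrom_sizes_path, bin_width=config.bin_width)

    all_counts: dict[str, np.ndarray] = {}
    profiles: list[LibraryProfile] = []
    for _, row in library_table.iterrows():
        counts, n_class = count_library(row["path"], binning, config)
        all_counts[row["library_id"]] = counts
        profiles.append(LibraryProfile(row["library_id"], row["group"], n_class))
    kept, excluded = exclude_low_count_libraries(profiles, min_reads=config.min_reads)
    matrix = np.column_stack([all_counts[p.library_id] for p in kept])
    diff, curve, selection = analyze_counts(matrix, kept, binning, config)

    stats_path = outdir / "interval_stats.tsv"
    diff.stats.to_csv(stats_path, sep="\t", index=False, float_format="%.6g")
    curve_path = outdir / "ratio_curve.tsv"
    curve.points.to_csv(curve_path, sep="\t", index=False, float_format="%.6g")
    sel_path = outdir / "selected_intervals.tsv"
    selection.selected.to_csv(sel_path, sep="\t", index=False, float_format="%.6g")
    lib_path = outdir / "library_profiles.tsv"
    pd.DataFrame(
        [
            {
                "library_id": p.library_id,
                "group": p.group,
                "total_fragments": p.total_fragments,
                "size_factor": p.size_factor,
                "excluded_reason": p.excluded_reason or "",
            }
            for p in profiles
        ]
    ).to_csv(lib_path, sep="\t", index=False, float_format="%.6g")

    annotation = None
    if genes_path is not None:
        genes = read_bed_features(genes_path, "genes")
        flanks = make_flanks(genes, flank=config.flank_bp, chrom_sizes=binning.chrom_sizes)
        feature_sets: list[FeatureSet] = [genes, flanks]
        if ccres_path is not None:
            feature_sets.append(read_bed_features(ccres_path, "cCREs"))
        query = selection.selected if len(selection.selected) else diff.stats
        annotation = overlap_summary(
            query[["chrom", "start", "end"]], feature_sets, binning.chrom_sizes
        )
        annotation.per_set.to_csv(
            outdir / "overlap_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if annotation.exclusive_fractions:
            pd.Series(annotation.exclusive_fractions).rename("fraction").to_csv(
                outdir / "exclusive_fractions.tsv", sep="\t", header=True
            )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": {
            "chrom_sizes": _checksum(chrom_sizes_path),
            "libraries": {
                row["library_id"]: _checksum(row["path"]) for _, row in library_table.iterrows()
            },
        },
        "stages": {
            "n_libraries": len(profiles),
            "n_kept": len(kept),
            "n_excluded": len(excluded),
            "n_bins": binning.n_bins,
            "n_retained_intervals": int(len(diff.stats)),
            "n_zero_control": diff.n_zero_control,
            "n_curve_windows": int(len(curve.points)),
            "n_selected": int(len(selection.selected)),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(binning, kept, excluded, diff, curve, selection, annotation)


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_synthetic(
    sim_cfg, config: PipelineConfig, min_reads: float | None = None
) -> tuple[PipelineResult, "pd.DataFrame"]:
    """Simulate fragments in memory and run counting + analysis on them.

    Convenience path used by tests and the acceptance script; equivalent to
    writing BEDs and calling :func:`run_pipeline` but without file IO.
    Returns the result and the simulation's locus ground truth.
    """
    from .simulate import simulate_fragments

    sim = simulate_fragments(sim_cfg)
    binning = GenomeBinning(sim.binning_sizes, bin_width=config.bin_width)
    profiles = []
    cols = []
    for lib in sim.libraries:
        cls = classify_lengths(lib.fragments["length"].to_numpy())
        n_class = int((cls == config.class_filter).sum())
        profiles.append(LibraryProfile(lib.library_id, lib.group, n_class))
        cols.append(count_extremities(lib.fragments, binning, config.class_filter))
    threshold = config.min_reads if min_reads is None else min_reads
    kept, excluded = exclude_low_count_libraries(profiles, min_reads=threshold)
    keep_idx = [i for i, p in enumerate(profiles) if p.excluded_reason is None]
    matrix = np.column_stack([cols[i] for i in keep_idx])
    diff, curve, selection = analyze_counts(matrix, kept, binning, config)
    result = PipelineResult(binning, kept, excluded, diff, curve, selection)
    return result, sim.truth.loci
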
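"""Synthetic inputs for the whole pipeline: fragments, annotation, spike trains.

The fragment generator emulates the study design: two genotype groups
(6 control + 7 mutant libraries by default) of paired-end ATAC fragments
whose lengths follow a subnucleosomal / nucleosomal / poly-nucleosomal
mixture, placed either at accessible loci of varying widths (probability
proportional to locus accessibility, times a planted group multiplier in the
mutant) or uniformly as background.  A configurable fraction of loci carries
a depletion multiplier (< 1) and a smaller fraction an enhancement
multiplier (> 1), biased toward depletion to mirror a genome-wide
accessibility loss in the mutant.  Ground truth (locus coordinates,
multipliers, per-library depths) is returned and serialized for recovery
tests.

The spike-train generator interleaves pacemaker-like tonic firing (refractory
shifted-exponential inter-spike intervals, so tonic activity cannot open a
burst) with planted bursts of short intra-burst intervals, and records the
realized burst spike fraction as truth.

Everything is deterministic given the seed: one child RNG stream per library
or neuron, spawned from the master seed, so outputs are stable under
reordering.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import SpikeTrain

LENGTH_RANGES = {
    "subnucleosomal": (30, 140),
    "nucleosomal": (141, 280),
    "polynucleosomal": (281, 600),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic ATAC study (defaults = study conditions)."""

    seed: int = 0
    genome: tuple = (("chr1", 5_000_000), ("chr2", 5_000_000))
    n_control: int = 6
    n_mutant: int = 7
    n_low_control: int = 0  # extra shallow libraries, to exercise exclusion
    n_low_mutant: int = 0
    low_depth: int = 5_000
    mean_depth: int = 250_000  # fragments per library, desk scale
    depth_sigma: float = 0.2  # lognormal spread of library depths
    n_loci: int = 2_000
    locus_width_range: tuple = (200, 1_200)
    baseline_sigma: float = 1.0  # lognormal accessibility across loci
    length_mixture: tuple = (0.50, 0.35, 0.15)  # sub / nuc / poly weights
    background_fraction: float = 0.30  # fragments placed uniformly
    f_dep: float = 0.10  # fraction of loci depleted in the mutant
    m_dep: float = 0.6
    f_enh: float = 0.05  # fraction enhanced in the mutant
    m_enh: float = 1.4
    # annotation layout
    gene_width_range: tuple = (10_000, 50_000)
    gene_gap_range: tuple = (10_000, 80_000)  # wide enough that some DNA lies beyond any 20-kb flank
    flank_bp: int = 20_000
    locus_category_fractions: tuple = (0.70, 0.20, 0.10)  # genic / flank / intergenic
    n_ccres: int = 3_000
    ccre_width_range: tuple = (150, 350)

    def __post_init__(self) -> None:
        if not (0 <= self.f_dep <= 1 and 0 <= self.f_enh <= 1 and self.f_dep + self.f_enh <= 1):
            raise ValueError("effect fractions must be in [0,1] with f_dep + f_enh <= 1")
        if self.m_dep <= 0 or self.m_enh <= 0:
            raise ValueError("effect multipliers must be positive")
        widest = self.locus_width_range[1]
        if any(widest > size for _, size in self.genome):
            raise ValueError("locus wider than a chromosome")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)


@dataclass
class SimTruth:
    """Ground truth of a fragment simulation."""

    loci: pd.DataFrame  # chrom,start,end,baseline,multiplier,category
    depths: dict[str, int]
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loci": self.loci.to_dict(orient="list"),
            "depths": self.depths,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, default=_jsonable, indent=1))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(type(x))


@dataclass
class SimLibrary:
    library_id: str
    group: str
    fragments: pd.DataFrame  # chrom,start,end,length
    depth: int


@dataclass
class SimResult:
    config: SimConfig
    binning_sizes: dict[str, int]
    libraries: list[SimLibrary]
    genes: pd.DataFrame
    ccres: pd.DataFrame
    truth: SimTruth


def _sample_lengths(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    cls = rng.choice(3, size=n, p=np.asarray(mixture) / np.sum(mixture))
    lows = np.array([LENGTH_RANGES[k][0] for k in ("subnucleosomal", "nucleosomal", "polynucleosomal")])
    highs = np.array([LENGTH_RANGES[k][1] for k in ("subnucleosomal", "nucleosomal", "polynucleosomal")])
    return rng.integers(lows[cls], highs[cls] + 1)


def _make_genes(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    rows = []
    gi = 0
    for chrom, size in cfg.genome:
        pos = 0
        while True:
            gap = rng.integers(*cfg.gene_gap_range)
            width = rng.integers(*cfg.gene_width_range)
            start = pos + gap
            end = start + width
            if end + cfg.gene_gap_range[0] > size:
                break
            rows.append({"chrom": chrom, "start": int(start), "end": int(end), "name": f"gene{gi}"})
            gi += 1
            pos = end
    return pd.DataFrame(rows)


def _place_loci(rng: np.random.Generator, cfg: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Accessible loci placed in genes / gene flanks / intergenic space."""
    chroms = [c for c, _ in cfg.genome]
    sizes = cfg.chrom_sizes
    cats = rng.choice(
        ["genic", "flank", "intergenic"], size=cfg.n_loci, p=cfg.locus_category_fractions
    )
    widths = rng.integers(*cfg.locus_width_range, size=cfg.n_loci)
    rows = []
    gene_arr = genes[["chrom", "start", "end"]].to_records(index=False)
    for cat, width in zip(cats, widths):
        if cat in ("genic", "flank") and len(gene_arr):
            g = gene_arr[rng.integers(len(gene_arr))]
            if cat == "genic":
                center = rng.integers(g.start, g.end)
            else:
                side = rng.integers(2)
                if side == 0:
                    center = rng.integers(max(0, g.start - cfg.flank_bp), max(1, g.start))
                else:
                    center = rng.integers(g.end, min(sizes[g.chrom], g.end + cfg.flank_bp))
            chrom = g.chrom
        else:
            chrom = chroms[rng.integers(len(chroms))]
            center = rng.integers(0, sizes[chrom])
            cat = "intergenic"
        half = int(width) // 2
        start = int(np.clip(center - half, 0, sizes[chrom] - width))
        rows.append(
            {"chrom": str(chrom), "start": start, "end": start + int(width), "category": cat}
        )
    loci = pd.DataFrame(rows)
    loci["baseline"] = rng.lognormal(0.0, cfg.baseline_sigma, size=cfg.n_loci)
    mult = np.ones(cfg.n_loci)
    n_dep = int(round(cfg.f_dep * cfg.n_loci))
    n_enh = int(round(cfg.f_enh * cfg.n_loci))
    affected = rng.permutation(cfg.n_loci)[: n_dep + n_enh]
    mult[affected[:n_dep]] = cfg.m_dep
    mult[affected[n_dep : n_dep + n_enh]] = cfg.m_enh
    loci["multiplier"] = mult
    return loci


def _make_ccres(rng: np.random.Generator, cfg: SimConfig, loci: pd.DataFrame) -> pd.DataFrame:
    """Candidate regulatory elements: half centred at loci, half uniform."""
    sizes = cfg.chrom_sizes
    chroms = [c for c, _ in cfg.genome]
    rows = []
    n_at_loci = min(cfg.n_ccres // 2, len(loci))
    pick = rng.permutation(len(loci))[:n_at_loci]
    for i in pick:
        loc = loci.iloc[i]
        width = int(rng.integers(*cfg.ccre_width_range))
        center = (loc["start"] + loc["end"]) // 2 + int(rng.integers(-200, 201))
        start = int(np.clip(center - width // 2, 0, sizes[loc["chrom"]] - width))
        rows.append({"chrom": loc["chrom"], "start": start, "end": start + width, "name": "cCRE"})
    for _ in range(cfg.n_ccres - n_at_loci):
        chrom = chroms[rng.integers(len(chroms))]
        width = int(rng.integers(*cfg.ccre_width_range))
        start = int(rng.integers(0, sizes[chrom] - width))
        rows.append({"chrom": chrom, "start": start, "end": start + width, "name": "cCRE"})
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    df["name"] = [f"cCRE{i}" for i in range(len(df))]
    return df


def _simulate_library(
    rng: np.random.Generator,
    cfg: SimConfig,
    loci: pd.DataFrame,
    group: str,
    depth: int,
) -> pd.DataFrame:
    sizes = cfg.chrom_sizes
    chroms = [c for c, _ in cfg.genome]
    chrom_len = np.array([sizes[c] for c in chroms], dtype=np.int64)
    n_bg = rng.binomial(depth, cfg.background_fraction)
    n_loc = depth - n_bg

    weights = loci["baseline"].to_numpy().copy()
    if group == "mutant":
        weights = weights * loci["multiplier"].to_numpy()
    weights = weights / weights.sum()
    pick = rng.choice(len(loci), size=n_loc, p=weights)
    centers = ((loci["start"].to_numpy() + loci["end"].to_numpy()) // 2)[pick]
    widths = (loci["end"].to_numpy() - loci["start"].to_numpy())[pick]
    mids = centers + np.rint(rng.normal(0.0, widths / 4.0)).astype(np.int64)
    lengths = _sample_lengths(rng, n_loc, cfg.length_mixture)
    chrom_idx = pd.Categorical(loci["chrom"].to_numpy()[pick], categories=chroms).codes
    starts = mids - lengths // 2
    starts = np.clip(starts, 0, chrom_len[chrom_idx] - lengths)

    bg_chrom_idx = rng.integers(len(chroms), size=n_bg)
    bg_lengths = _sample_lengths(rng, n_bg, cfg.length_mixture)
    bg_starts = (rng.random(n_bg) * (chrom_len[bg_chrom_idx] - bg_lengths)).astype(np.int64)

    df = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[np.concatenate([chrom_idx, bg_chrom_idx])],
            "start": np.concatenate([starts, bg_starts]),
            "length": np.concatenate([lengths, bg_lengths]),
        }
    )
    df["end"] = df["start"] + df["length"]
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return df[["chrom", "start", "end", "length"]]


def simulate_fragments(cfg: SimConfig) -> SimResult:
    """Generate per-library fragment tables plus annotation and ground truth."""
    master = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_libs = master.spawn(2)
    rng_layout = np.random.default_rng(ss_layout)
    genes = _make_genes(rng_layout, cfg)
    loci = _place_loci(rng_layout, cfg, genes)
    ccres = _make_ccres(rng_layout, cfg, loci)

    plan: list[tuple[str, str, bool]] = []
    plan += [(f"control_{i+1}", "control", False) for i in range(cfg.n_control)]
    plan += [(f"mutant_{i+1}", "mutant", False) for i in range(cfg.n_mutant)]
    plan += [(f"control_low_{i+1}", "control", True) for i in range(cfg.n_low_control)]
    plan += [(f"mutant_low_{i+1}", "mutant", True) for i in range(cfg.n_low_mutant)]

    libraries = []
    depths: dict[str, int] = {}
    for child, (lib_id, group, is_low) in zip(ss_libs.spawn(len(plan)), plan):
        rng = np.random.default_rng(child)
        if is_low:
            depth = int(cfg.low_depth)
        else:
            depth = int(round(cfg.mean_depth * rng.lognormal(0.0, cfg.depth_sigma)))
        frags = _simulate_library(rng, cfg, loci, group, depth)
        libraries.append(SimLibrary(lib_id, group, frags, depth))
        depths[lib_id] = depth

    truth = SimTruth(loci=loci, depths=depths, config=dataclasses.asdict(cfg))
    return SimResult(
        config=cfg,
        binning_sizes=cfg.chrom_sizes,
        libraries=libraries,
        genes=genes,
        ccres=ccres,
        truth=truth,
    )


def write_sim_outputs(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write BED fragments per library, chrom.sizes, annotation and truth."""
    outdir = Path(outdir)
    (outdir / "libraries").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cs = outdir / "chrom.sizes"
    with open(cs, "w") as fh:
        for chrom, size in sim.binning_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = cs
    manifest_rows = []
    for lib in sim.libraries:
        p = outdir / "libraries" / f"{lib.library_id}.bed"
        lib.fragments[["chrom", "start", "end"]].to_csv(p, sep="\t", header=False, index=False)
        manifest_rows.append(
            {"library_id": lib.library_id, "group": lib.group, "path": str(p), "depth": lib.depth}
        )
    lib_tsv = outdir / "libraries.tsv"
    pd.DataFrame(manifest_rows).to_csv(lib_tsv, sep="\t", index=False)
    paths["libraries"] = lib_tsv
    genes_bed = outdir / "genes.bed"
    sim.genes.to_csv(genes_bed, sep="\t", header=False, index=False)
    paths["genes"] = genes_bed
    ccres_bed = outdir / "ccres.bed"
    sim.ccres.to_csv(ccres_bed, sep="\t", header=False, index=False)
    paths["ccres"] = ccres_bed
    truth_json = outdir / "truth.json"
    sim.truth.to_json(truth_json)
    paths["truth"] = truth_json
    return paths


@dataclass
class BurstParams:
    """Planted burst structure of a simulated spike train."""

    burst_rate: float = 0.15  # bursts per second
    spikes_per_burst: int = 4
    intra_burst_isi: float = 0.030  # s; well below the 80 ms onset threshold
    isi_jitter: float = 0.5  # multiplicative jitter, U(1-j, 1+j)
    min_gap: float = 0.50  # s between a burst and anything else


@dataclass
class SpikeSimResult:
    trains: list[SpikeTrain]
    truth: pd.DataFrame  # neuron_id, n_spikes, n_burst_spikes, burst_fraction


def simulate_spike_trains(
    n_neurons: int = 10,
    duration: float = 300.0,
    tonic_rate: float = 2.0,
    burst_params: BurstParams | None = None,
    seed: int = 0,
    tonic_refractory: float = 0.25,
) -> SpikeSimResult:
    """Tonic + bursty spike trains with known burst spike fraction.

    Tonic inter-spike intervals are ``refractory + Exp(mean)`` with the mean
    chosen to hit ``tonic_rate`` on average, so no two tonic spikes fall
    within the 80 ms onset window.  Bursts of ``spikes_per_burst`` spikes at
    ``intra_burst_isi`` (jittered) are inserted at Poisson-rate onsets with a
    guard gap, and tonic spikes closer than the guard gap to a burst are
    removed.  The truth table records the realized burst spike fraction per
    neuron.
    """
    if burst_params is None:
        burst_params = BurstParams()
    bp = burst_params
    if bp.intra_burst_isi >= 0.080:
        raise ValueError("intra-burst ISI must be < 80 ms for detectable bursts")
    if tonic_rate > 0 and 1.0 / tonic_rate <= tonic_refractory:
        raise ValueError("tonic rate too high for the refractory period")
    master = np.random.SeedSequence(seed)
    trains: list[SpikeTrain] = []
    rows = []
    for i, child in enumerate(master.spawn(n_neurons)):
        rng = np.random.default_rng(child)
        burst_spikes: list[float] = []
        if bp.burst_rate > 0:
            t = rng.exponential(1.0 / bp.burst_rate)
            while t < duration - 1.0:
                isis = bp.intra_burst_isi * rng.uniform(
                    1 - bp.isi_jitter, 1 + bp.isi_jitter, size=bp.spikes_per_burst - 1
                )
                spikes = t + np.concatenate([[0.0], np.cumsum(isis)])
                if spikes[-1] < duration:
                    burst_spikes.extend(spikes)
                t = spikes[-1] + bp.min_gap + rng.exponential(1.0 / bp.burst_rate)
        tonic: list[float] = []
        if tonic_rate > 0:
            exp_mean = 1.0 / tonic_rate - tonic_refractory
            t = rng.exponential(1.0 / tonic_rate)
            while t < duration:
                tonic.append(t)
                t += tonic_refractory + rng.exponential(exp_mean)
        barr = np.asarray(burst_spikes)
        if barr.size and tonic:
            tarr = np.asarray(tonic)
            d = np.min(np.abs(tarr[:, None] - barr[None, :]), axis=1)
            tarr = tarr[d > bp.min_gap / 2]
        else:
            tarr = np.asarray(tonic)
        times = np.sort(np.concatenate([barr, tarr]))
        times = np.unique(times)
        nid = f"neuron_{i+1}"
        trains.append(SpikeTrain(nid, times, duration))
        n_burst = int(barr.size)
        rows.append(
            {
                "neuron_id": nid,
                "n_spikes": int(times.size),
                "n_burst_spikes": n_burst,
                "burst_fraction": n_burst / times.size if times.size else 0.0,
            }
        )
    return SpikeSimResult(trains=trains, truth=pd.DataFrame(rows))
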
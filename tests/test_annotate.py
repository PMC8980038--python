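"""Gene/flank/cCRE overlap with half-open semantics, against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from atacburst.annotate import (
    FeatureSet,
    make_flanks,
    merge_intervals,
    overlap_any,
    overlap_summary,
    read_bed_features,
    read_gff3_genes,
    subtract_intervals,
)


def fs(name, rows):
    return FeatureSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def q(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestFlanks:
    def test_flank_arithmetic(self):
        genes = fs("genes", [("chr1", 50_000, 60_000)])
        flanks = make_flanks(genes, flank=20_000, chrom_sizes={"chr1": 1_000_000})
        got = sorted(map(tuple, flanks.intervals[["start", "end"]].to_numpy()))
        assert got == [(30_000, 50_000), (60_000, 80_000)]

    def test_flank_clipped_at_chromosome_start(self):
        genes = fs("genes", [("chr1", 5_000, 9_000)])
        flanks = make_flanks(genes, flank=20_000, chrom_sizes={"chr1": 1_000_000})
        got = sorted(map(tuple, flanks.intervals[["start", "end"]].to_numpy()))
        assert got == [(0, 5_000), (9_000, 29_000)]

    def test_intergenic_flank_trimmed_between_close_genes(self):
        """Two genes 10 kb apart: in exclusive mode their facing flanks are
        trimmed to the 10-kb gap."""
        genes = fs("genes", [("chr1", 100_000, 120_000), ("chr1", 130_000, 150_000)])
        flanks = make_flanks(genes, flank=20_000, chrom_sizes={"chr1": 1_000_000})
        inner = [
            (s, e)
            for s, e in flanks.intervals[["start", "end"]].to_numpy()
            if s >= 120_000 and e <= 130_000
        ]
        assert inner == [(120_000, 130_000), (120_000, 130_000)]  # one per gene
        # no flank base falls inside any gene body
        for s, e in flanks.intervals[["start", "end"]].to_numpy():
            for gs, ge in ((100_000, 120_000), (130_000, 150_000)):
                assert e <= gs or s >= ge

    def test_inclusive_mode_keeps_gene_overlap(self):
        genes = fs("genes", [("chr1", 100_000, 120_000), ("chr1", 130_000, 150_000)])
        flanks = make_flanks(genes, flank=20_000, exclusive=False)
        spans = flanks.intervals
        assert ((spans["start"] < 150_000) & (spans["end"] > 130_000)).any()


class TestHalfOpenSemantics:
    def test_fifty_bp_intersection_counts(self):
        flags, _ = overlap_any(q([("chr1", 150, 250)]), fs("genes", [("chr1", 200, 5000)]))
        assert flags[0]

    def test_touching_intervals_do_not_overlap(self):
        flags, _ = overlap_any(q([("chr1", 150, 200)]), fs("genes", [("chr1", 200, 5000)]))
        assert not flags[0]
        flags, _ = overlap_any(q([("chr1", 5000, 5100)]), fs("genes", [("chr1", 200, 5000)]))
        assert not flags[0]
        flags, _ = overlap_any(q([("chr1", 4999, 5100)]), fs("genes", [("chr1", 200, 5000)]))
        assert flags[0]


def test_constructed_fractions_40_20_40():
    """100 query intervals placed 40 in genes, 20 in flanks, 40 elsewhere."""
    genes = fs("genes", [("chr1", i * 100_000, i * 100_000 + 30_000) for i in range(1, 5)])
    flanks = make_flanks(genes, flank=20_000, chrom_sizes={"chr1": 10_000_000})
    rows = []
    for i in range(40):  # inside gene bodies
        g = i % 4
        rows.append(("chr1", (g + 1) * 100_000 + 1000 + i * 10, (g + 1) * 100_000 + 1100 + i * 10))
    for i in range(20):  # inside downstream flanks
        g = i % 4
        rows.append(("chr1", (g + 1) * 100_000 + 30_500 + i * 10, (g + 1) * 100_000 + 30_600 + i * 10))
    for i in range(40):  # far intergenic (beyond 20-kb flanks)
        rows.append(("chr1", 600_000 + i * 1000, 600_000 + i * 1000 + 100))
    summary = overlap_summary(q(rows), [genes, flanks], {"chr1": 10_000_000})
    assert summary.exclusive_fractions == pytest.approx(
        {"gene": 0.40, "flank": 0.20, "intergenic": 0.40}
    )


def test_exclusive_fractions_sum_to_one(rng):
    genes = fs("genes", [("chr1", int(s), int(s) + 5_000) for s in range(10_000, 500_000, 50_000)])
    flanks = make_flanks(genes, flank=20_000, chrom_sizes={"chr1": 1_000_000})
    starts = rng.integers(0, 999_000, size=200)
    query = q([("chr1", int(s), int(s) + 500) for s in starts])
    summary = overlap_summary(query, [genes, flanks], {"chr1": 1_000_000})
    assert sum(summary.exclusive_fractions.values()) == pytest.approx(1.0)
    # gene precedence: an interval flagged genic never counts as flank
    flags = summary.query_flags
    both = flags["genes"] & flags["flanks"]
    assert summary.exclusive_fractions["gene"] >= both.mean()


def brute_force_overlap(query, features):
    """O(n*m) all-pairs oracle with half-open semantics."""
    qflags = np.zeros(len(query), dtype=bool)
    fhit = set()
    for i, (qc, qs, qe) in enumerate(query[["chrom", "start", "end"]].itertuples(index=False)):
        for j, (fc, fs_, fe) in enumerate(
            features.intervals[["chrom", "start", "end"]].itertuples(index=False)
        ):
            if qc == fc and qs < fe and fs_ < qe:
                qflags[i] = True
                fhit.add(features.intervals.index[j])
    return qflags, fhit


def test_overlap_matches_brute_force_oracle(rng):
    chroms = ["chr1", "chr2"]
    feats = fs(
        "genes",
        [
            (chroms[rng.integers(2)], int(s), int(s) + int(rng.integers(1, 2000)))
            for s in rng.integers(0, 99_000, size=400)
        ],
    )
    query = q(
        [
            (chroms[rng.integers(2)], int(s), int(s) + int(rng.integers(1, 500)))
            for s in rng.integers(0, 99_500, size=600)
        ]
    )
    flags, hit_ids = overlap_any(query, feats)
    oflags, ohit = brute_force_overlap(query, feats)
    assert np.array_equal(flags, oflags)
    assert hit_ids == ohit
    summary = overlap_summary(query, [feats], {"chr1": 200_000, "chr2": 200_000})
    row = summary.per_set.iloc[0]
    assert row["n_query_overlapping"] == oflags.sum()
    assert row["n_features_hit"] == len(ohit)


def test_chrom_mismatch_raises():
    with pytest.raises(ValueError, match="chrM"):
        overlap_summary(q([("chrM", 0, 10)]), [fs("genes", [("chr1", 0, 10)])])


def test_merge_and_subtract_helpers():
    merged = merge_intervals(np.array([[10, 20], [15, 30], [40, 50]]))
    assert merged.tolist() == [[10, 30], [40, 50]]
    assert subtract_intervals((0, 100), merged) == [(0, 10), (30, 40), (50, 100)]
    assert subtract_intervals((12, 18), merged) == []


def test_bed_and_gff3_feature_reading(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("chr1\t100\t200\tgeneA\nchr2\t0\t50\tgeneB\n")
    feats = read_bed_features(bed, "genes")
    assert feats.intervals["name"].tolist() == ["geneA", "geneB"]
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
        "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1;Parent=geneA\n"
    )
    genes = read_gff3_genes(gff)
    assert genes.intervals[["chrom", "start", "end"]].values.tolist() == [["chr1", 100, 200]]
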
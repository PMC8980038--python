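"""Fragment parsing, length classification and extremity binning."""

import numpy as np
import pandas as pd
import pytest

from atacburst.fragments import (
    FragmentRecord,
    GenomeBinning,
    ReadReport,
    classify_length,
    classify_lengths,
    count_extremities,
    load_fragment_table,
    read_counts_tsv,
    read_fragments,
    write_counts_tsv,
)

from conftest import random_fragments


@pytest.mark.parametrize(
    "length,expected",
    [
        (1, "subnucleosomal"),
        (140, "subnucleosomal"),
        (141, "nucleosomal"),
        (280, "nucleosomal"),
        (281, "polynucleosomal"),
        (1000, "polynucleosomal"),
    ],
)
def test_length_class_boundaries(length, expected):
    assert classify_length(length) == expected


def test_length_class_domain_error():
    with pytest.raises(ValueError):
        classify_length(0)
    with pytest.raises(ValueError):
        classify_lengths(np.array([5, 0]))


def test_length_classes_partition_contiguously():
    """Over 1..1000 bp the classes form exactly three contiguous runs."""
    classes = [classify_length(l) for l in range(1, 1001)]
    runs = [classes[0]]
    for c in classes[1:]:
        if c != runs[-1]:
            runs.append(c)
    assert runs == ["subnucleosomal", "nucleosomal", "polynucleosomal"]
    assert classes[139] == "subnucleosomal" and classes[140] == "nucleosomal"
    assert classes[279] == "nucleosomal" and classes[280] == "polynucleosomal"
    vec = classify_lengths(np.arange(1, 1001))
    assert list(vec) == classes


def test_binning_bin_count_and_coords(small_binning):
    # chr1: ceil(10050/100)=101 (last bin 50 bp), chr2: 50
    assert small_binning.n_bins == 151
    assert small_binning.bin_index("chr1", 0) == 0
    assert small_binning.bin_index("chr1", 10_049) == 100
    assert small_binning.bin_coords(100) == ("chr1", 10_000, 10_050)
    assert small_binning.bin_index("chr2", 0) == 101
    with pytest.raises(ValueError):
        small_binning.bin_index("chr1", 10_050)
    with pytest.raises(KeyError):
        small_binning.bin_index("chrX", 0)


def test_every_position_maps_to_exactly_one_bin(small_binning):
    for chrom, size in small_binning.chrom_sizes.items():
        idx = small_binning.bin_indices(chrom, np.arange(size))
        # contiguous, non-decreasing, each bin hit bin_width times (last truncated)
        counts = np.bincount(idx, minlength=small_binning.n_bins)
        hit = np.flatnonzero(counts)
        assert np.array_equal(hit, np.arange(hit[0], hit[0] + len(hit)))
        assert counts[hit].sum() == size


def test_count_extremities_hand_placements(small_binning):
    col = count_extremities(
        [FragmentRecord("chr1", 105, 245)], small_binning, class_filter=None
    )
    assert col[1] == 1 and col[2] == 1 and col.sum() == 2
    col = count_extremities(
        [FragmentRecord("chr1", 100, 150)], small_binning, class_filter=None
    )
    assert col[1] == 2 and col.sum() == 2
    col = count_extremities([], small_binning)
    assert col.sum() == 0


def test_extremity_conservation_and_dataframe_equivalence(small_binning, rng):
    """Column sum is 2x the class-filtered fragment count; record and
    DataFrame code paths agree bin by bin."""
    df = random_fragments(rng, small_binning, 2000)
    for cls in ("subnucleosomal", "nucleosomal", "polynucleosomal", None):
        col = count_extremities(df, small_binning, class_filter=cls)
        if cls is None:
            n = len(df)
        else:
            n = int((classify_lengths(df["length"].to_numpy()) == cls).sum())
        assert col.sum() == 2 * n
        recs = (FragmentRecord(c, s, e) for c, s, e in zip(df.chrom, df.start, df.end))
        col_rec = count_extremities(recs, small_binning, class_filter=cls)
        assert np.array_equal(col, col_rec)


def test_binning_translation_consistency(rng):
    """Shifting all fragments by +bin_width shifts non-zero bins by +1 index."""
    binning = GenomeBinning({"chr1": 100_000}, bin_width=100)
    df = random_fragments(rng, binning, 500, max_len=120)
    df = df[(df.start >= 100) & (df.end <= 99_000)].copy()
    col = count_extremities(df, binning, class_filter=None)
    shifted = df.assign(start=df.start + 100, end=df.end + 100)
    col_shift = count_extremities(shifted, binning, class_filter=None)
    assert np.array_equal(col[:-1], col_shift[1:])


def test_bed_roundtrip(tmp_path, small_binning, rng):
    df = random_fragments(rng, small_binning, 300)
    path = tmp_path / "frags.bed"
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
    recs = list(read_fragments(path, small_binning))
    back = pd.DataFrame(
        {"chrom": [r.chrom for r in recs], "start": [r.start for r in recs],
         "end": [r.end for r in recs]}
    )
    pd.testing.assert_frame_equal(
        back.astype({"start": np.int64, "end": np.int64}),
        df[["chrom", "start", "end"]].reset_index(drop=True),
    )
    # vectorized loader agrees with the record stream
    table = load_fragment_table(path, small_binning)
    pd.testing.assert_frame_equal(table[["chrom", "start", "end"]], back.astype({"start": np.int64, "end": np.int64}))


def test_bam_and_bed_give_identical_fragments(tmp_path, small_binning):
    """The same five templates written as BED and as paired SAM records parse
    to identical fragment records."""
    import pysam

    frags = [("chr1", 105, 245), ("chr1", 0, 140), ("chr1", 9_900, 10_050),
             ("chr2", 400, 541), ("chr2", 10, 300)]
    bed = tmp_path / "f.bed"
    with open(bed, "w") as fh:
        for c, s, e in frags:
            fh.write(f"{c}\t{s}\t{e}\n")
    sam = tmp_path / "f.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in small_binning.chrom_sizes.items()],
    }
    read_len = 10
    with pysam.AlignmentFile(str(sam), "wh", header=header) as out:
        for i, (c, s, e) in enumerate(sorted(frags)):
            tid = out.get_tid(c)
            a = pysam.AlignedSegment()
            a.query_name = f"t{i}"
            a.query_sequence = "A" * read_len
            a.flag = 0x1 | 0x2 | 0x40 | 0x20  # paired, proper, read1, mate reverse
            a.reference_id = tid
            a.reference_start = s
            a.mapping_quality = 60
            a.cigar = [(0, read_len)]
            a.next_reference_id = tid
            a.next_reference_start = e - read_len
            a.template_length = e - s
            b = pysam.AlignedSegment()
            b.query_name = f"t{i}"
            b.query_sequence = "A" * read_len
            b.flag = 0x1 | 0x2 | 0x80 | 0x10  # paired, proper, read2, reverse
            b.reference_id = tid
            b.reference_start = e - read_len
            b.mapping_quality = 60
            b.cigar = [(0, read_len)]
            b.next_reference_id = tid
            b.next_reference_start = s
            b.template_length = -(e - s)
            out.write(a)
            out.write(b)
    from_bed = sorted((r.chrom, r.start, r.end) for r in read_fragments(bed, small_binning))
    from_sam = sorted((r.chrom, r.start, r.end) for r in read_fragments(sam, small_binning))
    assert from_sam == from_bed == sorted(frags)


def test_read_fragments_validation(tmp_path, small_binning):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t10\t10\nchrUn\t0\t50\nchr1\t50\t120\n")
    report = ReadReport()
    recs = list(read_fragments(path, small_binning, report))
    assert [(r.start, r.end) for r in recs] == [(50, 120)]
    assert report.n_rejected == 1  # zero-length
    assert report.n_dropped_unknown_chrom == 1
    malformed = tmp_path / "malformed.bed"
    malformed.write_text("chr1\t100\n")
    with pytest.raises(ValueError, match="malformed.bed:1"):
        list(read_fragments(malformed, small_binning))


def test_counts_tsv_roundtrip(tmp_path, small_binning, rng):
    df = random_fragments(rng, small_binning, 500)
    col = count_extremities(df, small_binning, class_filter=None)
    path = tmp_path / "c.tsv"
    write_counts_tsv(col, small_binning, path)
    back = read_counts_tsv(path, small_binning)
    assert np.array_equal(col, back)
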
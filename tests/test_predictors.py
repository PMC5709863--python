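"""Predictor extraction: GC accounting, SAM depth/breadth semantics, the
depth-TSV dialects and predictor-table assembly."""

import numpy as np
import pandas as pd
import pytest

from decontree.predictors import (
    AlignmentFilter,
    AlignmentSummary,
    ScaffoldRecord,
    build_predictor_table,
    compute_scaffold_stats,
    read_predictor_table,
    summaries_from_depth_tsv,
    summarize_alignments,
    write_predictor_table,
)

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:s1\tLN:8\n@SQ\tSN:s2\tLN:8\n@RG\tID:pe\n@RG\tID:mp\n"


def sam_line(name, flag, ref, pos, cigar, seq, tags=""):
    qual = "I" * len(seq)
    line = f"{name}\t{flag}\t{ref}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
    if tags:
        line += "\t" + tags
    return line + "\n"


def write_sam(path, lines, header=SAM_HEADER):
    path.write_text(header + "".join(lines))
    return path


def write_fasta(path, records):
    path.write_text("".join(f">{sid}\n{seq}\n" for sid, seq in records))
    return path


@pytest.mark.parametrize(
    "seq, length, gc",
    [("ATGC", 4, 0.5), ("AAAA", 4, 0.0), ("ATGNNC", 6, 2 / 4)],
)
def test_scaffold_stats_gc(tmp_path, seq, length, gc):
    fasta = write_fasta(tmp_path / "a.fasta", [("s1", seq)])
    (rec,) = compute_scaffold_stats(fasta)
    assert rec.length == length
    assert rec.gc_fraction == pytest.approx(gc)


def test_scaffold_stats_errors(tmp_path):
    with pytest.raises(ValueError, match="no sequences"):
        compute_scaffold_stats(write_fasta(tmp_path / "e.fasta", []))
    with pytest.raises(ValueError, match="s2"):
        compute_scaffold_stats(
            write_fasta(tmp_path / "z.fasta", [("s1", "ACGT"), ("s2", "")])
        )


def test_scaffold_stats_all_n_warns(tmp_path):
    fasta = write_fasta(tmp_path / "n.fasta", [("s1", "NNNN")])
    with pytest.warns(UserWarning):
        (rec,) = compute_scaffold_stats(fasta)
    assert rec.gc_fraction == 0.0 and rec.all_ambiguous


def test_fasta_round_trip_idempotent(tmp_path, toy_bundle):
    records = compute_scaffold_stats(toy_bundle["fasta"])
    out = tmp_path / "copy.fasta"
    from Bio import SeqIO

    SeqIO.write(SeqIO.parse(str(toy_bundle["fasta"]), "fasta"), str(out), "fasta")
    assert compute_scaffold_stats(out) == records


SCAFFOLDS = [ScaffoldRecord("s1", 8, 0.5), ScaffoldRecord("s2", 8, 0.5)]


def test_depth_and_breadth_hand_count(tmp_path):
    sam = write_sam(
        tmp_path / "a.sam",
        [sam_line("r1", 0, "s1", 1, "4M", "ATAT"),
         sam_line("r2", 0, "s1", 1, "4M", "GCGC")],
    )
    s1, s2 = summarize_alignments(sam, SCAFFOLDS)
    assert s1.mean_depth == pytest.approx(1.0)  # depth (2,2,2,2,0,0,0,0)
    assert s1.breadth == pytest.approx(0.5)
    assert s1.aligned_read_gc == pytest.approx(0.5)  # ATAT + GCGC
    assert s2.mean_depth == 0 and s2.breadth == 0 and s2.no_data


def test_deletion_consumes_reference(tmp_path):
    sam = write_sam(tmp_path / "d.sam", [sam_line("r1", 0, "s1", 1, "2M2D2M", "ATAT")])
    (s1, _) = summarize_alignments(sam, SCAFFOLDS)
    assert s1.breadth == pytest.approx(6 / 8)  # 2M + 2D + 2M positions
    assert s1.mean_depth == pytest.approx(6 / 8)


def test_excluded_flags_and_proper_pairing(tmp_path):
    lines = [
        sam_line("sec", 256, "s1", 1, "4M", "ACGT"),
        sam_line("sup", 2048, "s1", 1, "4M", "ACGT"),
        sam_line("qcf", 512, "s1", 1, "4M", "ACGT"),
        sam_line("unp", 1, "s1", 1, "4M", "ACGT"),  # paired, not proper
    ]
    sam = write_sam(tmp_path / "f.sam", lines)
    (s1, _) = summarize_alignments(sam, SCAFFOLDS)
    assert s1.mean_depth == 0 and s1.no_data
    relaxed = summarize_alignments(
        sam, SCAFFOLDS, AlignmentFilter(require_proper_pair=False)
    )
    assert relaxed[0].mean_depth == pytest.approx(0.5)  # only "unp" retained


def test_mate_pair_read_group_exclusion(tmp_path):
    lines = [
        sam_line("pe1", 0, "s1", 1, "4M", "ACGT", tags="RG:Z:pe"),
        sam_line("mp1", 0, "s1", 5, "4M", "ACGT", tags="RG:Z:mp"),
    ]
    sam = write_sam(tmp_path / "rg.sam", lines)
    full = summarize_alignments(sam, SCAFFOLDS)[0]
    assert full.breadth == pytest.approx(1.0)
    filtered = summarize_alignments(
        sam, SCAFFOLDS, AlignmentFilter(exclude_read_groups=("mp",))
    )[0]
    assert filtered.breadth == pytest.approx(0.5)


def test_soft_clips_excluded_from_read_gc(tmp_path):
    sam = write_sam(tmp_path / "sc.sam", [sam_line("r1", 0, "s1", 1, "2S4M", "GGATAT")])
    (s1, _) = summarize_alignments(sam, SCAFFOLDS)
    assert s1.aligned_read_gc == pytest.approx(0.0)  # GG clipped off


def test_unknown_reference_raises(tmp_path):
    sam = write_sam(tmp_path / "u.sam", [sam_line("r1", 0, "s2", 1, "4M", "ACGT")])
    with pytest.raises(ValueError, match="unknown reference"):
        summarize_alignments(sam, SCAFFOLDS[:1])


def test_doubling_alignments_doubles_depth_only(tmp_path):
    base = [sam_line("r1", 0, "s1", 1, "4M", "ATGC")]
    one = summarize_alignments(write_sam(tmp_path / "1.sam", base), SCAFFOLDS)[0]
    two = summarize_alignments(
        write_sam(tmp_path / "2.sam", base + [sam_line("r2", 0, "s1", 1, "4M", "ATGC")]),
        SCAFFOLDS,
    )[0]
    assert two.mean_depth == pytest.approx(2 * one.mean_depth)
    assert two.breadth == one.breadth
    assert two.aligned_read_gc == one.aligned_read_gc


def test_depth_tsv_summary_dialect(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text(
        "scaffold_id\tmean_depth\tbreadth\taligned_read_gc\ns1\t2.5\t0.75\t0.4\n"
    )
    s1, s2 = summaries_from_depth_tsv(p, SCAFFOLDS)
    assert (s1.mean_depth, s1.breadth, s1.aligned_read_gc) == (2.5, 0.75, 0.4)
    assert s2.no_data and s2.mean_depth == 0


def test_depth_tsv_per_base_dialect(tmp_path):
    p = tmp_path / "pb.tsv"
    rows = "".join(f"s1\t{i}\t2\t0.4\n" for i in range(1, 5))
    p.write_text("scaffold_id\tpos\tdepth\tread_gc\n" + rows)
    (s1, _) = summaries_from_depth_tsv(p, SCAFFOLDS)
    assert s1.mean_depth == pytest.approx(1.0)
    assert s1.breadth == pytest.approx(0.5)
    assert s1.aligned_read_gc == pytest.approx(0.4)


def test_depth_tsv_position_out_of_range(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("scaffold_id\tpos\tdepth\ns1\t9\t2\n")
    with pytest.raises(ValueError, match="outside"):
        summaries_from_depth_tsv(p, SCAFFOLDS)


def test_build_predictor_table_shape_and_zero_rna():
    stats = [ScaffoldRecord(f"s{i}", 100, 0.4) for i in range(3)]
    dna = [AlignmentSummary(f"s{i}", 2.0, 0.9, 0.41) for i in range(3)]
    rna = [AlignmentSummary("s0", 1.0, 0.3, 0.45)]  # s1, s2 never expressed
    table = build_predictor_table(stats, dna, rna)
    assert table.shape == (3, 8)
    assert (table.loc["s1", ["rna_mean_depth", "rna_breadth", "rna_read_gc"]] == 0).all()
    assert table.loc["s0", "rna_breadth"] == pytest.approx(0.3)


def test_build_predictor_table_duplicate_id_rejected():
    stats = [ScaffoldRecord("s1", 10, 0.5)]
    dup = [AlignmentSummary("s1", 1, 1, 0.5), AlignmentSummary("s1", 2, 1, 0.5)]
    with pytest.raises(ValueError, match="duplicate"):
        build_predictor_table(stats, dup, [])


def test_predictor_table_tsv_round_trip(tmp_path, toy_bundle):
    table = toy_bundle["table"]
    path = tmp_path / "pred.tsv"
    write_predictor_table(table, path)
    back = read_predictor_table(path)
    pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-9)
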
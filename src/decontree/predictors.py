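"""Per-scaffold predictor variables from sequence and alignment evidence.

Eight predictors are computed for every scaffold of an assembly: (1) length,
(2) GC content, (3) mean DNA sequencing depth, (4) mean RNA sequencing
depth, (5) breadth of DNA coverage, (6) breadth of RNA coverage, (7) GC
content of aligned DNA reads and (8) GC content of aligned RNA reads.
Breadth is the fraction of scaffold positions covered by at least one
retained alignment. Alignment evidence comes from SAM/BAM (via pysam) or
from pre-computed depth TSVs so that no aligner is needed downstream.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .cart import PREDICTOR_NAMES

_GC_BASES = set("GCgcSs")  # S = strong (G or C) IUPAC code
_UNAMBIGUOUS = set("ACGTacgt")


@dataclass(frozen=True)
class ScaffoldRecord:
    """Length and GC content of one assembled scaffold.

    GC is computed over unambiguous bases only; N and other ambiguity codes
    count toward length but not GC. ``all_ambiguous`` flags scaffolds whose
    GC is undefined (reported as 0).
    """

    scaffold_id: str
    length: int
    gc_fraction: float
    all_ambiguous: bool = False


@dataclass(frozen=True)
class AlignmentSummary:
    """Depth, breadth and aligned-read GC for one scaffold in one library."""

    scaffold_id: str
    mean_depth: float
    breadth: float
    aligned_read_gc: float
    no_data: bool = False  # no reads aligned; GC reported as 0


@dataclass
class AlignmentFilter:
    """Which alignments contribute to coverage.

    Secondary, supplementary, unmapped and QC-fail records are always
    dropped. Paired reads must additionally be properly paired when
    ``require_proper_pair`` is set. Reads whose read group is listed in
    ``exclude_read_groups`` (e.g. mate-pair libraries, whose chimeric
    artifacts distort coverage) are skipped entirely.
    ``gc_aligned_bases_only`` restricts read GC to reference-aligned bases
    (M/=/X); the default uses the full soft-clip-trimmed read sequence.
    """

    require_proper_pair: bool = True
    exclude_read_groups: tuple = ()
    gc_aligned_bases_only: bool = False
    min_depth_for_breadth: int = 1


def compute_scaffold_stats(fasta: Union[str, Path]) -> list[ScaffoldRecord]:
    """Length and GC content of every sequence in a FASTA file.

    Length counts all residues including N; GC is (#G + #C) / (#A + #C +
    #G + #T). An empty file or a zero-length sequence is an error; a
    sequence of only ambiguous bases gets gc 0 with a warning flag.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        seq = str(rec.seq)
        if len(seq) == 0:
            raise ValueError(f"zero-length sequence: {rec.id!r}")
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        unambiguous = sum(1 for b in seq if b in _UNAMBIGUOUS)
        gc = sum(1 for b in seq if b in "GCgc")
        if unambiguous == 0:
            warnings.warn(
                f"scaffold {rec.id!r} has no unambiguous bases; GC set to 0"
            )
            records.append(ScaffoldRecord(rec.id, len(seq), 0.0, all_ambiguous=True))
        else:
            records.append(ScaffoldRecord(rec.id, len(seq), gc / unambiguous))
    if not records:
        raise ValueError(f"no sequences found in {fasta}")
    return records


def _read_gc_counts(aln: pysam.AlignedSegment, aligned_only: bool) -> tuple[int, int]:
    """(gc_bases, total_bases) contributed by one alignment's read sequence."""
    if aligned_only:
        seq = "".join(
            aln.query_sequence[q] for q, _ in aln.get_aligned_pairs(matches_only=True)
        )
    else:
        seq = aln.query_alignment_sequence or ""
    gc = sum(1 for b in seq if b in _GC_BASES)
    return gc, len(seq)


def _reference_spans(aln: pysam.AlignedSegment):
    """Half-open reference intervals consumed by M/=/X/D cigar operations."""
    pos = aln.reference_start
    start = None
    for op, ln in aln.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            if start is None:
                start = pos
            pos += ln
        else:
            if op == 3:  # N skips reference and breaks the span
                if start is not None:
                    yield start, pos
                    start = None
                pos += ln
    if start is not None:
        yield start, pos


def summarize_alignments(
    alignments: Union[str, Path],
    scaffolds: Sequence[ScaffoldRecord],
    options: Optional[AlignmentFilter] = None,
) -> list[AlignmentSummary]:
    """Per-scaffold depth/breadth/read-GC from a SAM/BAM file.

    Depth at a position is the number of retained alignments whose CIGAR
    consumes that reference position (M/=/X/D). Every scaffold in
    ``scaffolds`` gets a summary; scaffolds without retained alignments get
    the zero-evidence summary.
    """
    options = options or AlignmentFilter()
    lengths = {s.scaffold_id: s.length for s in scaffolds}
    depth = {sid: np.zeros(n, dtype=np.int32) for sid, n in lengths.items()}
    gc_counts = {sid: [0, 0] for sid in lengths}

    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_qcfail:
                continue
            if options.require_proper_pair and aln.is_paired and not aln.is_proper_pair:
                continue
            if options.exclude_read_groups:
                rg = aln.get_tag("RG") if aln.has_tag("RG") else None
                if rg in options.exclude_read_groups:
                    continue
            ref = aln.reference_name
            if ref not in lengths:
                raise ValueError(f"alignment to unknown reference {ref!r}")
            vec = depth[ref]
            for start, end in _reference_spans(aln):
                vec[max(start, 0) : min(end, len(vec))] += 1
            g, t = _read_gc_counts(aln, options.gc_aligned_bases_only)
            gc_counts[ref][0] += g
            gc_counts[ref][1] += t

    out = []
    for sid, n in lengths.items():
        vec = depth[sid]
        g, t = gc_counts[sid]
        mean = float(vec.sum()) / n
        breadth = float((vec >= options.min_depth_for_breadth).sum()) / n
        out.append(
            AlignmentSummary(
                sid,
                mean,
                breadth,
                g / t if t else 0.0,
                no_data=(t == 0),
            )
        )
    return out


def summaries_from_depth_tsv(
    path: Union[str, Path],
    scaffolds: Sequence[ScaffoldRecord],
    options: Optional[AlignmentFilter] = None,
) -> list[AlignmentSummary]:
    """Alignment summaries from a TSV instead of SAM/BAM.

    Two dialects are accepted, distinguished by header:

    * summary: ``scaffold_id  mean_depth  breadth  aligned_read_gc`` — one
      row per scaffold, taken as-is;
    * per-base: ``scaffold_id  pos  depth`` (1-based positions, optional
      constant ``read_gc`` column) — depth vectors are reassembled and
      summarized here. Positions outside [1, scaffold length] are an error.

    Scaffolds absent from the file get the zero-evidence summary.
    """
    options = options or AlignmentFilter()
    lengths = {s.scaffold_id: s.length for s in scaffolds}
    df = pd.read_csv(path, sep="\t")
    unknown = set(df["scaffold_id"].astype(str)) - set(lengths)
    if unknown:
        raise ValueError(f"depth TSV refers to unknown scaffolds: {sorted(unknown)}")

    out = {}
    if "mean_depth" in df.columns:
        for row in df.itertuples(index=False):
            sid = str(row.scaffold_id)
            out[sid] = AlignmentSummary(
                sid,
                float(row.mean_depth),
                float(row.breadth),
                float(row.aligned_read_gc),
                no_data=(row.mean_depth == 0),
            )
    elif {"pos", "depth"} <= set(df.columns):
        has_gc = "read_gc" in df.columns
        for sid, grp in df.groupby("scaffold_id", sort=False):
            sid = str(sid)
            n = lengths[sid]
            pos = grp["pos"].to_numpy(dtype=int)
            if pos.min() < 1 or pos.max() > n:
                raise ValueError(
                    f"depth TSV position outside [1, {n}] for scaffold {sid!r}"
                )
            vec = np.zeros(n)
            vec[pos - 1] = grp["depth"].to_numpy(dtype=float)
            gc = float(grp["read_gc"].iloc[0]) if has_gc else 0.0
            mean = float(vec.sum()) / n
            out[sid] = AlignmentSummary(
                sid,
                mean,
                float((vec >= options.min_depth_for_breadth).sum()) / n,
                gc,
                no_data=(mean == 0 and not has_gc),
            )
    else:
        raise ValueError(
            "depth TSV must have columns (scaffold_id, mean_depth, breadth, "
            "aligned_read_gc) or (scaffold_id, pos, depth[, read_gc])"
        )

    for sid in lengths:
        if sid not in out:
            out[sid] = AlignmentSummary(sid, 0.0, 0.0, 0.0, no_data=True)
    return [out[s.scaffold_id] for s in scaffolds]


def load_alignment_evidence(
    path: Union[str, Path],
    scaffolds: Sequence[ScaffoldRecord],
    options: Optional[AlignmentFilter] = None,
) -> list[AlignmentSummary]:
    """Dispatch on file type: .sam/.bam/.cram via pysam, otherwise depth TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        return summarize_alignments(path, scaffolds, options)
    return summaries_from_depth_tsv(path, scaffolds, options)


def build_predictor_table(
    stats: Sequence[ScaffoldRecord],
    dna: Sequence[AlignmentSummary],
    rna: Sequence[AlignmentSummary],
) -> pd.DataFrame:
    """Assemble the 8-column predictor table, indexed by scaffold id.

    Scaffolds missing from the RNA (or DNA) evidence get zero-valued
    columns — absence of transcription is itself a signal, not missing
    data. Columns are in the canonical order of ``PREDICTOR_NAMES``.
    """
    ids = [s.scaffold_id for s in stats]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scaffold_id in scaffold records")

    def index(summaries, label):
        d = {}
        for s in summaries:
            if s.scaffold_id in d:
                raise ValueError(
                    f"duplicate scaffold_id {s.scaffold_id!r} in {label} summaries"
                )
            d[s.scaffold_id] = s
        return d

    zero = AlignmentSummary("", 0.0, 0.0, 0.0, no_data=True)
    dna_map = index(dna, "DNA")
    rna_map = index(rna, "RNA")
    rows = {}
    for s in stats:
        d = dna_map.get(s.scaffold_id, zero)
        r = rna_map.get(s.scaffold_id, zero)
        rows[s.scaffold_id] = (
            float(s.length),
            s.gc_fraction,
            d.mean_depth,
            r.mean_depth,
            d.breadth,
            r.breadth,
            d.aligned_read_gc,
            r.aligned_read_gc,
        )
    table = pd.DataFrame.from_dict(rows, orient="index", columns=PREDICTOR_NAMES)
    table.index.name = "scaffold_id"
    return table


def write_predictor_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_predictor_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="scaffold_id")
    table.index = table.index.astype(str)
    missing = set(PREDICTOR_NAMES) - set(table.columns)
    if missing:
        raise ValueError(f"predictor table missing columns: {sorted(missing)}")
    return table[list(PREDICTOR_NAMES)].astype(float)
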
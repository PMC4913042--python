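"""Alignment, reference and table I/O.

This module owns every standard format the caller touches: SAM/BAM
alignments (via :mod:`pysam`), FASTA references (via :mod:`pyfaidx` or
plain in-memory dicts), and the tab-separated call tables / BEDPE exports.
It also performs the first analytic step of the pipeline: extracting
soft-clipped reads, i.e. reads whose CIGAR ends in an ``S`` operation and
which therefore carry an aligned "stack" segment plus an unaligned "tail".

Coordinates are 0-based half-open everywhere inside the package; all
user-facing tables are written 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pysam

log = logging.getLogger(__name__)

# CIGAR op classes (SAM spec): which ops consume query / reference bases.
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
CIGAR_OPS = "MIDNSHP=X"  # index == pysam integer op code

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedRead:
    """One primary alignment of a sequencing read to the reference.

    ``ref_start`` is 0-based; ``strand`` is the strand the read aligned to.
    ``seq``/``quals`` are stored in alignment orientation, as in SAM.
    """

    read_id: str
    chrom: str
    ref_start: int
    cigar: list  # list of (op: str, length: int)
    seq: str
    quals: list  # per-base Phred scores, same length as seq
    mapq: int = 60
    strand: str = "+"
    is_paired: bool = False
    is_read1: bool = True
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None
    mate_strand: Optional[str] = None

    def __post_init__(self):
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.read_id}: CIGAR query length {qlen} != seq length {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.read_id}: quals/seq length mismatch")

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned span on the reference."""
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_OPS)


@dataclass
class ClippedRead:
    """A read end with a soft-clipped tail.

    ``clip_pos`` is the breakpoint-facing reference coordinate: for a right
    clip, one past the last aligned base; for a left clip, the first aligned
    base.  ``tail_seq`` may be shorter than the raw soft clip if low-quality
    bases were trimmed from its far end.
    """

    read: AlignedRead
    clip_side: str  # "left" | "right"
    clip_pos: int
    stack_seq: str
    tail_seq: str
    tail_quals: list

    @property
    def chrom(self) -> str:
        return self.read.chrom


def _to_aligned_read(rec: "pysam.AlignedSegment") -> AlignedRead:
    cigar = [(CIGAR_OPS[op], n) for op, n in rec.cigartuples]
    quals = rec.query_qualities
    seq = rec.query_sequence
    return AlignedRead(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        cigar=cigar,
        seq=seq,
        quals=list(quals) if quals is not None else [30] * len(seq),
        mapq=rec.mapping_quality,
        strand="-" if rec.is_reverse else "+",
        is_paired=rec.is_paired,
        is_read1=not (rec.is_paired and rec.is_read2),
        mate_chrom=rec.next_reference_name if rec.is_paired and not rec.mate_is_unmapped else None,
        mate_start=rec.next_reference_start if rec.is_paired and not rec.mate_is_unmapped else None,
        mate_strand=("-" if rec.mate_is_reverse else "+") if rec.is_paired and not rec.mate_is_unmapped else None,
    )


def read_alignments(
    path: Union[str, Path],
    region: Optional[str] = None,
    keep_duplicates: bool = False,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped; duplicates are
    skipped unless ``keep_duplicates``.  ``region`` is a ``chrom:start-end``
    string (1-based, samtools style) or a bare chromosome name; an unknown
    chromosome yields an empty stream with a warning.  Region queries fall
    back to a linear scan when no index is available.
    """
    path = str(path)
    try:
        handle = pysam.AlignmentFile(path, require_index=False)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignments from {path!r}: {exc}") from exc

    with handle:
        if region is not None:
            chrom = region.split(":")[0]
            if chrom not in handle.references:
                log.warning("region %r: chromosome %r not in %s; empty stream", region, chrom, path)
                return
            try:
                records = handle.fetch(region=region)
            except ValueError:
                # no index: linear scan and filter by overlap
                records = _scan_region(handle, region)
        else:
            records = handle.fetch(until_eof=True)

        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate and not keep_duplicates:
                continue
            yield _to_aligned_read(rec)


def _scan_region(handle, region: str):
    chrom, _, span = region.partition(":")
    if span:
        lo_s, _, hi_s = span.partition("-")
        lo = int(lo_s.replace(",", "")) - 1
        hi = int(hi_s.replace(",", "")) if hi_s else None
    else:
        lo, hi = 0, None
    for rec in handle.fetch(until_eof=True):
        if rec.is_unmapped or rec.reference_name != chrom:
            continue
        if rec.reference_end <= lo:
            continue
        if hi is not None and rec.reference_start >= hi:
            continue
        yield rec


def write_alignments(
    reads: Iterable[AlignedRead],
    path: Union[str, Path],
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write reads as a coordinate-sorted SAM (or BAM by extension)."""
    path = str(path)
    refs = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in refs],
    }
    tid = {c: i for i, c in enumerate(refs)}
    mode = "wb" if path.endswith(".bam") else "w"
    ordered = sorted(reads, key=lambda r: (tid[r.chrom], r.ref_start, r.read_id))
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 93) + 33) for q in r.quals)
            )
            a.reference_id = tid[r.chrom]
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if r.is_paired:
                flag |= 0x1 | 0x2
                flag |= 0x40 if r.is_read1 else 0x80
                if r.mate_strand == "-":
                    flag |= 0x20
                a.next_reference_id = tid.get(r.mate_chrom, -1)
                a.next_reference_start = r.mate_start if r.mate_start is not None else -1
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.flag = flag
            out.write(a)


def extract_clipped_reads(
    reads: Iterable[AlignedRead],
    min_tail: int = 10,
    qual_trim: int = 3,
) -> list:
    """Collect soft-clipped read ends as :class:`ClippedRead` objects.

    A read contributes one ClippedRead per end whose soft clip is at least
    ``min_tail`` bases.  Bases below ``qual_trim`` at the far (outward) end of
    a tail are trimmed before use; a tail that trims away entirely is dropped.
    Hard-clipped ends carry no bases and are counted but never emitted.
    """
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    out: list = []
    n_hard = 0
    for read in reads:
        cig = read.cigar
        # leading/trailing soft clips may sit inside hard clips
        lead = 0
        if cig and cig[0][0] == "H":
            n_hard += 1
            lead = 1
        trail = len(cig) - 1
        if cig and cig[-1][0] == "H":
            n_hard += 1
            trail -= 1
        left_clip = cig[lead][1] if lead <= trail and cig[lead][0] == "S" else 0
        right_clip = cig[trail][1] if trail >= lead and cig[trail][0] == "S" else 0
        qstart, qend = left_clip, len(read.seq) - right_clip
        stack_seq = read.seq[qstart:qend]

        if left_clip >= min_tail:
            tail = read.seq[:left_clip]
            quals = read.quals[:left_clip]
            i = 0
            while i < len(quals) and quals[i] < qual_trim:
                i += 1
            if i < len(tail):
                out.append(
                    ClippedRead(read, "left", read.ref_start, stack_seq, tail[i:], list(quals[i:]))
                )
        if right_clip >= min_tail:
            tail = read.seq[qend:]
            quals = read.quals[qend:]
            j = len(tail)
            while j > 0 and quals[j - 1] < qual_trim:
                j -= 1
            if j > 0:
                out.append(
                    ClippedRead(read, "right", read.ref_end, stack_seq, tail[:j], list(quals[:j]))
                )
    if n_hard:
        log.warning("%d hard-clipped read ends carried no bases and were ignored", n_hard)
    return out


ReferenceLike = Union[Mapping[str, str], "pyfaidx.Fasta"]  # noqa: F821


def _chrom_seq_len(reference, chrom: str) -> int:
    try:
        return len(reference[chrom])
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in reference") from exc


def fetch_reference(reference: ReferenceLike, chrom: str, start: int, end: int) -> str:
    """Return the uppercased reference subsequence ``[start, end)``.

    ``reference`` is either a pyfaidx ``Fasta`` handle or a plain
    ``{chrom: sequence}`` mapping (as produced by the simulator).
    """
    n = _chrom_seq_len(reference, chrom)
    if not (0 <= start < end <= n):
        raise ValueError(
            f"requested {chrom}:{start}-{end} outside available bounds [0, {n})"
        )
    piece = reference[chrom][start:end]
    return str(piece).upper()


def open_reference(path: Union[str, Path]):
    """Open an indexed FASTA file (builds the .fai if missing)."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# call tables

CALL_COLUMNS = [
    "chromA", "posA", "strandA", "chromB", "posB", "strandB",
    "sv_class", "S", "log10_S", "n_reads",
]


def calls_to_dataframe(calls: Sequence) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate SV calls (1-based positions, breakend strands)."""
    import pandas as pd

    rows = []
    for c in calls:
        spec = c.junction.spec
        rows.append(
            {
                "chromA": spec.bpA.chrom,
                "posA": spec.bpA.pos + 1,
                "strandA": "+" if spec.bpA.side == "right" else "-",
                "chromB": spec.bpB.chrom,
                "posB": spec.bpB.pos + 1,
                "strandB": "+" if spec.bpB.side == "left" else "-",
                "sv_class": c.junction.sv_class,
                "S": c.score.S,
                "log10_S": c.score.log10_S,
                "n_reads": c.score.n_reads,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_call_table(calls: Sequence, path: Union[str, Path]) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedpe(calls: Sequence, path: Union[str, Path], slop: int = 0) -> None:
    """BEDPE export of calls (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            spec = c.junction.spec
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            spec.bpA.chrom, max(0, spec.bpA.pos - slop), spec.bpA.pos + 1 + slop,
                            spec.bpB.chrom, max(0, spec.bpB.pos - slop), spec.bpB.pos + 1 + slop,
                            f"call_{i}", f"{c.score.S:.6g}",
                            "+" if spec.bpA.side == "right" else "-",
                            "+" if spec.bpB.side == "left" else "-",
                        ],
                    )
                )
                + "\n"
            )


def coverage_track(reads: Iterable[AlignedRead], chrom_lengths: Mapping[str, int]):
    """Per-base depth arrays (aligned reference span of each read)."""
    import numpy as np

    depth = {c: np.zeros(int(n), dtype=np.int32) for c, n in chrom_lengths.items()}
    for r in reads:
        arr = depth.get(r.chrom)
        if arr is None:
            continue
        arr[max(0, r.ref_start) : min(len(arr), r.ref_end)] += 1
    return depth
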
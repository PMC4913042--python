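"""Synthetic references, planted SVs, and reads with truth alignments.

The simulator builds small random genomes, realizes planted structural
variants as "donor" chromosomes (segment lists over the reference), samples
reads from the donor, and emits truth alignments back onto the reference in
which junction-crossing reads carry the exact soft-clip structure an
aligner would produce: the longer reference segment is the primary
alignment, the shorter side is soft-clipped at the junction coordinate.
This lets the whole caller run end-to-end with a known answer and no
external aligner.

The replica preset mirrors a targeted leukemia translocation panel: 8
capture regions (one per fusion partner of the four recurrent B-ALL
translocations), a 4-sample training cohort with 7 planted junctions, and
a 23-sample test cohort with 31 planted junctions, scaled to 10-kb
regions with 250-bp single-end reads at 30x coverage.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import AlignedRead, revcomp
from .junctions import Breakend, JunctionSpec, classify

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# RNG stream constants: one stream per purpose so changing e.g. the error
# rate never shifts read positions.
_STREAM_GENOME = 101
_STREAM_POSITIONS = 202
_STREAM_ERRORS = 303
_STREAM_STRANDS = 404


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 100_000
    read_length: int = 250
    coverage: float = 30.0
    substitution_error_rate: float = 0.0
    quality_profile: str = "constant"  # "constant" | "linear-decay"
    base_quality: int = 35
    paired: bool = False
    insert_mean: int = 500
    insert_sd: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.read_length) <= 0:
            raise ValueError("n_chroms, chrom_length, read_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution_error_rate must be in [0, 1)")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def simulate_reference(
    config: SimConfig,
    chrom_names: Optional[Sequence[str]] = None,
    repeat_block: Optional[Tuple[str, int, str, int]] = None,
) -> Dict[str, str]:
    """I.i.d. uniform-ACGT chromosomes, deterministic for a given seed.

    ``repeat_block=(chrom, pos, unit, n)`` optionally overwrites a region
    with a perfect tandem repeat for repeat-failure tests.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    names = list(chrom_names) if chrom_names else [f"chr{i + 1}" for i in range(config.n_chroms)]
    ref = {}
    for name in names:
        idx = rng.integers(0, 4, size=config.chrom_length)
        ref[name] = "".join(_BASES[idx])
    if repeat_block is not None:
        chrom, pos, unit, n = repeat_block
        block = (unit * n)[: len(ref[chrom]) - pos]
        ref[chrom] = ref[chrom][:pos] + block + ref[chrom][pos + len(block):]
    return ref


# ---------------------------------------------------------------------------
# donor construction


@dataclass(frozen=True)
class Segment:
    """A donor interval mapped to a reference interval.

    ``strand == "-"`` means the donor carries the reverse complement of
    ``ref[ref_start:ref_end]``.
    """

    donor_start: int
    donor_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"


@dataclass
class DonorChrom:
    name: str
    segments: List[Segment]
    seq: str


@dataclass
class DonorGenome:
    chroms: Dict[str, DonorChrom]

    @property
    def total_length(self) -> int:
        return sum(len(c.seq) for c in self.chroms.values())


@dataclass
class SVPlan:
    sv_class: str  # deletion | duplication | inversion | translocation
    chromA: str
    posA: int
    chromB: str
    posB: int
    reciprocal: bool = False

    def __post_init__(self):
        if self.sv_class in ("deletion", "duplication", "inversion"):
            if self.chromA != self.chromB:
                raise ValueError(f"{self.sv_class} requires a single chromosome")
            if not self.posA < self.posB:
                raise ValueError(f"{self.sv_class} requires posA < posB")
        elif self.sv_class == "translocation":
            if self.chromA == self.chromB:
                raise ValueError("translocation requires two chromosomes")
        else:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")


@dataclass
class TruthSV:
    """One planted junction: canonical breakend pair plus class."""

    spec: JunctionSpec
    sv_class: str


def _segments_to_seq(segments: Sequence[Segment], reference) -> str:
    parts = []
    for s in segments:
        piece = str(reference[s.ref_chrom][s.ref_start:s.ref_end]).upper()
        parts.append(piece if s.strand == "+" else revcomp(piece))
    return "".join(parts)


def _merge_adjacent(raw: Sequence[Tuple[str, int, int, str]]) -> List[Tuple[str, int, int, str]]:
    """Fuse reference-contiguous forward pieces so that only true junctions
    remain as segment boundaries."""
    merged: List[Tuple[str, int, int, str]] = []
    for chrom, lo, hi, strand in raw:
        if hi <= lo:
            continue
        if (merged and strand == "+" and merged[-1][3] == "+"
                and merged[-1][0] == chrom and merged[-1][2] == lo):
            merged[-1] = (chrom, merged[-1][1], hi, "+")
        else:
            merged.append((chrom, lo, hi, strand))
    return merged


def _with_donor_coords(raw: Sequence[Tuple[str, int, int, str]]) -> List[Segment]:
    segs, off = [], 0
    for chrom, lo, hi, strand in _merge_adjacent(raw):
        segs.append(Segment(off, off + (hi - lo), chrom, lo, hi, strand))
        off += hi - lo
    return segs


def plant_svs(
    reference: Dict[str, str],
    plans: Sequence[SVPlan],
    min_separation: int = 1000,
) -> Tuple[DonorGenome, List[TruthSV]]:
    """Realize planted SVs as donor chromosomes plus a truth table.

    Intra-chromosomal plans on a shared chromosome must be separated by at
    least ``min_separation`` bases; a chromosome entering a translocation
    may carry no other plan.  A non-reciprocal translocation builds a single
    fusion chromosome (the unjoined arms are dropped); ``reciprocal`` emits
    both derivatives and conserves total length.
    """
    intra: Dict[str, List[SVPlan]] = {}
    translocated: Dict[str, SVPlan] = {}
    for p in plans:
        if p.sv_class == "translocation":
            for c in (p.chromA, p.chromB):
                if c in translocated or c in intra:
                    raise ValueError(f"overlapping plans on chromosome {c}")
                translocated[c] = p
        else:
            if p.chromA in translocated:
                raise ValueError(f"overlapping plans on chromosome {p.chromA}")
            intra.setdefault(p.chromA, []).append(p)
    for chrom, ps in intra.items():
        ps.sort(key=lambda p: p.posA)
        for a, b in zip(ps, ps[1:]):
            if b.posA - a.posB < min_separation:
                raise ValueError(
                    f"plans on {chrom} overlap within {min_separation} bp: {a} / {b}"
                )

    donor_chroms: Dict[str, DonorChrom] = {}
    truth: List[TruthSV] = []

    def add_junction(bp1: Breakend, bp2: Breakend):
        spec = JunctionSpec(bp1, bp2, source="truth")
        truth.append(TruthSV(spec, classify(spec.bpA, spec.bpB)))

    seen_translocations = set()
    for chrom in reference:
        n = len(reference[chrom])
        if chrom in translocated:
            p = translocated[chrom]
            if id(p) in seen_translocations:
                continue
            seen_translocations.add(id(p))
            lenB = len(reference[p.chromB])
            der1 = _with_donor_coords(
                [(p.chromA, 0, p.posA, "+"), (p.chromB, p.posB, lenB, "+")]
            )
            name1 = f"der_{p.chromA}_{p.chromB}"
            donor_chroms[name1] = DonorChrom(name1, der1, _segments_to_seq(der1, reference))
            add_junction(Breakend(p.chromA, p.posA, "right"), Breakend(p.chromB, p.posB, "left"))
            if p.reciprocal:
                der2 = _with_donor_coords(
                    [(p.chromB, 0, p.posB, "+"), (p.chromA, p.posA, len(reference[p.chromA]), "+")]
                )
                name2 = f"der_{p.chromB}_{p.chromA}"
                donor_chroms[name2] = DonorChrom(name2, der2, _segments_to_seq(der2, reference))
                add_junction(Breakend(p.chromB, p.posB, "right"), Breakend(p.chromA, p.posA, "left"))
            continue

        raw: List[Tuple[str, int, int, str]] = []
        cursor = 0
        for p in intra.get(chrom, []):
            raw.append((chrom, cursor, p.posA, "+"))
            if p.sv_class == "deletion":
                add_junction(Breakend(chrom, p.posA, "right"), Breakend(chrom, p.posB, "left"))
            elif p.sv_class == "inversion":
                raw.append((chrom, p.posA, p.posB, "-"))
                add_junction(Breakend(chrom, p.posA, "right"), Breakend(chrom, p.posB, "right"))
                add_junction(Breakend(chrom, p.posA, "left"), Breakend(chrom, p.posB, "left"))
            elif p.sv_class == "duplication":
                raw.append((chrom, p.posA, p.posB, "+"))
                raw.append((chrom, p.posA, p.posB, "+"))
                add_junction(Breakend(chrom, p.posB, "right"), Breakend(chrom, p.posA, "left"))
            cursor = p.posB
        raw.append((chrom, cursor, n, "+"))
        segs = _with_donor_coords(raw)
        donor_chroms[chrom] = DonorChrom(chrom, segs, _segments_to_seq(segs, reference))

    return DonorGenome(donor_chroms), truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimRead:
    read_id: str
    donor_chrom: str
    start: int           # donor coordinates, [start, end)
    end: int
    reverse: bool        # machine read is the reverse complement of the donor slice
    seq: str             # machine orientation, with errors applied
    quals: List[int]
    is_read1: bool = True
    mate: Optional[int] = None  # index of the mate in the emitted list


def _quality_vector(config: SimConfig) -> List[int]:
    L, q0 = config.read_length, config.base_quality
    if config.quality_profile == "constant":
        return [q0] * L
    if config.quality_profile == "linear-decay":
        drop = 20
        return [max(2, round(q0 - drop * i / max(1, L - 1))) for i in range(L)]
    raise ValueError(f"unknown quality_profile {config.quality_profile!r}")


def simulate_reads(donor: DonorGenome, config: SimConfig) -> List[SimRead]:
    """Sample reads uniformly from the donor genome.

    Single-end by default; ``config.paired`` samples fragments of normally
    distributed length and reports both ends (R2 reverse-complemented).
    Substitution errors are applied at the configured rate; base qualities
    follow the configured profile.  Deterministic for a given seed.
    """
    pos_rng = _rng(config.seed, _STREAM_POSITIONS)
    err_rng = _rng(config.seed, _STREAM_ERRORS)
    strand_rng = _rng(config.seed, _STREAM_STRANDS)

    chroms = [c for c in donor.chroms.values() if len(c.seq) >= config.read_length]
    if not chroms:
        return []
    lengths = np.array([len(c.seq) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    total = int(lengths.sum())
    L = config.read_length
    quals = _quality_vector(config)

    def apply_errors(seq: str) -> str:
        if config.substitution_error_rate <= 0:
            return seq
        n_err = err_rng.binomial(len(seq), config.substitution_error_rate)
        if n_err == 0:
            return seq
        positions = err_rng.choice(len(seq), size=n_err, replace=False)
        out = list(seq)
        for p in positions:
            cur = out[p]
            alts = [b for b in "ACGT" if b != cur]
            out[p] = alts[err_rng.integers(0, 3)]
        return "".join(out)

    reads: List[SimRead] = []
    if not config.paired:
        n_reads = round(config.coverage * total / L)
        chrom_idx = pos_rng.choice(len(chroms), size=n_reads, p=weights)
        for i in range(n_reads):
            c = chroms[chrom_idx[i]]
            start = int(pos_rng.integers(0, len(c.seq) - L + 1))
            rev = bool(strand_rng.integers(0, 2))
            piece = c.seq[start : start + L]
            machine = revcomp(piece) if rev else piece
            reads.append(
                SimRead(f"read_{i:07d}", c.name, start, start + L, rev,
                        apply_errors(machine), list(quals))
            )
        return reads

    n_frags = round(config.coverage * total / (2 * L))
    chrom_idx = pos_rng.choice(len(chroms), size=n_frags, p=weights)
    for i in range(n_frags):
        c = chroms[chrom_idx[i]]
        flen = int(max(2 * L, round(pos_rng.normal(config.insert_mean, config.insert_sd))))
        flen = min(flen, len(c.seq))
        fs = int(pos_rng.integers(0, len(c.seq) - flen + 1))
        fe = fs + flen
        r1 = SimRead(f"frag_{i:07d}", c.name, fs, fs + L, False,
                     apply_errors(c.seq[fs : fs + L]), list(quals), is_read1=True)
        r2 = SimRead(f"frag_{i:07d}", c.name, fe - L, fe, True,
                     apply_errors(revcomp(c.seq[fe - L : fe])), list(quals), is_read1=False)
        r1.mate = len(reads) + 1
        r2.mate = len(reads)
        reads.extend([r1, r2])
    return reads


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = "" if r.mate is None else ("/1" if r.is_read1 else "/2")
            fh.write(f"@{r.read_id}{suffix}\n{r.seq}\n+\n")
            fh.write("".join(chr(min(q, 93) + 33) for q in r.quals) + "\n")


# ---------------------------------------------------------------------------
# truth alignments


def emit_truth_alignments(
    reads: Sequence[SimRead],
    donor: DonorGenome,
) -> Tuple[List[AlignedRead], List[str]]:
    """Map simulated reads back to reference coordinates as a truth SAM.

    A read contained in one donor segment gets a full-match CIGAR.  A read
    crossing a junction is aligned to its longest reference segment with the
    remainder soft-clipped, reproducing the stack/tail structure the caller
    consumes; the soft-clip boundary falls exactly at the junction
    coordinate.  Reads crossing two or more junctions are assigned to their
    longest single segment and their ids returned as flagged.

    Returns (alignments, flagged_read_ids).
    """
    out: List[AlignedRead] = []
    flagged: List[str] = []

    for r in reads:
        segs = donor.chroms[r.donor_chrom].segments
        pieces = [
            (max(r.start, s.donor_start), min(r.end, s.donor_end), s)
            for s in segs
            if s.donor_start < r.end and s.donor_end > r.start
        ]
        if not pieces:
            continue
        if len(pieces) > 2:
            flagged.append(r.read_id)
        ps, pe, seg = max(pieces, key=lambda t: (t[1] - t[0], -t[0]))
        left_d = ps - r.start          # donor-frame clip lengths
        right_d = r.end - pe
        m = pe - ps

        # donor-frame read (errors included)
        donor_frame = revcomp(r.seq) if r.reverse else r.seq
        donor_quals = r.quals[::-1] if r.reverse else r.quals

        if seg.strand == "+":
            ref_start = seg.ref_start + (ps - seg.donor_start)
            cigar = [("S", left_d), ("M", m), ("S", right_d)]
            seq, quals = donor_frame, donor_quals
            minus = r.reverse
        else:
            ref_start = seg.ref_end - (pe - seg.donor_start)
            cigar = [("S", right_d), ("M", m), ("S", left_d)]
            seq, quals = revcomp(donor_frame), donor_quals[::-1]
            minus = not r.reverse
        cigar = [(op, n) for op, n in cigar if n > 0]
        out.append(
            AlignedRead(
                read_id=r.read_id,
                chrom=seg.ref_chrom,
                ref_start=ref_start,
                cigar=cigar,
                seq=seq,
                quals=list(quals),
                mapq=60,
                strand="-" if minus else "+",
                is_paired=r.mate is not None,
                is_read1=r.is_read1,
            )
        )

    # mate fields for paired reads
    if any(r.mate is not None for r in reads):
        aligned_by_key = {(a.read_id, a.is_read1): a for a in out}
        for a in out:
            if not a.is_paired:
                continue
            mate = aligned_by_key.get((a.read_id, not a.is_read1))
            if mate is not None:
                a.mate_chrom = mate.chrom
                a.mate_start = mate.ref_start
                a.mate_strand = mate.strand
    return out, flagged


# ---------------------------------------------------------------------------
# replica preset: targeted leukemia translocation panel

#: fusion type → (chromosome of slot-A region, chromosome of slot-B region)
REPLICA_TYPES = {
    "t(1;19)": ("chr1", "chr19"),
    "t(4;11)": ("chr4", "chr11"),
    "t(9;22)": ("chr9", "chr22"),
    "t(12;21)": ("chr12", "chr21"),
}
REPLICA_REGION_LENGTH = 10_000
REPLICA_CHROMS = [c for pair in REPLICA_TYPES.values() for c in pair]


@dataclass
class ReplicaSample:
    name: str
    sv_type: str
    reciprocal: bool
    role: str  # "train" | "test"

    @property
    def n_junctions(self) -> int:
        return 2 if self.reciprocal else 1


def replica_design(n_test: int = 23, n_train: int = 4) -> List[ReplicaSample]:
    """Sample sheet of the replica: 23 test samples carrying 31 junctions
    (8 reciprocal + 15 single) and 4 training samples carrying 7 junctions
    (3 reciprocal + 1 single)."""
    types = list(REPLICA_TYPES)
    design: List[ReplicaSample] = []
    for i in range(n_train):
        design.append(
            ReplicaSample(f"train_{i:02d}", types[i % len(types)], reciprocal=i < 3, role="train")
        )
    for i in range(n_test):
        design.append(
            ReplicaSample(f"test_{i:02d}", types[i % len(types)], reciprocal=i % 3 == 0, role="test")
        )
    return design


def replica_bookkeeping(design: Optional[List[ReplicaSample]] = None) -> Dict[str, int]:
    """Printed-count bookkeeping of the test cohort: samples, regions,
    planted translocations, and unrearranged region instances."""
    design = design or replica_design()
    test = [s for s in design if s.role == "test"]
    n_regions = len(REPLICA_CHROMS)
    n_junctions = sum(s.n_junctions for s in test)
    return {
        "n_samples": len(test),
        "n_regions": n_regions,
        "n_translocations": n_junctions,
        "n_normal_instances": len(test) * n_regions - n_junctions,
    }


def replica_reference(seed: int) -> Dict[str, str]:
    cfg = SimConfig(n_chroms=len(REPLICA_CHROMS), chrom_length=REPLICA_REGION_LENGTH, seed=seed)
    return simulate_reference(cfg, chrom_names=REPLICA_CHROMS)


def replica_sample_plans(
    sample: ReplicaSample,
    seed: int,
    margin: int = 2000,
) -> List[SVPlan]:
    """Breakpoint positions for one sample (deterministic per sample name)."""
    tag = zlib.crc32(sample.name.encode()) % 100_000
    rng = _rng(seed, 1000 + tag)
    chromA, chromB = REPLICA_TYPES[sample.sv_type]
    lo, hi = margin, REPLICA_REGION_LENGTH - margin
    posA = int(rng.integers(lo, hi))
    posB = int(rng.integers(lo, hi))
    return [SVPlan("translocation", chromA, posA, chromB, posB, reciprocal=sample.reciprocal)]


def simulate_replica_sample(
    reference: Dict[str, str],
    sample: ReplicaSample,
    seed: int,
    error_rate: float = 0.0,
) -> Tuple[List[AlignedRead], List[TruthSV]]:
    """Donor, reads and truth alignments for one replica sample."""
    plans = replica_sample_plans(sample, seed)
    donor, truth = plant_svs(reference, plans)
    tag = zlib.crc32(sample.name.encode()) % 100_000
    cfg = SimConfig(
        read_length=250,
        coverage=30.0,
        substitution_error_rate=error_rate,
        seed=(seed * 131 + tag) % (2**31),
    )
    reads = simulate_reads(donor, cfg)
    alignments, _ = emit_truth_alignments(reads, donor)
    return alignments, truth
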
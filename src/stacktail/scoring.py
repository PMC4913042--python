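"""Support scoring of candidate junctions.

Every stacked (soft-clipped) read is locally realigned to each candidate
junction sequence.  A read i that aligns across the concatenation point
covers l_A bases on the A side and l_B bases on the B side; with alignment
quality Q_i in [0, 1] its evidence for the junction is

    Q_i * min(l_A, l_B)

and the junction's support is the sum over reads:

    S = sum_i Q_i * min(l_A,i, l_B,i)

Reads that align entirely to one flank have min(l_A, l_B) = 0 and
contribute nothing, so S measures only junction-spanning evidence.
Thresholds are applied on log10(S).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import Align

from .alignment_io import revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentScheme:
    """Local-alignment scoring parameters.

    Gap convention: the first base of a gap scores ``gap_open``, each
    further base ``gap_extend`` (a length-k gap scores
    ``gap_open + (k-1) * gap_extend``).
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: float = 20.0


@dataclass
class LocalAlignment:
    read_id: str
    junction_id: str
    read_interval: Tuple[int, int]      # [qstart, qend) on the (oriented) read
    junction_interval: Tuple[int, int]  # [jstart, jend) on the junction
    score: float
    n_matches: int
    n_mismatches: int
    n_gap_bases: int
    strand: str  # "+" | "-"


@dataclass
class SupportContribution:
    read_id: str
    junction_id: str
    Q: float
    l_A: int
    l_B: int

    @property
    def contribution(self) -> float:
        return self.Q * min(self.l_A, self.l_B)


@dataclass
class JunctionScore:
    junction_id: str
    S: float
    log10_S: float
    n_reads: int
    contributions: List[SupportContribution] = field(default_factory=list)
    S_adjusted: Optional[float] = None


_ALIGNER_CACHE: dict = {}


def _aligner(scheme: AlignmentScheme) -> Align.PairwiseAligner:
    key = (scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner(
            mode="local",
            match_score=scheme.match,
            mismatch_score=scheme.mismatch,
            open_gap_score=scheme.gap_open,
            extend_gap_score=scheme.gap_extend,
        )
        _ALIGNER_CACHE[key] = aligner
    return aligner


def _read_seq(read) -> str:
    """Full sequence (stack + tail) of a ClippedRead / AlignedRead / str."""
    if isinstance(read, str):
        return read
    if hasattr(read, "read"):  # ClippedRead
        return read.read.seq
    return read.seq


def _read_id(read) -> str:
    if isinstance(read, str):
        return read  # bare sequences identify themselves
    if hasattr(read, "read"):
        return read.read.read_id
    return read.read_id


def align_read_to_junction(
    read,
    junction,
    scheme: AlignmentScheme = AlignmentScheme(),
) -> Optional[LocalAlignment]:
    """Best Smith–Waterman local alignment of a read against a junction.

    Both strands are tried (a strand tie keeps "+"); None is returned when
    the best score falls below ``scheme.min_score`` or either sequence is
    empty.  Intervals for a minus-strand hit are on the reverse-complemented
    read.
    """
    jseq = junction.seq if hasattr(junction, "seq") else str(junction)
    qseq = _read_seq(read)
    if not jseq or not qseq:
        return None
    aligner = _aligner(scheme)

    best = None  # (score, strand, oriented query)
    for strand, q in (("+", qseq), ("-", revcomp(qseq))):
        score = aligner.score(jseq, q)
        if best is None or score > best[0]:
            best = (score, strand, q)
    score, strand, q = best
    if score < scheme.min_score:
        return None

    aln = aligner.align(jseq, q)[0]
    tgt_blocks, qry_blocks = aln.aligned
    jstart, jend = int(tgt_blocks[0][0]), int(tgt_blocks[-1][1])
    qstart, qend = int(qry_blocks[0][0]), int(qry_blocks[-1][1])
    n_match = n_mis = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        aligned_len += te - ts
        for a, b in zip(jseq[ts:te], q[qs:qe]):
            if a == b:
                n_match += 1
            else:
                n_mis += 1
    n_gaps = (jend - jstart - aligned_len) + (qend - qstart - aligned_len)
    jid = junction.junction_id if hasattr(junction, "junction_id") else "junction"
    return LocalAlignment(
        read_id=_read_id(read),
        junction_id=jid,
        read_interval=(qstart, qend),
        junction_interval=(jstart, jend),
        score=float(score),
        n_matches=n_match,
        n_mismatches=n_mis,
        n_gap_bases=n_gaps,
        strand=strand,
    )


def compute_alignment_quality(
    aln: LocalAlignment,
    read_length: int,
    scheme: AlignmentScheme = AlignmentScheme(),
) -> float:
    """Alignment quality Q = score / (match * read length), clipped to [0, 1].

    A perfect full-length alignment has Q = 1, so a read's contribution is
    then exactly the number of bases it aligns on the lesser side of the
    junction.
    """
    if read_length <= 0:
        return 0.0
    q = aln.score / (scheme.match * read_length)
    return max(0.0, min(1.0, q))


def read_support(aln: LocalAlignment, junction, Q: float) -> SupportContribution:
    """Split the aligned junction interval at the breakpoint offset."""
    jstart, jend = aln.junction_interval
    off = junction.breakpoint_offset
    l_A = max(0, min(jend, off) - jstart)
    l_B = max(0, jend - max(jstart, off))
    return SupportContribution(aln.read_id, aln.junction_id, Q, l_A, l_B)


def score_junction(
    junction_id: str,
    contribs: Sequence[SupportContribution],
) -> JunctionScore:
    """Sum read contributions into the junction's support S."""
    for c in contribs:
        if c.junction_id != junction_id:
            raise ValueError(f"contribution for {c.junction_id} mixed into {junction_id}")
    S = float(sum(c.contribution for c in contribs))
    n = sum(1 for c in contribs if c.contribution > 0)
    log10_S = math.log10(S) if S > 0 else float("-inf")
    return JunctionScore(junction_id, S, log10_S, n, list(contribs))


def score_junctions(
    clipped_reads: Iterable,
    junctions: Sequence,
    scheme: AlignmentScheme = AlignmentScheme(),
    winner_takes_all: bool = False,
) -> List[Tuple]:
    """Align every stacked read to every junction and score the library.

    Each physical read contributes at most once per junction (a read clipped
    at both ends is aligned once).  By default a read may support several
    junctions; with ``winner_takes_all`` it keeps only its single best
    contribution across the library.

    Returns ``[(CandidateJunction, JunctionScore), ...]``.
    """
    unique = {}
    for cr in clipped_reads:
        unique.setdefault(_read_id(cr), cr)
    per_junction = {j.junction_id: [] for j in junctions}
    for rid, cr in unique.items():
        rlen = len(_read_seq(cr))
        contribs = []
        for j in junctions:
            aln = align_read_to_junction(cr, j, scheme)
            if aln is None:
                continue
            Q = compute_alignment_quality(aln, rlen, scheme)
            contribs.append((j.junction_id, read_support(aln, j, Q)))
        if winner_takes_all and contribs:
            contribs = [max(contribs, key=lambda t: t[1].contribution)]
        for jid, sc in contribs:
            per_junction[jid].append(sc)
    return [(j, score_junction(j.junction_id, per_junction[j.junction_id]))
            for j in junctions]


def adjust_score_for_coverage(
    score: JunctionScore,
    local_cov: float,
    baseline_cov: float,
) -> JunctionScore:
    """Linear coverage normalization for whole-genome scoring.

    S_adjusted = S * baseline / max(local, baseline): junctions in deeper-
    than-baseline (typically repetitive) regions are down-weighted
    proportionally; coverage at or below baseline leaves S unchanged (low
    coverage is never up-weighted).  The raw S is retained alongside.
    """
    if baseline_cov <= 0:
        raise ValueError("baseline_cov must be > 0")
    if local_cov <= 0:
        log.warning("%s: non-positive local coverage; score left unadjusted",
                    score.junction_id)
        score.S_adjusted = score.S
        return score
    score.S_adjusted = score.S * baseline_cov / max(local_cov, baseline_cov)
    return score
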
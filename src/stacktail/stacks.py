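"""Breakpoint-candidate detection from soft-clip stacks.

Reads sharing a soft-clip coordinate form a "stack"; a recurrent alignment
stop (right clip) or start (left clip) coordinate is a candidate breakpoint.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, List

log = logging.getLogger(__name__)


@dataclass
class BreakpointCandidate:
    """A recurrent clip coordinate with its supporting reads."""

    chrom: str
    pos: int
    clip_side: str  # "left" | "right"
    n_reads: int
    member_reads: list = field(default_factory=list)  # read ids

    @property
    def key(self):
        return (self.chrom, self.pos, self.clip_side)


def find_breakpoint_candidates(
    clipped: Iterable,
    min_stack_reads: int = 2,
    fuzz: int = 0,
) -> List[BreakpointCandidate]:
    """Cluster clipped reads into candidate breakpoints.

    Reads are grouped by (chrom, clip side) and clustered greedily around
    modal clip positions: the most frequent remaining position (ties to the
    smallest coordinate) seeds a cluster that absorbs positions within
    ``fuzz`` bases.  Clusters with at least ``min_stack_reads`` members
    become candidates located at the modal position.  With ``fuzz=0`` this
    is an exact group-by.
    """
    if min_stack_reads < 1:
        raise ValueError("min_stack_reads must be >= 1")
    if fuzz < 0:
        raise ValueError("fuzz must be >= 0")

    groups = defaultdict(list)
    for cr in clipped:
        groups[(cr.chrom, cr.clip_side)].append(cr)

    out: List[BreakpointCandidate] = []
    for (chrom, side), members in groups.items():
        by_pos = defaultdict(list)
        for cr in members:
            by_pos[cr.clip_pos].append(cr.read.read_id)
        counts = Counter({p: len(ids) for p, ids in by_pos.items()})
        while counts:
            mode = min(counts, key=lambda p: (-counts[p], p))
            absorbed = [p for p in counts if abs(p - mode) <= fuzz]
            ids = sorted(rid for p in absorbed for rid in by_pos[p])
            if len(ids) >= min_stack_reads:
                out.append(BreakpointCandidate(chrom, mode, side, len(ids), ids))
            for p in absorbed:
                del counts[p]
    out.sort(key=lambda c: (c.chrom, c.pos, c.clip_side))
    return out


def candidate_density_filter(
    candidates: List[BreakpointCandidate],
    max_per_kb: float,
    window: int = 1000,
) -> List[BreakpointCandidate]:
    """Cap candidate density to guard the pairing combinatorics.

    Within each fixed ``window``-sized tile of a chromosome, only the
    ``max_per_kb`` best-supported candidates (ties to the smallest position)
    are kept.
    """
    if max_per_kb <= 0:
        raise ValueError("max_per_kb must be > 0")
    cap = int(max_per_kb)
    tiles = defaultdict(list)
    for c in candidates:
        tiles[(c.chrom, c.pos // window)].append(c)
    keep = set()
    n_dropped = 0
    for tile, cands in tiles.items():
        ranked = sorted(cands, key=lambda c: (-c.n_reads, c.pos, c.clip_side))
        keep.update(id(c) for c in ranked[:cap])
        n_dropped += max(0, len(cands) - cap)
    if n_dropped:
        log.info("density filter dropped %d candidates (cap %d per %d bp)", n_dropped, cap, window)
    return [c for c in candidates if id(c) in keep]


def candidates_to_bed(candidates: List[BreakpointCandidate], path) -> None:
    """BED export (0-based half-open; name = clip side, score = read count)."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.clip_side}\t{c.n_reads}\n")
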
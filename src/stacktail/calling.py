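"""From scored junctions to SV calls.

Covers threshold training (midpoint between the lowest-scoring true
positive and the false positive immediately below it), thresholding on
log10(S), single-linkage collapsing of near-duplicate predictions,
windowed call-set comparison, and evaluation against a simulated truth
table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

log = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    threshold: float = 2.985045       # on the log10(S) scale
    collapse_window: int = 500
    comparison_window: int = 500
    use_adjusted: bool = False

    def __post_init__(self):
        if self.collapse_window < 0 or self.comparison_window < 0:
            raise ValueError("windows must be >= 0")


@dataclass
class SVCall:
    junction: "CandidateJunction"  # noqa: F821
    score: "JunctionScore"         # noqa: F821
    passed: bool = False
    rank: int = 0
    cluster_id: Optional[int] = None
    cluster_size: int = 1

    @property
    def sv_class(self) -> str:
        return self.junction.sv_class

    def comparison_value(self, use_adjusted: bool = False) -> float:
        s = self.score.S
        if use_adjusted and self.score.S_adjusted is not None:
            s = self.score.S_adjusted
        return math.log10(s) if s > 0 else float("-inf")

    @property
    def coords(self):
        spec = self.junction.spec
        return (spec.bpA.chrom, spec.bpA.pos, spec.bpA.side,
                spec.bpB.chrom, spec.bpB.pos, spec.bpB.side)


def train_threshold(labeled: Sequence[Tuple[float, bool]]) -> float:
    """Train the support threshold from labeled log10(S) scores.

    Returns the midpoint between the lowest-scoring true positive t and the
    highest false positive strictly below t; with no false positive below t
    the fallback is t/2.  The result is strictly below every true positive,
    guaranteeing full sensitivity on the training set.
    """
    trues = [s for s, is_true in labeled if is_true]
    if not trues:
        raise ValueError("threshold training requires at least one true-labeled score")
    t = min(trues)
    falses_below = [s for s, is_true in labeled if not is_true and s < t]
    if falses_below:
        return (t + max(falses_below)) / 2.0
    return t / 2.0


def call_svs(
    scored: Sequence[Tuple],
    config: CallerConfig,
) -> List[SVCall]:
    """Threshold and rank scored junctions.

    ``scored`` is ``[(CandidateJunction, JunctionScore), ...]``.  A call
    passes when its comparison score (log10 of adjusted S if configured) is
    >= threshold (closed comparison: a score exactly at threshold passes).
    Calls are ranked by descending score, ties broken by junction
    coordinates.
    """
    calls = [SVCall(j, s) for j, s in scored]
    for c in calls:
        c.passed = c.comparison_value(config.use_adjusted) >= config.threshold
    calls.sort(key=lambda c: (-c.comparison_value(config.use_adjusted), c.coords))
    for i, c in enumerate(calls):
        c.rank = i + 1
    return calls


def _collapse_key(call: SVCall):
    spec = call.junction.spec
    return (call.sv_class, spec.bpA.side, spec.bpB.side, spec.bpA.chrom, spec.bpB.chrom)


def collapse_calls(calls: Sequence[SVCall], window: int = 500) -> List[SVCall]:
    """Collapse near-duplicate calls into single representatives.

    Calls with the same SV class, breakend sides and chromosome pair whose
    corresponding breakpoints each lie within ``window`` bases are clustered
    by single linkage; each cluster's highest-scoring member (ties to the
    smallest coordinates) is kept, retaining its own score and recording the
    cluster size.  Idempotent.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    calls = list(calls)
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    from collections import defaultdict

    groups = defaultdict(list)
    for i, c in enumerate(calls):
        groups[_collapse_key(c)].append(i)
    for idxs in groups.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                a, b = calls[i].junction.spec, calls[j].junction.spec
                if (abs(a.bpA.pos - b.bpA.pos) <= window
                        and abs(a.bpB.pos - b.bpB.pos) <= window):
                    union(i, j)

    clusters = defaultdict(list)
    for i in range(len(calls)):
        clusters[find(i)].append(i)
    reps: List[SVCall] = []
    for cid, members in enumerate(sorted(clusters.values(), key=lambda m: calls[m[0]].coords)):
        rep_i = min(members, key=lambda i: (-calls[i].score.S, calls[i].coords))
        rep = calls[rep_i]
        rep.cluster_id = cid
        rep.cluster_size = len(members)
        reps.append(rep)
    reps.sort(key=lambda c: (-c.score.S, c.coords))
    return reps


def _breakpoint_distance(a, b, window: int) -> Optional[int]:
    """Total breakpoint distance between two calls, or None if unmatched."""
    if (a.bpA.chrom, a.bpB.chrom) != (b.bpA.chrom, b.bpB.chrom):
        return None
    dA, dB = abs(a.bpA.pos - b.bpA.pos), abs(a.bpB.pos - b.bpB.pos)
    if dA <= window and dB <= window:
        return dA + dB
    return None


def compare_call_sets(
    a: Sequence[SVCall],
    b: Sequence[SVCall],
    window: int = 500,
) -> Dict:
    """Windowed intersection of two call sets.

    A call in A matches a call in B when both breakpoints agree within
    ``window`` bases.  Matching is greedy on total breakpoint distance
    (deterministic tie-break by coordinates) with each call used at most
    once, so |A∩B| is symmetric.
    """
    pairs = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            d = _breakpoint_distance(ca.junction.spec, cb.junction.spec, window)
            if d is not None:
                pairs.append((d, ca.coords, cb.coords, i, j))
    pairs.sort()
    used_a, used_b, matches = set(), set(), []
    for d, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, d))
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_matched": len(matches),
        "matches": matches,
        "only_a": [i for i in range(len(a)) if i not in used_a],
        "only_b": [j for j in range(len(b)) if j not in used_b],
    }


@dataclass
class EvaluationResult:
    n_truth: int
    n_calls: int
    n_matched: int
    sensitivity: float
    ppv: Optional[float]  # None (reported as NA) when there are no calls
    n_exact: int          # matched truths recovered at the exact base pair
    per_class: Dict[str, Dict[str, int]] = field(default_factory=dict)
    matched_truth_idx: List[int] = field(default_factory=list)


def evaluate_against_truth(
    calls: Sequence[SVCall],
    truth: Sequence,
    window: int = 500,
) -> EvaluationResult:
    """Sensitivity / PPV of passed calls against a planted truth table.

    ``truth`` entries expose ``spec`` (a JunctionSpec) and ``sv_class``.
    Matching is positional (both breakpoints within ``window``), greedy on
    total distance, one-to-one.
    """
    if not truth:
        raise ValueError("empty truth table")
    passed = [c for c in calls if c.passed]
    pairs = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(passed):
            d = _breakpoint_distance(t.spec, c.junction.spec, window)
            if d is not None:
                pairs.append((d, ti, ci))
    pairs.sort()
    used_t, used_c, matched = set(), set(), []
    n_exact = 0
    per_class: Dict[str, Dict[str, int]] = {}
    for d, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matched.append(ti)
        if d == 0:
            n_exact += 1
    for ti, t in enumerate(truth):
        entry = per_class.setdefault(t.sv_class, {"n_truth": 0, "n_found": 0})
        entry["n_truth"] += 1
        if ti in used_t:
            entry["n_found"] += 1
    return EvaluationResult(
        n_truth=len(truth),
        n_calls=len(passed),
        n_matched=len(used_t),
        sensitivity=len(used_t) / len(truth),
        ppv=(len(used_c) / len(passed)) if passed else None,
        n_exact=n_exact,
        per_class=per_class,
        matched_truth_idx=sorted(matched),
    )


def predict_sample_type(calls: Sequence[SVCall], type_of) -> Optional[str]:
    """Sample-level SV type: the type of the highest-scoring passed call.

    ``type_of`` maps a call to a type label (or None to skip it).  Returns
    None when no passed call has a type.
    """
    for c in sorted((c for c in calls if c.passed), key=lambda c: c.rank):
        t = type_of(c)
        if t is not None:
            return t
    return None


def write_vcf_bnd(calls: Sequence[SVCall], path, chrom_lengths=None) -> None:
    """Minimal VCF 4.2 breakend (BND) export: two records per junction."""
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for c, n in chrom_lengths.items():
            lines.append(f"##contig=<ID={c},length={int(n)}>")
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">')
    lines.append('##INFO=<ID=SUPPORT,Number=1,Type=Float,Description="Junction support S">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    def alt(this, partner):
        # VCF 4.2 bracket notation: this side "right" => sequence continues
        # into the partner after t; "left" => partner precedes t.
        p = f"{partner.chrom}:{partner.pos + 1}"
        if this.side == "right":
            return f"N[{p}[" if partner.side == "left" else f"N]{p}]"
        return f"[{p}[N" if partner.side == "left" else f"]{p}]N"

    for i, c in enumerate(calls):
        spec = c.junction.spec
        a, b = spec.bpA, spec.bpB
        info = f"SVTYPE=BND;SUPPORT={c.score.S:.6g}"
        lines.append(f"{a.chrom}\t{a.pos + 1}\tbnd_{i}_1\tN\t{alt(a, b)}\t.\tPASS\t{info}")
        lines.append(f"{b.chrom}\t{b.pos + 1}\tbnd_{i}_2\tN\t{alt(b, a)}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
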
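"""End-to-end pipelines: targeted calling, whole-genome calling, and the
replica experiment (training + test cohorts) used for validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import alignment_io, calling, junctions, scoring, simulator, stacks

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    min_tail: int = 10
    min_stack_reads: int = 2
    fuzz: int = 0
    flank_margin: int = 50          # flank_len = max read length + margin
    max_candidates_per_kb: float = 20.0
    coverage_k: float = 10.0        # high-coverage exclusion multiplier
    scheme: scoring.AlignmentScheme = field(default_factory=scoring.AlignmentScheme)


@dataclass
class TargetedResult:
    candidates: List
    junctions: List
    scored: List[Tuple]
    calls: List


def run_targeted(
    reads: Iterable,
    reference,
    region_pairs: Sequence[Tuple],
    config: calling.CallerConfig,
    params: PipelineParams = PipelineParams(),
) -> TargetedResult:
    """Stacks → targeted pairing → junction building → scoring → calling."""
    reads = list(reads)
    clipped = alignment_io.extract_clipped_reads(reads, min_tail=params.min_tail)
    candidates = stacks.find_breakpoint_candidates(
        clipped, min_stack_reads=params.min_stack_reads, fuzz=params.fuzz
    )
    candidates = stacks.candidate_density_filter(candidates, params.max_candidates_per_kb)
    specs = junctions.pair_candidates_targeted(candidates, region_pairs)
    max_rl = max((len(r.seq) for r in reads), default=100)
    flank_len = max_rl + params.flank_margin
    lib = [j for j in (junctions.build_junction_sequence(s, flank_len, reference) for s in specs)
           if j is not None]
    scored = scoring.score_junctions(clipped, lib, params.scheme)
    calls = calling.call_svs(scored, config)
    calls = calling.collapse_calls(calls, config.collapse_window)
    return TargetedResult(candidates, lib, scored, calls)


def run_wgs(
    reads: Iterable,
    reference,
    chrom_lengths: Dict[str, int],
    config: calling.CallerConfig,
    candidate_specs: Optional[Sequence] = None,
    params: PipelineParams = PipelineParams(),
    orientation_window: int = 1000,
) -> TargetedResult:
    """Whole-genome mode around externally nominated breakpoint pairs.

    Candidate specs (e.g. from a BEDPE of discordant-pair clusters) are
    refined to nearby soft-clip stacks, orientation-resolved from discordant
    pairs when unknown, filtered for excessive coverage, scored, and
    coverage-adjusted before calling.
    """
    reads = list(reads)
    clipped = alignment_io.extract_clipped_reads(reads, min_tail=params.min_tail)
    candidates = stacks.find_breakpoint_candidates(
        clipped, min_stack_reads=params.min_stack_reads, fuzz=params.fuzz
    )
    depth = alignment_io.coverage_track(reads, chrom_lengths)

    if candidate_specs is None:
        if not any(r.is_paired for r in reads):
            raise ValueError(
                "whole-genome mode without a candidate list requires paired-end reads"
            )
        candidate_specs = discordant_candidate_pairs(reads)

    refined = [junctions.refine_spec_positions(s, candidates) for s in candidate_specs]
    resolved: List = []
    for s in refined:
        if s.orientation_known:
            resolved.append(s)
            continue
        orient = junctions.infer_orientation_from_discordant_pairs(
            reads, s.bpA, s.bpB, window=orientation_window
        )
        if orient is None:
            resolved.extend(junctions.expand_orientations(s))
        else:
            sideA = "right" if orient[0] == junctions.FORWARD else "left"
            sideB = "left" if orient[1] == junctions.FORWARD else "right"
            resolved.append(
                junctions.JunctionSpec(
                    junctions.Breakend(s.bpA.chrom, s.bpA.pos, sideA),
                    junctions.Breakend(s.bpB.chrom, s.bpB.pos, sideB),
                    source="discordant",
                    low_confidence=s.low_confidence,
                )
            )
    resolved = junctions.exclude_high_coverage_regions(resolved, depth, k=params.coverage_k)

    max_rl = max((len(r.seq) for r in reads), default=100)
    flank_len = max_rl + params.flank_margin
    dedup = {}
    for s in resolved:
        dedup.setdefault(s.key, s)
    lib = [j for j in (junctions.build_junction_sequence(s, flank_len, reference)
                       for s in dedup.values())
           if j is not None]
    scored = scoring.score_junctions(clipped, lib, params.scheme)

    import numpy as np

    sampled = np.concatenate([arr[::10] for arr in depth.values()])
    baseline = float(np.median(sampled))

    def local_cov(j):
        vals = []
        for bp in (j.spec.bpA, j.spec.bpB):
            arr = depth.get(bp.chrom)
            if arr is None:
                continue
            lo, hi = max(0, bp.pos - 500), min(len(arr), bp.pos + 500)
            if hi > lo:
                vals.append(float(arr[lo:hi].mean()))
        return sum(vals) / len(vals) if vals else 0.0

    if baseline > 0:
        scored = [(j, scoring.adjust_score_for_coverage(s, local_cov(j), baseline))
                  for j, s in scored]
    calls = calling.call_svs(scored, config)
    calls = calling.collapse_calls(calls, config.collapse_window)
    return TargetedResult(candidates, lib, scored, calls)


def discordant_candidate_pairs(
    reads: Iterable,
    bin_size: int = 1000,
    min_pairs: int = 2,
    max_concordant_insert: int = 10_000,
) -> List:
    """Cluster discordant read pairs into provisional breakpoint pairs."""
    from collections import Counter

    bins = Counter()
    for r in reads:
        if not r.is_paired or r.mate_chrom is None or not r.is_read1:
            continue
        discordant = (
            r.mate_chrom != r.chrom
            or r.mate_strand == r.strand
            or abs((r.mate_start or 0) - r.ref_start) > max_concordant_insert
        )
        if not discordant:
            continue
        a = (r.chrom, r.ref_start // bin_size)
        b = (r.mate_chrom, r.mate_start // bin_size)
        bins[tuple(sorted((a, b)))] += 1
    specs = []
    for (a, b), n in sorted(bins.items()):
        if n < min_pairs or a == b:
            continue
        specs.append(
            junctions.JunctionSpec(
                junctions.Breakend(a[0], a[1] * bin_size + bin_size // 2, "right"),
                junctions.Breakend(b[0], b[1] * bin_size + bin_size // 2, "left"),
                source="discordant",
                orientation_known=False,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# replica experiment


def replica_region_pairs() -> List[Tuple]:
    """Both derivative orders of each canonical fusion, whole regions."""
    L = simulator.REPLICA_REGION_LENGTH
    pairs = []
    for chromA, chromB in simulator.REPLICA_TYPES.values():
        pairs.append(((chromA, 0, L), (chromB, 0, L), "forward", "forward"))
        pairs.append(((chromB, 0, L), (chromA, 0, L), "forward", "forward"))
    return pairs


def junction_type(call) -> Optional[str]:
    """Fusion type of a call from its chromosome pair, if canonical."""
    chroms = frozenset((call.junction.spec.bpA.chrom, call.junction.spec.bpB.chrom))
    for name, pair in simulator.REPLICA_TYPES.items():
        if frozenset(pair) == chroms:
            return name
    return None


@dataclass
class SampleRun:
    sample: simulator.ReplicaSample
    truth: List
    calls: List
    evaluation: Optional[calling.EvaluationResult] = None
    predicted_type: Optional[str] = None


@dataclass
class ReplicaResult:
    threshold: float
    samples: List[SampleRun]
    n_truth: int
    n_matched: int
    sensitivity: float
    ppv: Optional[float]
    n_exact: int
    n_samples: int
    n_type_correct: int


def run_replica(
    seed: int = 1,
    error_rate: float = 0.0,
    params: PipelineParams = PipelineParams(),
    match_window: int = 500,
) -> ReplicaResult:
    """Train on the 4-sample cohort, call the 23-sample test cohort.

    The threshold is trained from the training cohort's junction scores
    labeled against its truth table, then applied unchanged to every test
    sample.  Reported metrics aggregate the test cohort only.
    """
    reference = simulator.replica_reference(seed)
    design = simulator.replica_design()
    region_pairs = replica_region_pairs()

    # training cohort: gather labeled log10 scores
    labeled: List[Tuple[float, bool]] = []
    permissive = calling.CallerConfig(threshold=float("-inf"))
    for sample in (s for s in design if s.role == "train"):
        reads, truth = simulator.simulate_replica_sample(reference, sample, seed, error_rate)
        res = run_targeted(reads, reference, region_pairs, permissive, params)
        for j, sc in res.scored:
            if sc.S <= 0:
                continue
            is_true = any(
                calling._breakpoint_distance(t.spec, j.spec, match_window) is not None
                for t in truth
            )
            labeled.append((sc.log10_S, is_true))
    threshold = calling.train_threshold(labeled)
    config = calling.CallerConfig(threshold=threshold)

    runs: List[SampleRun] = []
    all_matched = all_truth = all_calls = all_exact = matched_calls = 0
    n_type_correct = 0
    for sample in (s for s in design if s.role == "test"):
        reads, truth = simulator.simulate_replica_sample(reference, sample, seed, error_rate)
        res = run_targeted(reads, reference, region_pairs, config, params)
        ev = calling.evaluate_against_truth(res.calls, truth, window=match_window)
        predicted = calling.predict_sample_type(res.calls, junction_type)
        if predicted == sample.sv_type:
            n_type_correct += 1
        runs.append(SampleRun(sample, truth, res.calls, ev, predicted))
        all_truth += ev.n_truth
        all_matched += ev.n_matched
        all_calls += ev.n_calls
        all_exact += ev.n_exact
        matched_calls += ev.n_matched
    return ReplicaResult(
        threshold=threshold,
        samples=runs,
        n_truth=all_truth,
        n_matched=all_matched,
        sensitivity=all_matched / all_truth if all_truth else 0.0,
        ppv=(matched_calls / all_calls) if all_calls else None,
        n_exact=all_exact,
        n_samples=len(runs),
        n_type_correct=n_type_correct,
    )
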
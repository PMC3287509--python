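"""Genome-wide tandem repeat detection.

Candidate periods are seeded from exact k-mer matches at bounded distance
and refined by wraparound dynamic programming against a majority-vote
consensus of the period. The reported score is

    score = match*(#matches) - mismatch*(#mismatches) - indel*(#indel bases)

with the default weights 2/7/7, a minimum reportable score of 50, a
maximum period of 500 bp and a copy-number floor of 1.8. Only the forward
strand is scanned: a tandem array is its own reverse-complement's mirror.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._align import AlignCosts, WrapAlignment, wraparound_dp
from .seqio import Interval, SeqRecord, n_fraction

MAX_N_FRACTION = 0.10  # candidate windows above this N content are skipped


@dataclass(frozen=True)
class ScoringParams:
    """Alignment weights and reporting thresholds for the repeat finder."""

    match: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_score: int = 50
    max_period: int = 500
    min_copies: float = 1.8
    seed_k: int = 5

    def __post_init__(self) -> None:
        if min(self.match, self.mismatch_penalty, self.indel_penalty, self.min_score, self.max_period) <= 0:
            raise ValueError("all scoring parameters must be positive")
        if not 1 <= self.seed_k <= 12:
            raise ValueError("seed_k must be in 1..12")

    @property
    def costs(self) -> AlignCosts:
        return AlignCosts(self.match, self.mismatch_penalty, self.indel_penalty, self.indel_penalty)


@dataclass
class TandemRepeat:
    """One detected tandem repeat array."""

    interval: Interval
    period_size: int
    copy_number: float
    consensus: str
    percent_match: float
    percent_indels: float
    score: int
    entropy: float

    @property
    def span(self) -> int:
        return len(self.interval)


@dataclass
class RepeatSummary:
    """Genome-level tandem repeat summary (one row of the summary table)."""

    genome_id: str
    genome_size: int
    n_repeats: int
    total_repeat_bp: int
    pct_genome: float
    mean_period: Optional[float]
    period_range: Optional[tuple[int, int]]
    mean_copies: Optional[float]
    copies_range: Optional[tuple[float, float]]
    mean_internal_match: Optional[float]


def shannon_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the A/C/G/T composition of ``seq``."""
    counts = [seq.count(b) for b in "ACGT"]
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


def find_candidate_periods(seq: str, k: int = 5, max_period: int = 500) -> list[tuple[int, int]]:
    """All (position, period) pairs of exact k-mer matches at distance <= max_period.

    ``position`` is the left (earlier) k-mer start; ``period`` the distance
    between the two occurrences. Pairs are emitted once each.
    """
    seq = seq.upper()
    n = len(seq)
    if k > n:
        return []
    occ: dict[str, deque[int]] = {}
    out: list[tuple[int, int]] = []
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        positions = occ.setdefault(kmer, deque())
        while positions and i - positions[0] > max_period:
            positions.popleft()
        for j in positions:
            out.append((j, i - j))
        positions.append(i)
    return out


def wraparound_align(
    seq_window: str,
    consensus: str,
    params: ScoringParams = ScoringParams(),
) -> tuple[int, WrapAlignment, float, float]:
    """Global wraparound alignment of a window against tandem consensus copies.

    Returns (score, alignment, percent_match, percent_indels). The pattern
    phase is free at both ends, so terminal fractional copies are allowed.
    """
    if len(consensus) > params.max_period:
        raise ValueError(f"consensus longer than max_period ({params.max_period})")
    aln = wraparound_dp(seq_window, consensus, params.costs, local=False)
    return aln.score, aln, aln.percent_match, aln.percent_indels


def _phase_consensus(seq: str, start: int, period: int, limit: int) -> str:
    """Majority-vote consensus over period-phased chunks of seq[start:limit]."""
    chunks = []
    pos = start
    while pos + period <= min(limit, len(seq)):
        chunks.append(seq[pos : pos + period])
        pos += period
    if not chunks:
        return seq[start : start + period]
    cols = []
    for j in range(period):
        counts: dict[str, int] = {}
        for ch in chunks:
            counts[ch[j]] = counts.get(ch[j], 0) + 1
        # majority; ties resolved in favour of the earliest chunk's base
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0] == chunks[0][j]))
        cols.append(best[0])
    return "".join(cols)


def _column_consensus(window: str, aln: WrapAlignment, cons: str) -> str:
    """Refine the consensus by majority vote over period-aligned window bases."""
    counts: list[dict[str, int]] = [defaultdict(int) for _ in cons]
    for op, ti, pj in aln.ops:
        if op in "MX":
            counts[pj][window[ti]] += 1
    out = []
    for j, cnt in enumerate(counts):
        if not cnt:
            out.append(cons[j])
            continue
        best = max(cnt.items(), key=lambda kv: (kv[1], kv[0] == cons[j]))
        out.append(best[0])
    return "".join(out)


def _seed_runs(seeds: Iterable[tuple[int, int]], k: int) -> list[tuple[int, int, int, int]]:
    """Group seeds by period into runs: (period, first, last, n_seeds).

    A run breaks when consecutive seed positions at the same period are
    more than max(30, 2k) apart. Runs need enough seeds and coverage to be
    worth verifying; the alignment score is the real filter.
    """
    by_period: dict[int, list[int]] = defaultdict(list)
    for pos, d in seeds:
        by_period[d].append(pos)
    max_gap = max(30, 2 * k)
    runs: list[tuple[int, int, int, int]] = []
    for d, positions in by_period.items():
        positions.sort()
        first = prev = positions[0]
        count = 1
        for pos in positions[1:]:
            if pos - prev > max_gap:
                runs.append((d, first, prev, count))
                first, count = pos, 0
            prev = pos
            count += 1
        runs.append((d, first, prev, count))
    good = []
    for d, first, last, count in runs:
        if count < max(2, math.ceil(0.12 * d)):
            continue
        if last - first + k < 0.5 * d:
            continue
        good.append((d, first, last, count))
    return good


def _verify_run(
    seq: str, seq_id: str, d: int, first: int, last: int, params: ScoringParams
) -> Optional[TandemRepeat]:
    k = params.seed_k
    wstart = max(0, first - d // 2 - 8)
    wend = min(len(seq), last + k + d + d // 2 + 8)
    window = seq[wstart:wend]
    if n_fraction(window) > MAX_N_FRACTION:
        return None
    cons = _phase_consensus(seq, first, d, last + k + d)
    aln = wraparound_dp(window, cons, params.costs, local=True)
    if aln.score < params.min_score or not aln.ops:
        return None
    refined = _column_consensus(window, aln, cons)
    if refined != cons:
        aln2 = wraparound_dp(window, refined, params.costs, local=True)
        if aln2.score >= aln.score:
            aln, cons = aln2, refined
    copies = round(aln.pattern_consumed / d, 1)
    if aln.score < params.min_score or copies < params.min_copies:
        return None
    start, end = wstart + aln.text_start, wstart + aln.text_end
    span = seq[start:end]
    return TandemRepeat(
        interval=Interval(seq_id, start, end),
        period_size=d,
        copy_number=copies,
        consensus=cons,
        percent_match=aln.percent_match,
        percent_indels=aln.percent_indels,
        score=aln.score,
        entropy=shannon_entropy(span),
    )


def _harmonic(p1: int, p2: int, slack: int = 2) -> bool:
    small, large = sorted((p1, p2))
    if small == 0:
        return False
    rem = large % small
    return rem <= slack or small - rem <= slack


def _jaccard(a: Interval, b: Interval) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union


def reduce_harmonics(
    candidates: Sequence[TandemRepeat], near_tie: float = 0.9
) -> list[TandemRepeat]:
    """Collapse redundant reports of the same array at harmonic periods.

    Candidates sharing >=50% of their span whose periods are equal or
    near multiples are treated as one array; the representative is the
    highest-scoring report, except that a smaller-period report scoring
    within ``near_tie`` of the best wins (the minimal period explaining
    an array is preferred — between-copy noise makes p and 2p scores of
    the same array differ by a few points either way). Reports with
    distinct spans survive as separate arrays.
    """
    cands = list(candidates)
    n = len(cands)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = cands[i], cands[j]
            if _jaccard(a.interval, b.interval) >= 0.5 and (
                a.period_size == b.period_size or _harmonic(a.period_size, b.period_size)
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[TandemRepeat]] = {}
    for i, cand in enumerate(cands):
        groups.setdefault(find(i), []).append(cand)
    accepted = []
    for group in groups.values():
        best = max(c.score for c in group)
        eligible = [c for c in group if c.score >= near_tie * best]
        accepted.append(min(eligible, key=lambda c: (c.period_size, -c.score, c.interval.start)))
    return sorted(accepted, key=lambda r: (r.interval.start, r.period_size))


def find_tandem_repeats(
    record: SeqRecord | str,
    params: ScoringParams = ScoringParams(),
) -> list[TandemRepeat]:
    """Detect all maximal tandem repeat arrays in a DNA sequence."""
    if isinstance(record, str):
        record = SeqRecord(id="seq", residues=record)
    seq = record.residues
    seeds = find_candidate_periods(seq, params.seed_k, params.max_period)
    candidates = []
    for d, first, last, _count in _seed_runs(seeds, params.seed_k):
        rep = _verify_run(seq, record.id, d, first, last, params)
        if rep is not None:
            candidates.append(rep)
    return reduce_harmonics(candidates)


def _union_bp(intervals: Iterable[Interval]) -> int:
    spans = sorted((iv.start, iv.end) for iv in intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in spans:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def summarize_repeats(repeats: Sequence[TandemRepeat], genome: SeqRecord) -> RepeatSummary:
    """Genome-level summary; overlapping arrays are counted once in the total."""
    n = len(repeats)
    if n == 0:
        return RepeatSummary(genome.id, len(genome), 0, 0, 0.0, None, None, None, None, None)
    total = _union_bp(r.interval for r in repeats)
    periods = [r.period_size for r in repeats]
    copies = [r.copy_number for r in repeats]
    matches = [r.percent_match for r in repeats]
    return RepeatSummary(
        genome_id=genome.id,
        genome_size=len(genome),
        n_repeats=n,
        total_repeat_bp=total,
        pct_genome=100.0 * total / len(genome),
        mean_period=float(np.mean(periods)),
        period_range=(min(periods), max(periods)),
        mean_copies=float(np.mean(copies)),
        copies_range=(min(copies), max(copies)),
        mean_internal_match=float(np.mean(matches)),
    )
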
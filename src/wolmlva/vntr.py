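"""VNTR locus characterization.

Decomposes a locus into period instances against a consensus period
(classifying full / internally-deleted "half" / terminal partial copies),
and annotates the internal structure of a period: direct repeats,
inverted repeats and palindromic hairpins (dyads).

Copy-number bookkeeping follows the field's printed conventions: full
copies count 1.0, copies carrying a large internal deletion count 0.5,
terminal partial copies count their aligned fraction rounded to one
decimal, e.g. a 7-copy array with a trailing 42 bp of a 141 bp period is
"7.3", and four full plus two deleted copies is "4+2x0.5".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from ._align import AlignCosts, wraparound_dp
from .seqio import revcomp
from .trfind import shannon_entropy

#: An internal deletion at least this long (bp) classifies a period
#: instance as a half copy (0.5); smaller indels are tolerated by full
#: copies. Sits between observed tolerated small indels (<=18 bp) and
#: observed half-copy deletions (>=25 bp).
HALF_DELETION_THRESHOLD = 20

#: Decomposition alignment weights. Deliberately gentler on gaps than the
#: repeat finder's reporting weights so that deleted half copies at array
#: ends are bridged rather than trimmed by the local alignment.
DECOMPOSE_COSTS = AlignCosts(match=2, mismatch=3, gap_open=5, gap_extend=1)

#: Minimum local alignment score for a locus to count as having repeat
#: structure at all.
MIN_DECOMPOSE_SCORE = 40

#: Quality gates for terminal partial copies. Local alignment will happily
#: extend a few lucky bases into non-repeat flank; a terminal partial is
#: only believed when it is a substantial, clean prefix/suffix of the
#: consensus. (The smallest genuine partials seen at real loci are ~0.3.)
MIN_PARTIAL_FRACTION = 0.15
MIN_PARTIAL_IDENTITY = 85.0
#: Gate on inserted (unaligned locus) bases only: junk extension chains
#: lucky matches through cheap insertions, whereas genuine partials with
#: internal deletions (which are real locus features) stay insertion-poor.
MAX_PARTIAL_INSERT_FRACTION = 0.10

#: Unit Shannon entropy (bits) below which candidate motifs are discarded
#: as homopolymer/low-complexity.
MIN_MOTIF_ENTROPY = 1.0


@dataclass
class PeriodInstance:
    """One period copy within a locus."""

    start: int  # within-locus, 0-based half-open
    end: int
    klass: str  # {"full", "half", "partial"}
    aligned_fraction: float
    deletions: list[tuple[int, int]]  # (consensus offset, length)
    identity_to_consensus: float

    @property
    def copies(self) -> float:
        if self.klass == "full":
            return 1.0
        if self.klass == "half":
            return 0.5
        return round(self.aligned_fraction, 1)


@dataclass
class PeriodDecomposition:
    """A VNTR locus cut into period instances against a consensus."""

    locus_id: str
    consensus: str
    instances: list[PeriodInstance]
    copy_number: float
    copy_string: str
    region_start: int = 0  # repeat region within the input sequence
    region_end: int = 0
    score: int = 0

    @property
    def has_repeat(self) -> bool:
        return bool(self.instances)


@dataclass
class StructuralMotif:
    """Internal structural feature of a period: repeat unit or hairpin."""

    kind: str  # {"direct_repeat", "inverted_repeat", "dyad"}
    positions: list[int]
    unit_length: int
    unit_seq: str = ""
    stem_len: int = 0
    loop_len: int = 0
    mismatches: int = 0

    @property
    def span(self) -> int:
        """For dyads: total hairpin span = 2*stem + loop."""
        return 2 * self.stem_len + self.loop_len if self.kind == "dyad" else self.unit_length


def fractional_copy(aligned_len: int, period_len: int) -> float:
    """Fractional copy number of a partial period, one decimal (half-even)."""
    if period_len <= 0:
        raise ValueError("period length must be positive")
    if not 0 < aligned_len <= period_len:
        raise ValueError("aligned length must be in (0, period_len]")
    return round(aligned_len / period_len, 1)


def _copy_string(n_full: int, n_half: int, partials: Sequence[float]) -> str:
    parts = []
    if n_full:
        parts.append(str(n_full))
    if n_half:
        parts.append(f"{n_half}x0.5")
    parts.extend(f"{p:g}" for p in partials if p > 0)
    return "+".join(parts) if parts else "0"


def decompose_periods(
    locus_seq: str,
    consensus: str,
    locus_id: str = "locus",
    min_score: int = MIN_DECOMPOSE_SCORE,
) -> PeriodDecomposition:
    """Cut a locus into period instances by wraparound alignment.

    The locus is locally aligned against unbounded tandem copies of the
    consensus; instance boundaries are cut wherever consensus coordinate 0
    is consumed. Flanking non-repeat sequence (e.g. in an amplicon) is
    left out of the repeat region. A locus with no alignment scoring above
    ``min_score`` yields an empty decomposition, not an exception.
    """
    if len(consensus) < 10:
        raise ValueError("consensus must be at least 10 bp")
    locus_seq = locus_seq.upper()
    p = len(consensus)
    aln = wraparound_dp(locus_seq, consensus, DECOMPOSE_COSTS, local=True)
    if aln.score < min_score or not aln.ops:
        return PeriodDecomposition(locus_id, consensus.upper(), [], 0.0, "0")

    # split ops into instances at consumption of consensus position 0
    groups: list[list[tuple[str, int, int]]] = []
    current: list[tuple[str, int, int]] = []
    for op in aln.ops:
        kind, _ti, pj = op
        if kind in "MXD" and pj == 0 and current:
            groups.append(current)
            current = []
        current.append(op)
    if current:
        groups.append(current)

    # Local alignment happily chains a few lucky matches through cheap
    # gaps into non-repeat flank. Incomplete terminal groups (candidate
    # partial copies) are therefore re-trimmed under a stricter local
    # objective (+1 match, -3 otherwise) that junk cannot sustain.
    def _consumed(group) -> int:
        return sum(1 for kind, _, _ in group if kind in "MXD")

    def _strict_trim(group, from_end: bool):
        # trimming junk off the end keeps the best-scoring prefix, and
        # off the start the best-scoring suffix
        ops = group if from_end else group[::-1]
        best = score = best_k = 0
        for k, (kind, _, _) in enumerate(ops, 1):
            score += 1 if kind == "M" else -3
            if score > best:
                best, best_k = score, k
        ops = ops[:best_k]
        return ops if from_end else ops[::-1]

    if groups and _consumed(groups[-1]) < 0.9 * p:
        groups[-1] = _strict_trim(groups[-1], from_end=True)
        if not groups[-1]:
            groups.pop()
    if groups and _consumed(groups[0]) < 0.9 * p:
        groups[0] = _strict_trim(groups[0], from_end=False)
        if not groups[0]:
            groups.pop(0)
    if not groups:
        return PeriodDecomposition(locus_id, consensus.upper(), [], 0.0, "0")

    instances: list[PeriodInstance] = []
    indel_fractions: list[float] = []
    last_text = aln.text_start
    for gi, group in enumerate(groups):
        text_positions = [ti for kind, ti, _ in group if kind in "MXI"]
        start = text_positions[0] if text_positions else last_text
        end = text_positions[-1] + 1 if text_positions else last_text
        last_text = end
        n_m = sum(1 for kind, _, _ in group if kind == "M")
        n_x = sum(1 for kind, _, _ in group if kind == "X")
        aligned_fraction = (n_m + n_x) / p
        # deletion runs; runs split by <=2 aligned bases (noise placing a
        # chance match inside a deleted block) are merged
        deletions: list[tuple[int, int]] = []
        run_start, n_del, gap = None, 0, 0
        for kind, _, pj in group:
            if kind == "D":
                if run_start is None:
                    run_start, n_del = pj, 0
                n_del += 1  # merged length counts deleted bases only
                gap = 0
            elif run_start is not None:
                gap += 1
                if gap > 2:
                    deletions.append((run_start, n_del))
                    run_start, n_del, gap = None, 0, 0
        if run_start is not None:
            deletions.append((run_start, n_del))
        identity = 100.0 * n_m / (n_m + n_x) if (n_m + n_x) else 0.0
        terminal = gi == 0 or gi == len(groups) - 1
        if any(length >= HALF_DELETION_THRESHOLD for _, length in deletions):
            klass = "half"
        elif aligned_fraction >= 0.9:
            klass = "full"
        elif terminal:
            klass = "partial"
        else:
            klass = "full"  # interior copy degraded by small scattered indels
        instances.append(
            PeriodInstance(start, end, klass, aligned_fraction, deletions, identity)
        )
        n_ins = sum(1 for kind, _, _ in group if kind == "I")
        indel_fractions.append(n_ins / max(1, len(group)))

    # quality gate: a believable terminal partial is a substantial,
    # clean prefix/suffix of the consensus
    def _partial_ok(i: int) -> bool:
        inst = instances[i]
        if inst.klass != "partial":
            return True
        return (
            inst.aligned_fraction >= MIN_PARTIAL_FRACTION
            and inst.identity_to_consensus >= MIN_PARTIAL_IDENTITY
            and indel_fractions[i] <= MAX_PARTIAL_INSERT_FRACTION
        )

    while instances and not _partial_ok(0):
        instances.pop(0)
        indel_fractions.pop(0)
    while instances and not _partial_ok(len(instances) - 1):
        instances.pop()
        indel_fractions.pop()
    if not instances:
        return PeriodDecomposition(locus_id, consensus.upper(), [], 0.0, "0")

    n_full = sum(1 for i in instances if i.klass == "full")
    n_half = sum(1 for i in instances if i.klass == "half")
    partials = [i.copies for i in instances if i.klass == "partial"]
    copy_number = round(n_full + 0.5 * n_half + sum(partials), 1)
    return PeriodDecomposition(
        locus_id=locus_id,
        consensus=consensus.upper(),
        instances=instances,
        copy_number=copy_number,
        copy_string=_copy_string(n_full, n_half, partials),
        region_start=instances[0].start,
        region_end=instances[-1].end,
        score=aln.score,
    )


def _greedy_occurrences(seq: str, unit: str) -> list[int]:
    """Left-to-right non-overlapping occurrence starts of unit in seq."""
    out, i = [], seq.find(unit)
    while i != -1:
        out.append(i)
        i = seq.find(unit, i + len(unit))
    return out


def find_direct_repeats(
    seq: str,
    min_unit: int = 5,
    max_unit: int = 30,
    min_occurrences: int = 2,
    allow_inverted: bool = False,
) -> list[StructuralMotif]:
    """Maximal exact internal repeat units of a period.

    A unit is reported when it occurs at least ``min_occurrences`` times
    (counted greedily, non-overlapping), has Shannon entropy above 1 bit,
    and cannot be extended by one base at either end without losing
    occurrences. With ``allow_inverted`` unit/reverse-complement pairs are
    additionally reported as ``inverted_repeat`` motifs.
    """
    if min_unit < 5:
        raise ValueError("min_unit must be >= 5")
    seq = seq.upper()
    n = len(seq)
    motifs: list[StructuralMotif] = []
    for L in range(min_unit, min(max_unit, n // 2) + 1):
        units = {seq[i : i + L] for i in range(n - L + 1)}
        for unit in units:
            if shannon_entropy(unit) <= MIN_MOTIF_ENTROPY:
                continue
            occ = _greedy_occurrences(seq, unit)
            if len(occ) < min_occurrences:
                continue
            if _extendable(seq, unit, len(occ), max_unit):
                continue
            motifs.append(StructuralMotif("direct_repeat", occ, L, unit_seq=unit))
    if allow_inverted:
        motifs.extend(_inverted_pairs(seq, min_unit, max_unit))
    motifs.sort(key=lambda m: (m.positions[0], m.unit_length))
    return motifs


def _extendable(seq: str, unit: str, count: int, max_unit: int) -> bool:
    if len(unit) >= max_unit:
        return False
    n, L = len(seq), len(unit)
    for i in range(n - L):  # right extensions
        if seq[i : i + L] == unit:
            ext = seq[i : i + L + 1]
            if len(_greedy_occurrences(seq, ext)) >= count:
                return True
    for i in range(1, n - L + 1):  # left extensions
        if seq[i : i + L] == unit:
            ext = seq[i - 1 : i + L]
            if len(_greedy_occurrences(seq, ext)) >= count:
                return True
    return False


def _inverted_pairs(seq: str, min_unit: int, max_unit: int) -> list[StructuralMotif]:
    """Maximal unit / reverse-complement-unit pairs (any separation)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(seq)
    found: list[StructuralMotif] = []
    seen: set[tuple[int, int, int]] = set()
    for i in range(n):
        for j2 in range(i + min_unit, n + 1):  # arm2 exclusive end
            # grow matched stem inward from the outer ends i and j2-1
            L = 0
            while (
                i + L < j2 - 1 - L
                and seq[i + L] in comp
                and seq[j2 - 1 - L] == comp[seq[i + L]]
            ):
                L += 1
            if L < min_unit:
                continue
            L = min(L, max_unit)
            arm2_start = j2 - L
            if arm2_start < i + L:  # overlapping arms
                continue
            # maximal outward?
            if i > 0 and j2 < n and seq[j2] == comp.get(seq[i - 1], "?"):
                continue
            unit = seq[i : i + L]
            if shannon_entropy(unit) <= MIN_MOTIF_ENTROPY:
                continue
            key = (i, arm2_start, L)
            if key in seen:
                continue
            seen.add(key)
            found.append(
                StructuralMotif(
                    "inverted_repeat", [i, arm2_start], L, unit_seq=unit, stem_len=L,
                    loop_len=arm2_start - (i + L),
                )
            )
    return found


def find_dyads(
    seq: str,
    min_stem: int = 4,
    max_loop: int = 10,
    max_mismatch: int = 0,
) -> list[StructuralMotif]:
    """Palindromic (dyad) repeats able to form a hairpin.

    Reports positions where ``seq[i:i+stem]`` equals the reverse
    complement of ``seq[j:j+stem]`` with a loop of ``j-(i+stem)`` in
    ``[0, max_loop]``, maximal under stem extension (both outward and
    inward), tolerating up to ``max_mismatch`` non-complementary pairs.
    Low-complexity stems (entropy <= 1 bit) are suppressed.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    seq = seq.upper()
    n = len(seq)

    def pair_ok(a: int, b: int) -> bool:
        return seq[a] in comp and seq[b] == comp[seq[a]]

    out: list[StructuralMotif] = []
    for i in range(n):
        for loop in range(0, max_loop + 1):
            for stem in range(min_stem, (n - i - loop) // 2 + 1):
                a2 = i + stem + loop
                end = a2 + stem
                if end > n:
                    break
                mism = sum(0 if pair_ok(i + t, end - 1 - t) else 1 for t in range(stem))
                if mism > max_mismatch:
                    continue
                # maximality: no outward extension ...
                if i > 0 and end < n and pair_ok(i - 1, end):
                    continue
                # ... and no inward extension (shrinking the loop by 2)
                if loop >= 2 and pair_ok(i + stem, a2 - 1):
                    continue
                if shannon_entropy(seq[i : i + stem]) <= MIN_MOTIF_ENTROPY:
                    continue
                out.append(
                    StructuralMotif(
                        "dyad", [i, a2], stem, unit_seq=seq[i : i + stem],
                        stem_len=stem, loop_len=loop, mismatches=mism,
                    )
                )
    out.sort(key=lambda m: (m.positions[0], m.stem_len))
    return out


def copy_number_characters(
    decompositions_by_strain: dict[str, dict[str, "PeriodDecomposition | float"]],
) -> pd.DataFrame:
    """Strains x loci matrix of copy numbers for cladistic comparison.

    Values may be PeriodDecomposition objects or bare copy numbers.
    Missing loci become NaN (explicit NA, never a silent zero).
    """
    if len(decompositions_by_strain) < 2:
        raise ValueError("need at least two strains")
    loci = sorted({l for d in decompositions_by_strain.values() for l in d})
    rows = {}
    for strain, by_locus in decompositions_by_strain.items():
        row = {}
        for locus in loci:
            val = by_locus.get(locus)
            if val is None:
                row[locus] = math.nan
            elif isinstance(val, PeriodDecomposition):
                row[locus] = val.copy_number
            else:
                row[locus] = float(val)
        rows[strain] = row
    return pd.DataFrame.from_dict(rows, orient="index")[loci]


def manhattan_distance(matrix: pd.DataFrame, s1: str, s2: str) -> tuple[float, int]:
    """Manhattan distance between two strains' copy-number profiles.

    Returns (distance, n_loci_excluded_as_NA).
    """
    a, b = matrix.loc[s1], matrix.loc[s2]
    both = a.notna() & b.notna()
    if not both.any():
        raise ValueError(f"no shared loci between {s1} and {s2}")
    return float((a[both] - b[both]).abs().sum()), int((~both).sum())
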
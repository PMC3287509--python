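"""Wraparound dynamic programming (WDP) alignment engine.

Aligns a sequence window against an unbounded tandem concatenation of a
single period (the consensus): the alignment path may wrap from the last
period position back to the first. This is the classic mechanism behind
tandem-repeat refinement and period decomposition.

Two modes:

* ``global`` - every window base is consumed; the pattern phase is free at
  both ends (fractional first/last copies cost nothing beyond their own
  mismatches/indels).
* ``local``  - the maximum-scoring sub-segment of the window is aligned
  (Smith-Waterman-style floor at zero); used to locate a repeat array
  inside a larger context such as an amplicon.

Scoring is affine-gap: ``match`` is added per identity, ``mismatch``
subtracted per substitution, a gap run of length L costs
``gap_open + gap_extend*(L-1)``. With ``gap_open == gap_extend`` this
degenerates to the per-base linear indel cost used by the repeat finder.

All scores are integers, so DP-cell equality in the traceback is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG = np.int64(-(10**12))


@dataclass(frozen=True)
class AlignCosts:
    match: int = 2
    mismatch: int = 7
    gap_open: int = 7
    gap_extend: int = 7

    def __post_init__(self) -> None:
        if min(self.match, self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("all alignment weights must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass
class WrapAlignment:
    """Traceback of a wraparound alignment.

    ``ops`` is a forward-ordered list of ``(op, text_idx, pattern_idx)``:
    ``M``/``X`` consume one window and one pattern base, ``I`` consumes a
    window base opposite a gap (insertion), ``D`` consumes a pattern base
    opposite a gap (deletion). ``text_start``/``text_end`` delimit the
    aligned window segment (equal to the full window in global mode).
    """

    score: int
    ops: list[tuple[str, int, int]]
    text_start: int
    text_end: int
    period: int
    n_match: int = 0
    n_mismatch: int = 0
    n_insert: int = 0
    n_delete: int = 0

    def __post_init__(self) -> None:
        for op, _, _ in self.ops:
            if op == "M":
                self.n_match += 1
            elif op == "X":
                self.n_mismatch += 1
            elif op == "I":
                self.n_insert += 1
            else:
                self.n_delete += 1

    @property
    def n_indels(self) -> int:
        return self.n_insert + self.n_delete

    @property
    def n_columns(self) -> int:
        return len(self.ops)

    @property
    def percent_match(self) -> float:
        return 100.0 * self.n_match / self.n_columns if self.ops else 0.0

    @property
    def percent_indels(self) -> float:
        return 100.0 * self.n_indels / self.n_columns if self.ops else 0.0

    @property
    def pattern_consumed(self) -> int:
        """Total pattern bases consumed (aligned or deleted) across copies."""
        return self.n_match + self.n_mismatch + self.n_delete

    def copy_starts(self) -> list[int]:
        """Indices into ``ops`` where pattern position 0 is consumed."""
        return [k for k, (op, _, j) in enumerate(self.ops) if op in "MXD" and j == 0]


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def wraparound_dp(
    window: str,
    consensus: str,
    costs: AlignCosts = AlignCosts(),
    local: bool = False,
) -> WrapAlignment:
    """Align ``window`` against unbounded tandem copies of ``consensus``."""
    if not consensus:
        raise ValueError("empty consensus")
    if not window:
        raise ValueError("empty window")
    n, p = len(window), len(consensus)
    w = _encode(window.upper())
    c = _encode(consensus.upper())
    is_n = (w[:, None] == ord("N")) | (c[None, :] == ord("N"))
    sub = np.where((w[:, None] == c[None, :]) & ~is_n, costs.match, -costs.mismatch).astype(np.int64)

    go, ge = costs.gap_open, costs.gap_extend
    best = np.empty((n + 1, p), dtype=np.int64)
    vert = np.empty((n + 1, p), dtype=np.int64)
    best[0] = 0
    vert[0] = NEG
    idx2p = ge * np.arange(2 * p, dtype=np.int64)
    for i in range(1, n + 1):
        prev = best[i - 1]
        v = np.maximum(prev - go, vert[i - 1] - ge)
        base = np.maximum(np.roll(prev, 1) + sub[i - 1], v)
        if local:
            np.maximum(base, 0, out=base)
        if p > 1:
            dbl = np.concatenate([base, base])
            run = np.maximum.accumulate(dbl + idx2p)
            # H[j] = max_{t>=1} base[(j-t)%p] - go - ge*(t-1), via doubled prefix max
            h = run[p - 1 : 2 * p - 1] - idx2p[p : 2 * p] - (go - ge)
            row = np.maximum(base, h)
        else:
            row = base  # deleting the whole 1-bp period is never optimal
        if local:
            np.maximum(row, 0, out=row)
        best[i] = row
        vert[i] = v

    if local:
        flat = int(np.argmax(best))
        i_end, j_end = divmod(flat, p)
        score = int(best[i_end, j_end])
        if score <= 0:
            return WrapAlignment(0, [], 0, 0, p)
    else:
        j_end = int(np.argmax(best[n]))
        i_end = n
        score = int(best[n, j_end])

    ops = _traceback(w, c, sub, best, vert, costs, i_end, j_end, local)
    text_start = ops[0][1] if ops else i_end
    for op, ti, _ in ops:
        if op in "MXI":
            text_start = ti
            break
    return WrapAlignment(score, ops, text_start, i_end, p)


def _base_val(best, vert, sub, i, j, p, local) -> int:
    diag = best[i - 1][(j - 1) % p] + sub[i - 1][j]
    val = max(diag, vert[i][j])
    if local:
        val = max(val, 0)
    return val


def _traceback(w, c, sub, best, vert, costs, i, j, local) -> list[tuple[str, int, int]]:
    p = best.shape[1]
    go, ge = costs.gap_open, costs.gap_extend
    ops: list[tuple[str, int, int]] = []
    v = int(best[i][j])
    in_vert = False  # the loop resolves diag before vert, so start unresolved
    while i > 0:
        if local and v == 0 and not in_vert:
            break
        if not in_vert:
            diag = _diag(best, sub, i, j, p)
            if v == diag:
                op = "M" if sub[i - 1][j] > 0 else "X"
                ops.append((op, i - 1, j))
                i, j = i - 1, (j - 1) % p
                v = int(best[i][j])
                in_vert = False
                continue
            if v == int(vert[i][j]):
                in_vert = True
                continue
            # horizontal run: walk left circularly until a base cell explains v
            t = 0
            jj = j
            while True:
                t += 1
                jj = (jj - 1) % p
                cand = _base_val(best, vert, sub, i, jj, p, local) - go - ge * (t - 1)
                if cand == v:
                    for s in range(t):
                        ops.append(("D", i, (j - s) % p))
                    j = jj
                    v = _base_val(best, vert, sub, i, j, p, local)
                    bdiag = _diag(best, sub, i, j, p)
                    in_vert = v != bdiag and v == int(vert[i][j]) and not (local and v == 0)
                    break
                if t > p:
                    raise AssertionError("traceback failed in horizontal run")
        else:
            # vertical (insertion) run
            ops.append(("I", i - 1, -1))
            vv = int(vert[i][j])
            if vv == int(best[i - 1][j]) - go:
                i -= 1
                v = int(best[i][j])
                in_vert = False
            elif vv == int(vert[i - 1][j]) - ge:
                i -= 1
                in_vert = True
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in vertical run")
    ops.reverse()
    return ops


def _diag(best, sub, i, j, p) -> int:
    return int(best[i - 1][(j - 1) % p]) + int(sub[i - 1][j])
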
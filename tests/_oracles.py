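"""Independent brute-force oracles used to validate the fast implementations.

Everything here favours obviousness over speed: exhaustive enumeration,
naive scanning, explicit concatenation. Oracles share only *definitions*
with the package (scoring weights, maximality rules), never code paths,
except where a shared post-processing step (harmonic reduction) is the
very contract under test.
"""

from __future__ import annotations

import math

import numpy as np

from wolmlva._align import AlignCosts, wraparound_dp
from wolmlva.seqio import Interval, revcomp
from wolmlva.trfind import ScoringParams, TandemRepeat, reduce_harmonics, shannon_entropy

# ---------------------------------------------------------------- alignment


def linear_tandem_score(window: str, cons: str, match=2, mismatch=7, indel=7, max_copies=None) -> int:
    """Best score aligning window against an explicit tandem concatenation.

    Classic Needleman-Wunsch against cons*K with free pattern prefix and
    suffix; equivalent to wraparound DP with linear gap costs, without
    any wraparound cleverness.
    """
    n = len(window)
    if max_copies is None:
        max_copies = n // len(cons) + 2
    pat = cons * max_copies
    m = len(pat)
    NEG = -(10**9)
    prev = [0] * (m + 1)  # free pattern prefix
    for i in range(1, n + 1):
        cur = [prev[0] - indel]
        wi = window[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if wi == pat[j - 1] else -mismatch)
            cur.append(max(diag, prev[j] - indel, cur[j - 1] - indel))
        prev = cur
    return max(prev)  # free pattern suffix


# ---------------------------------------------------------------- trfind


def _phase_consensus(window: str, p: int) -> str:
    chunks = [window[k : k + p] for k in range(0, len(window) - p + 1, p)]
    if not chunks:
        return window[:p]
    out = []
    for j in range(p):
        counts: dict[str, int] = {}
        for ch in chunks:
            counts[ch[j]] = counts.get(ch[j], 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0] == chunks[0][j]))
        out.append(best[0])
    return "".join(out)


def brute_force_repeats(
    seq: str, params: ScoringParams = ScoringParams(), max_p: int = 10
) -> list[TandemRepeat]:
    """Exhaustive repeat search: every window x every period <= max_p.

    Each window is scored by wraparound alignment against the
    majority-vote consensus of its period-phased chunks; reportable
    candidates pass the same score/copy thresholds and the same harmonic
    reduction as the production finder.
    """
    n = len(seq)
    candidates: list[TandemRepeat] = []
    for p in range(1, min(max_p, n // 2) + 1):
        min_len = max(int(math.ceil(1.75 * p)), (params.min_score + 1) // params.match)
        for i in range(n):
            for j in range(i + min_len, n + 1):
                window = seq[i:j]
                cons = _phase_consensus(window, p)
                aln = wraparound_dp(window, cons, params.costs, local=False)
                copies = round(aln.pattern_consumed / p, 1)
                if aln.score < params.min_score or copies < params.min_copies:
                    continue
                candidates.append(
                    TandemRepeat(
                        interval=Interval("seq", i, j),
                        period_size=p,
                        copy_number=copies,
                        consensus=cons,
                        percent_match=aln.percent_match,
                        percent_indels=aln.percent_indels,
                        score=aln.score,
                        entropy=shannon_entropy(window),
                    )
                )
    return reduce_harmonics(candidates)


# ---------------------------------------------------------------- motifs


def brute_force_direct_repeats(seq, min_unit, max_unit, min_occurrences=2, min_entropy=1.0):
    """Naive enumeration of maximal exact repeat units (definition copy)."""

    def greedy_count(unit):
        count, i = 0, seq.find(unit)
        while i != -1:
            count += 1
            i = seq.find(unit, i + len(unit))
        return count

    found = []
    n = len(seq)
    for L in range(min_unit, min(max_unit, n // 2) + 1):
        for unit in {seq[i : i + L] for i in range(n - L + 1)}:
            if shannon_entropy(unit) <= min_entropy:
                continue
            cnt = greedy_count(unit)
            if cnt < min_occurrences:
                continue
            extendable = False
            if L < max_unit:
                for i in range(n - L + 1):
                    if seq[i : i + L] != unit:
                        continue
                    if i + L < n and greedy_count(seq[i : i + L + 1]) >= cnt:
                        extendable = True
                    if i > 0 and greedy_count(seq[i - 1 : i + L]) >= cnt:
                        extendable = True
            if not extendable:
                occ, i = [], seq.find(unit)
                while i != -1:
                    occ.append(i)
                    i = seq.find(unit, i + L)
                found.append((unit, L, tuple(occ)))
    return sorted(set(found), key=lambda t: (t[2][0], t[1]))


def brute_force_dyads(seq, min_stem, max_loop, max_mismatch=0, min_entropy=1.0):
    """Naive enumeration of maximal dyads (hairpin arms)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(seq)

    def ok(a, b):
        return seq[a] in comp and seq[b] == comp[seq[a]]

    out = []
    for i in range(n):
        for loop in range(max_loop + 1):
            stem = min_stem
            while True:
                end = i + 2 * stem + loop
                if end > n:
                    break
                arm1 = seq[i : i + stem]
                arm2 = seq[i + stem + loop : end]
                mism = sum(1 for a, b in zip(arm1, revcomp(arm2)) if a != b)
                if mism <= max_mismatch:
                    outward = i > 0 and end < n and ok(i - 1, end)
                    inward = loop >= 2 and ok(i + stem, i + stem + loop - 1)
                    if not outward and not inward and shannon_entropy(arm1) > min_entropy:
                        out.append((i, stem, loop, mism))
                stem += 1
    return sorted(out)


# ---------------------------------------------------------------- primers


def brute_force_primer_sites(template, primer, max_mismatch, iupac):
    """Naive sliding-window primer matcher (both strands)."""
    sites = []
    for probe, strand in ((primer, "+"), (revcomp_iupac(primer, iupac), "-")):
        m = len(probe)
        for i in range(len(template) - m + 1):
            mism = sum(
                1
                for k in range(m)
                if template[i + k] not in iupac.get(probe[k], probe[k])
            )
            if mism <= max_mismatch:
                sites.append((i, strand))
    return sorted(sites)


def revcomp_iupac(primer, iupac):
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return primer.translate(comp)[::-1]


# ---------------------------------------------------------------- trees


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary topology + positive branch lengths; returns
    (newick, leaf labels, additive distance matrix)."""
    import itertools

    labels = [f"L{i}" for i in range(n_leaves)]
    # graph as adjacency with branch lengths; start from 2-leaf tree
    next_internal = [n_leaves]
    edges: dict[tuple[int, int], float] = {}

    def add_edge(a, b, w):
        edges[(a, b)] = w
        edges[(b, a)] = w

    add_edge(0, 1, float(rng.uniform(0.1, 1.0)))
    for leaf in range(2, n_leaves):
        # attach to a random existing edge via a new internal node
        (a, b), w = list(edges.items())[rng.integers(len(edges)) // 2 * 2]
        node = next_internal[0]
        next_internal[0] += 1
        del edges[(a, b)], edges[(b, a)]
        split = float(rng.uniform(0.2, 0.8)) * w
        add_edge(a, node, split)
        add_edge(node, b, w - split)
        add_edge(node, leaf, float(rng.uniform(0.1, 1.0)))

    # all-pairs path lengths by BFS
    nodes = {x for x, _ in edges}
    adj: dict[int, list[tuple[int, float]]] = {x: [] for x in nodes}
    for (a, b), w in edges.items():
        adj[a].append((b, w))
    dm = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    stack.append(nxt)
        for dst in range(n_leaves):
            dm[src, dst] = dist[dst]
    dm = (dm + dm.T) / 2  # float summation order differs per direction
    return labels, dm
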
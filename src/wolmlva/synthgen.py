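"""Deterministic synthetic data generator with ground-truth annotations.

Emulates every structure the analyses assume: tandem arrays of a given
period and copy number (terminal partial and internally deleted "half"
periods included), planted direct repeats and palindromic hairpins
inside periods, SNP noise between period copies, conserved single-copy
flanks carrying primer sites, and ANK genes built from repeated 33-aa
units with optional duplications, swaps, premature stops, mobile-element
insertions and transmembrane tails.

Backgrounds default to 35% GC (AT-rich, endosymbiont-like). All
randomness flows through one seeded generator recorded in the Truth, so
regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ank import ANK_UNIT_LEN, default_profile
from .seqio import Interval, SeqRecord, revcomp
from .vntr import _copy_string

_BASES = np.array(list("ACGT"))

#: Most-frequent-codon back-translation table (E. coli style); codon
#: choice is irrelevant downstream and fixed for reproducibility.
CODON = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC", "Q": "CAG",
    "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCG", "S": "AGC", "T": "ACC", "W": "TGG",
    "Y": "TAT", "V": "GTG",
}

DEFAULT_GC = 0.35


class SpecError(ValueError):
    """Raised for inconsistent generator specifications."""


def random_dna(rng: np.random.Generator, length: int, gc: float = DEFAULT_GC) -> str:
    at = (1.0 - gc) / 2
    return "".join(rng.choice(_BASES, size=length, p=[at, gc / 2, gc / 2, at]))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            options = [b for b in "ACGT" if b != chars[i]]
            chars[i] = options[rng.integers(3)]
    return "".join(chars)


@dataclass(frozen=True)
class VntrSpec:
    """Parameters of a synthetic VNTR locus.

    Defaults mirror the VNTR-141-like study condition: a 141 bp period
    with a 15 bp internal direct repeat in two copies and a 23 bp hairpin
    (9 bp stem, 5 bp loop), flanked by conserved single-copy sequence
    carrying 19-20 bp primer sites.
    """

    period_len: int = 141
    n_full: int = 4
    n_half: int = 0
    half_deletion_len: int = 25
    terminal_fraction: float = 0.0
    snp_rate_between_copies: float = 0.0
    flank_len_f: int = 150
    flank_len_r: int = 150
    plant_hairpin: Optional[tuple[int, int]] = (9, 5)  # (stem, loop)
    #: (unit length, start offsets); negative offsets count from the
    #: period end, so the default plants unit A at the start and unit B
    #: ending 6 bp before the period end, whatever the period length.
    plant_direct_repeat: Optional[tuple[int, tuple[int, ...]]] = (15, (0, -21))
    primer_len: int = 19
    gc: float = DEFAULT_GC
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_half > 0 and self.period_len <= self.half_deletion_len:
            problems.append("period_len must exceed half_deletion_len")
        if self.n_full + self.n_half == 0 and self.terminal_fraction <= 0:
            problems.append("locus must contain at least a partial period")
        if not 0 <= self.terminal_fraction < 1:
            problems.append("terminal_fraction must be in [0, 1)")
        if not 0 <= self.snp_rate_between_copies <= 0.1:
            problems.append("snp_rate_between_copies must be in [0, 0.1]")
        if self.plant_hairpin is not None:
            stem, loop = self.plant_hairpin
            if 2 * stem + loop > self.period_len:
                problems.append("hairpin does not fit within the period")
        if self.plant_direct_repeat is not None:
            unit_len, offsets = self.plant_direct_repeat
            resolved = [o if o >= 0 else self.period_len + o for o in offsets]
            if any(o < 0 or o + unit_len > self.period_len for o in resolved):
                problems.append("direct repeat does not fit within the period")
        if min(self.flank_len_f, self.flank_len_r) < self.primer_len:
            problems.append("flanks must be at least primer_len")
        if problems:
            raise SpecError("; ".join(problems))


@dataclass
class Truth:
    """Ground-truth annotation serialized alongside generated sequence."""

    seed: int
    kind: str
    consensus: str = ""
    copy_number: float = 0.0
    copy_string: str = ""
    amplicon_length: int = 0
    array_start: int = 0
    array_end: int = 0
    primer_forward: str = ""
    primer_reverse: str = ""
    instances: list[tuple[int, int, str]] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)
    unit_order: list[int] = field(default_factory=list)
    unit_seqs: list[str] = field(default_factory=list)
    n_units: int = 0
    premature_stop_codon: Optional[int] = None
    insertion: Optional[tuple[int, int]] = None
    tm_tail: bool = False
    protein: str = ""
    loci: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def make_vntr_locus(spec: VntrSpec) -> tuple[SeqRecord, Truth]:
    """Generate flank + tandem array + flank with full ground truth.

    Primer sites are the outermost ``primer_len`` bases of the flanks, so
    the expected amplicon length equals the whole locus length.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    period = list(random_dna(rng, spec.period_len, spec.gc))
    motifs: list[dict] = []
    if spec.plant_direct_repeat is not None:
        unit_len, raw_offsets = spec.plant_direct_repeat
        offsets = [o if o >= 0 else spec.period_len + o for o in raw_offsets]
        unit = random_dna(rng, unit_len, 0.5)  # higher complexity than background
        for k, off in enumerate(offsets):
            period[off : off + unit_len] = unit
            # pin distinct boundary bases so the planted unit is maximal
            # (occurrences cannot all be extended by one base)
            if off > 0:
                period[off - 1] = "ACGT"[k % 4]
            if off + unit_len < spec.period_len:
                period[off + unit_len] = "TGCA"[k % 4]
        motifs.append({"kind": "direct_repeat", "unit_len": unit_len, "offsets": offsets, "unit": unit})
    if spec.plant_hairpin is not None:
        stem, loop = spec.plant_hairpin
        span = 2 * stem + loop
        # place mid-period, clear of the planted direct repeats
        occupied = []
        if spec.plant_direct_repeat is not None:
            ul, offs = spec.plant_direct_repeat
            occupied = [
                (o if o >= 0 else spec.period_len + o, (o if o >= 0 else spec.period_len + o) + ul)
                for o in offs
            ]
        # prefer mid-period, else first free slot clear of planted repeats
        preferred = spec.period_len // 2 - span // 2
        candidates = [preferred] + list(range(0, spec.period_len - span + 1))
        pos = next(
            (
                c
                for c in candidates
                if 0 <= c <= spec.period_len - span
                and all(c >= o_e or o_s >= c + span for o_s, o_e in occupied)
            ),
            None,
        )
        if pos is None:
            raise SpecError("hairpin placement clashes with planted repeats")
        arm = random_dna(rng, stem, 0.5)
        loop_seq = random_dna(rng, loop, 0.5)
        if loop >= 2:
            # pin non-pairing loop edges so the stem cannot extend inward
            loop_seq = "A" + loop_seq[1:-1] + "A"
        period[pos : pos + span] = arm + loop_seq + revcomp(arm)
        # pin non-pairing boundary bases so the stem cannot extend outward
        if pos > 0:
            period[pos - 1] = "A"
        if pos + span < spec.period_len:
            period[pos + span] = "A"
        motifs.append({"kind": "dyad", "stem": stem, "loop": loop, "offset": pos})
    consensus = "".join(period)

    pieces: list[str] = []
    instances: list[tuple[int, int, str]] = []
    cursor = 0
    for _ in range(spec.n_full):
        copy = _mutate(rng, consensus, spec.snp_rate_between_copies)
        pieces.append(copy)
        instances.append((cursor, cursor + len(copy), "full"))
        cursor += len(copy)
    del_start = spec.period_len // 2 - spec.half_deletion_len // 2
    for _ in range(spec.n_half):
        copy = _mutate(rng, consensus, spec.snp_rate_between_copies)
        copy = copy[:del_start] + copy[del_start + spec.half_deletion_len :]
        pieces.append(copy)
        instances.append((cursor, cursor + len(copy), "half"))
        cursor += len(copy)
    partial_len = int(spec.terminal_fraction * spec.period_len)
    partial_copies = 0.0
    if partial_len > 0:
        pieces.append(consensus[:partial_len])
        instances.append((cursor, cursor + partial_len, "partial"))
        cursor += partial_len
        partial_copies = round(partial_len / spec.period_len, 1)

    flank_f = random_dna(rng, spec.flank_len_f, spec.gc)
    flank_r = random_dna(rng, spec.flank_len_r, spec.gc)
    array = "".join(pieces)
    seq = flank_f + array + flank_r
    copy_number = round(spec.n_full + 0.5 * spec.n_half + partial_copies, 1)
    truth = Truth(
        seed=spec.seed,
        kind="vntr",
        consensus=consensus,
        copy_number=copy_number,
        copy_string=_copy_string(spec.n_full, spec.n_half, [partial_copies]),
        amplicon_length=len(seq),
        array_start=spec.flank_len_f,
        array_end=spec.flank_len_f + len(array),
        primer_forward=flank_f[: spec.primer_len],
        primer_reverse=revcomp(flank_r[-spec.primer_len :]),
        instances=[(s + spec.flank_len_f, e + spec.flank_len_f, k) for s, e, k in instances],
        motifs=motifs,
    )
    return SeqRecord(id=f"vntr_locus_seed{spec.seed}", residues=seq), truth


@dataclass(frozen=True)
class AnkGeneSpec:
    """Parameters of a synthetic ANK gene (CDS)."""

    n_units: int = 8
    per_unit_mutation_rate: float = 0.1
    duplicate_indices: tuple[int, ...] = ()
    swap_indices: Optional[tuple[int, int]] = None
    premature_stop_codon: Optional[int] = None
    insertion: Optional[tuple[int, int]] = None  # (nt position, length)
    tm_tail: bool = False
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not 1 <= self.n_units <= 20:
            problems.append("n_units must be in 1..20")
        if any(not 1 <= i <= self.n_units for i in self.duplicate_indices):
            problems.append("duplicate_indices out of range")
        if self.swap_indices is not None and any(
            not 1 <= i <= self.n_units for i in self.swap_indices
        ):
            problems.append("swap_indices out of range")
        if self.insertion is not None and self.insertion[0] < 3:
            problems.append("insertion inside the start codon")
        if problems:
            raise SpecError("; ".join(problems))


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_HYDROPHOBIC = np.array(list("LIVFA"))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice(_AA))
    return "".join(chars)


def back_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein)


def make_ank_gene(spec: AnkGeneSpec) -> tuple[SeqRecord, Truth]:
    """Generate an ANK CDS with planted architecture events and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = default_profile().consensus
    units = [_mutate_protein(rng, base, spec.per_unit_mutation_rate) for _ in range(spec.n_units)]
    order = list(range(1, spec.n_units + 1))
    if spec.swap_indices is not None:
        i, j = (x - 1 for x in spec.swap_indices)
        units[i], units[j] = units[j], units[i]
        order[i], order[j] = order[j], order[i]
    # duplications: identical tandem copy inserted after its template
    for idx in sorted(spec.duplicate_indices, reverse=True):
        pos = order.index(idx)
        units.insert(pos + 1, units[pos])
        order.insert(pos + 1, idx)

    protein = "M" + "".join(units)
    if spec.tm_tail:
        # two 23-aa hydrophobic stretches separated by a hydrophilic loop
        # long enough that hydropathy windows do not bridge them
        tm = lambda: "".join(rng.choice(_HYDROPHOBIC, 23))
        protein += "DNKQTS" + tm() + "KDNERQDSNKQEDNSTKQDE" + tm() + "K"
    cds = back_translate(protein) + "TAA"
    if spec.premature_stop_codon is not None:
        c = spec.premature_stop_codon - 1
        cds = cds[: 3 * c] + "TAA" + cds[3 * c + 3 :]
    if spec.insertion is not None:
        pos, length = spec.insertion
        cds = cds[:pos] + random_dna(rng, length) + cds[pos:]
    truth = Truth(
        seed=spec.seed,
        kind="ank",
        unit_order=order,
        unit_seqs=units,
        n_units=len(units),
        premature_stop_codon=spec.premature_stop_codon,
        insertion=spec.insertion,
        tm_tail=spec.tm_tail,
        protein=protein,
    )
    return SeqRecord(id=f"ank_gene_seed{spec.seed}", residues=cds), truth


def make_genome(
    specs: Sequence[VntrSpec],
    background_len: int,
    seed: int = 0,
    gc: float = DEFAULT_GC,
    genome_id: str = "synthetic_genome",
) -> tuple[SeqRecord, Truth]:
    """Embed VNTR loci at non-overlapping random positions in background.

    The Truth lists each locus with its genome interval and its own truth.
    """
    rng = np.random.default_rng(seed)
    loci = [make_vntr_locus(s) for s in specs]
    total = sum(len(rec) for rec, _ in loci)
    if total > background_len:
        raise SpecError("loci do not fit in the requested background length")
    genome = list(random_dna(rng, background_len, gc))
    placements: list[tuple[int, int]] = []
    truth = Truth(seed=seed, kind="genome")
    for rec, lt in loci:
        for _attempt in range(1000):
            start = int(rng.integers(0, background_len - len(rec) + 1))
            end = start + len(rec)
            if all(end <= s or start >= e for s, e in placements):
                break
        else:  # pragma: no cover - astronomically unlikely at sane densities
            raise SpecError("could not place loci without overlap")
        placements.append((start, end))
        genome[start:end] = rec.residues
        truth.loci.append(
            {
                "locus_start": start,
                "locus_end": end,
                "array_start": start + lt.array_start,
                "array_end": start + lt.array_end,
                "truth": dataclasses.asdict(lt),
            }
        )
    truth.loci.sort(key=lambda d: d["locus_start"])
    return SeqRecord(id=genome_id, residues="".join(genome)), truth


def truth_to_gff3(truth: Truth, genome_id: str, path) -> None:
    """Write planted array intervals of a genome truth as GFF3."""
    from .seqio import write_gff3

    features = []
    for locus in truth.loci:
        iv = Interval(genome_id, locus["array_start"], locus["array_end"])
        t = locus["truth"]
        features.append(
            (iv, {
                "type": "tandem_repeat",
                "period_size": len(t["consensus"]),
                "copy_number": t["copy_number"],
                "copy_string": t["copy_string"],
            })
        )
    write_gff3(features, path)
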
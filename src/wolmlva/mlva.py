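"""In-silico PCR typing (MLVA).

Locates primer binding sites on templates, extracts amplicons, sizes
them, calls per-locus copy-number alleles via period decomposition of
the amplicon, assembles multi-locus profiles and flags multiple
infections (more than one distinct amplicon length at a locus).

Amplicon length follows the standard PCR product convention: measured
from the 5' end of the forward primer footprint to the 5' end of the
reverse primer footprint, i.e. including both primer sequences.

The packaged primer panel (``default_primers``) covers the two
intergenic VNTR loci (VNTR-141, VNTR-105), the two ankyrin genes
(WD0550, WD0766) and the *wsp* surface-protein locus used as an
amplification quality control.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import IUPAC, Interval, SeqRecord
from .vntr import PeriodDecomposition, decompose_periods

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(primer: str) -> str:
    return primer.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    locus_id: str
    forward: str
    reverse: str
    max_mismatch: int = 0
    max_product: int = 5000

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be at least 15 bp")


@dataclass
class Amplicon:
    interval: Interval
    length: int
    locus_id: str
    template_id: str
    seq: str = ""


@dataclass
class MlvaAllele:
    locus_id: str
    amplicon_length: int
    copy_number: Optional[float] = None
    copy_string: Optional[str] = None


@dataclass
class MlvaProfile:
    strain_id: str
    alleles: dict[str, list[MlvaAllele]] = field(default_factory=dict)
    multiple_infection: dict[str, bool] = field(default_factory=dict)
    qc_failed: bool = False

    @property
    def valid(self) -> bool:
        return not self.qc_failed


def default_primers(max_mismatch: int = 0) -> list[PrimerPair]:
    """The packaged primer panel (VNTR-141, VNTR-105, WD0550, WD0766, wsp)."""
    text = resources.files("wolmlva.data").joinpath("primers.tsv").read_text()
    pairs = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        pairs.append(PrimerPair(row["locus"], row["forward"], row["reverse"], max_mismatch))
    return pairs


def read_primers(path, max_mismatch: int = 0) -> list[PrimerPair]:
    """Read a primers TSV (columns: locus, forward, reverse)."""
    with open(path) as fh:
        return [
            PrimerPair(row["locus"], row["forward"], row["reverse"], max_mismatch)
            for row in csv.DictReader(fh, delimiter="\t")
        ]


def _mismatch_counts(template: np.ndarray, primer: str) -> np.ndarray:
    """Vector of substitution counts of primer vs template at every offset."""
    m = len(primer)
    n = template.size
    if m > n:
        return np.empty(0, dtype=np.int32)
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for k, ch in enumerate(primer):
        allowed = np.frombuffer(IUPAC.get(ch, ch).encode(), dtype=np.uint8)
        counts += ~np.isin(template[k : k + n - m + 1], allowed)
    return counts


def find_primer_sites(
    template: str | SeqRecord, primer: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All primer binding sites: (position, strand).

    A ``+`` site means the primer matches the template forward strand at
    that position; a ``-`` site means the reverse complement of the
    primer matches there (the primer binds the minus strand). Only
    substitutions are tolerated, up to ``max_mismatch``. IUPAC ambiguity
    codes in the primer match their expansion set.
    """
    seq = template.residues if isinstance(template, SeqRecord) else template.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    sites: list[tuple[int, str]] = []
    fwd = _mismatch_counts(arr, primer.upper())
    for pos in np.nonzero(fwd <= max_mismatch)[0]:
        sites.append((int(pos), "+"))
    rev = _mismatch_counts(arr, iupac_revcomp(primer))
    for pos in np.nonzero(rev <= max_mismatch)[0]:
        sites.append((int(pos), "-"))
    return sorted(sites)


def in_silico_pcr(template: SeqRecord | str, pair: PrimerPair) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Both template orientations are considered: a product is spanned by a
    forward-primer ``+`` site upstream of a reverse-primer ``-`` site, or
    (template reverse-oriented relative to the primer design) a
    reverse-primer ``+`` site upstream of a forward-primer ``-`` site.
    """
    if isinstance(template, str):
        template = SeqRecord(id="template", residues=template)
    seq = template.residues
    mm = pair.max_mismatch
    f_sites = find_primer_sites(seq, pair.forward, mm)
    r_sites = find_primer_sites(seq, pair.reverse, mm)
    products: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()

    def _pair_up(starts: list[int], len_a: int, ends: list[int], len_b: int, strand: str):
        for i in starts:
            for j in ends:
                if j < i + len_a:
                    continue
                end = j + len_b
                length = end - i
                if length > pair.max_product or (i, end) in seen:
                    continue
                seen.add((i, end))
                products.append(
                    Amplicon(
                        interval=Interval(template.id, i, end, strand),
                        length=length,
                        locus_id=pair.locus_id,
                        template_id=template.id,
                        seq=seq[i:end],
                    )
                )

    _pair_up(
        [p for p, s in f_sites if s == "+"], len(pair.forward),
        [p for p, s in r_sites if s == "-"], len(pair.reverse), "+",
    )
    _pair_up(
        [p for p, s in r_sites if s == "+"], len(pair.reverse),
        [p for p, s in f_sites if s == "-"], len(pair.forward), "-",
    )
    products.sort(key=lambda a: (a.interval.start, a.length))
    return products


def call_allele(
    amplicon: Amplicon | str, consensus: str, locus_id: Optional[str] = None
) -> MlvaAllele:
    """Call a copy-number allele from an amplicon by period decomposition.

    An amplicon without repeat structure still yields a size-only allele
    (copy number absent), so size-based typing remains possible.
    """
    if isinstance(amplicon, Amplicon):
        seq = amplicon.seq
        locus_id = locus_id or amplicon.locus_id
        length = amplicon.length
    else:
        seq = amplicon
        locus_id = locus_id or "locus"
        length = len(seq)
    decomp = decompose_periods(seq, consensus, locus_id=locus_id)
    if not decomp.has_repeat:
        return MlvaAllele(locus_id, length)
    return MlvaAllele(locus_id, length, decomp.copy_number, decomp.copy_string)


def build_profile(
    strain_id: str,
    templates: Sequence[SeqRecord],
    pairs: Sequence[PrimerPair],
    consensi: Optional[dict[str, str]] = None,
    qc_locus: str = "wsp",
) -> MlvaProfile:
    """Assemble a multi-locus profile from templates (possibly a mixture).

    The QC locus must amplify from at least one template for the profile
    to be valid; otherwise it is flagged ``qc_failed``, mirroring the use
    of a ubiquitous single-copy gene as a DNA-extraction control.
    """
    if not pairs:
        raise ValueError("at least one primer pair required")
    consensi = consensi or {}
    profile = MlvaProfile(strain_id=strain_id)
    qc_present = False
    for pair in pairs:
        amplicons: list[Amplicon] = []
        for template in templates:
            amplicons.extend(in_silico_pcr(template, pair))
        if pair.locus_id == qc_locus:
            qc_present = True
            profile.qc_failed = not amplicons
            continue
        alleles = []
        for amp in amplicons:
            if pair.locus_id in consensi:
                alleles.append(call_allele(amp, consensi[pair.locus_id]))
            else:
                alleles.append(MlvaAllele(pair.locus_id, amp.length))
        profile.alleles[pair.locus_id] = alleles
        lengths = {a.amplicon_length for a in alleles}
        profile.multiple_infection[pair.locus_id] = len(lengths) > 1
    if not qc_present:
        profile.qc_failed = False  # no QC locus requested: nothing to fail
    return profile


def profile_distance(p1: MlvaProfile, p2: MlvaProfile) -> tuple[float, int]:
    """Manhattan distance over per-locus copy numbers of two profiles.

    Loci missing a copy number in either profile are excluded; the count
    of excluded loci is returned alongside the distance. Multi-allele
    loci contribute their minimum pairwise difference.
    """
    shared = set(p1.alleles) & set(p2.alleles)
    if not shared:
        raise ValueError("profiles share no loci")
    dist, excluded = 0.0, 0
    for locus in sorted(shared):
        c1 = [a.copy_number for a in p1.alleles[locus] if a.copy_number is not None]
        c2 = [a.copy_number for a in p2.alleles[locus] if a.copy_number is not None]
        if not c1 or not c2:
            excluded += 1
            continue
        dist += min(abs(a - b) for a in c1 for b in c2)
    return dist, excluded


def profiles_to_tsv(profiles: Sequence[MlvaProfile], path) -> None:
    """Serialize profiles: one row per strain/locus/allele."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["strain", "locus", "amplicon_length", "copy_number", "copy_string", "flags"])
        for prof in profiles:
            for locus in sorted(prof.alleles):
                flags = []
                if prof.multiple_infection.get(locus):
                    flags.append("multiple_infection")
                if prof.qc_failed:
                    flags.append("qc_failed")
                for allele in prof.alleles[locus]:
                    writer.writerow(
                        [
                            prof.strain_id,
                            locus,
                            allele.amplicon_length,
                            "" if allele.copy_number is None else allele.copy_number,
                            allele.copy_string or "",
                            ",".join(flags),
                        ]
                    )


def gel_report(profiles: Sequence[MlvaProfile], resolution: int = 5) -> str:
    """Human-readable band report; lengths within ``resolution`` bp collapse.

    This mimics agarose-gel resolution in the readable report only; the
    underlying data model always keeps exact lengths.
    """
    lines = []
    for prof in profiles:
        lines.append(f"strain {prof.strain_id}" + ("  [QC FAILED]" if prof.qc_failed else ""))
        for locus in sorted(prof.alleles):
            lengths = sorted(a.amplicon_length for a in prof.alleles[locus])
            bands: list[int] = []
            for ln in lengths:
                if not bands or ln - bands[-1] > resolution:
                    bands.append(ln)
            tag = "  (multiple infection)" if prof.multiple_infection.get(locus) else ""
            lines.append(f"  {locus}: " + " | ".join(f"{b} bp" for b in bands) + tag)
    return "\n".join(lines) + "\n"
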
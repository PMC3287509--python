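"""In-silico MLVA typing of three strains plus a mixed infection.

Three synthetic strains share one VNTR locus (identical flanks and
primer sites, as in real conserved-flank marker design) but carry 2, 4
and 7 period copies. A fourth "host" carries a mixture of two strains
and is flagged as a multiple infection by its two amplicon lengths.
"""

from wolmlva.mlva import PrimerPair, build_profile, gel_report
from wolmlva.synthgen import VntrSpec, make_vntr_locus

strains = {}
for name, n_full in [("strain_low", 2), ("strain_mid", 4), ("strain_high", 7)]:
    # same seed -> same flanks/primers/period, different copy number
    rec, truth = make_vntr_locus(VntrSpec(period_len=141, n_full=n_full, seed=11))
    rec.id = name
    strains[name] = (rec, truth)

truth = strains["strain_mid"][1]
pairs = [PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse)]
consensi = {"VNTR-141": truth.consensus}

profiles = [
    build_profile(name, [rec], pairs, consensi) for name, (rec, _) in strains.items()
]
mixed = build_profile(
    "mixed_host",
    [strains["strain_low"][0], strains["strain_high"][0]],
    pairs,
    consensi,
)
profiles.append(mixed)

print(gel_report(profiles))
# One band per strain; amplicon sizes differ by multiples of 141 bp
# (one period = one copy). The mixed host shows two bands at one locus,
# the in-silico analogue of a doubly infected specimen.
for p in profiles:
    for locus, alleles in p.alleles.items():
        for a in alleles:
            print(f"{p.strain_id:>12} {locus} {a.amplicon_length} bp -> {a.copy_string} copies")
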
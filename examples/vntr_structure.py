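"""Characterize the internal structure of a VNTR locus.

Generates a VNTR-141-like locus (15 bp direct-repeat units A and B, a
23 bp hairpin with a 9 bp palindromic stem, four full periods plus a
terminal partial copy), then decomposes the locus against its period
consensus and annotates the period's internal motifs.
"""

from wolmlva.synthgen import VntrSpec, make_vntr_locus
from wolmlva.vntr import decompose_periods, find_direct_repeats, find_dyads

spec = VntrSpec(
    period_len=141,
    n_full=4,
    terminal_fraction=0.3,
    plant_direct_repeat=(15, (0, -21)),
    plant_hairpin=(9, 5),
    seed=7,
)
locus, truth = make_vntr_locus(spec)

decomp = decompose_periods(locus.residues, truth.consensus)
print(f"locus: {len(locus)} bp, repeat region {decomp.region_start}..{decomp.region_end}")
print(f"copy number {decomp.copy_number} (copy string {decomp.copy_string!r})")
for inst in decomp.instances:
    dels = ", ".join(f"{l}bp@{o}" for o, l in inst.deletions) or "none"
    print(
        f"  {inst.start:>4}..{inst.end:<4} {inst.klass:>7} "
        f"aligned {inst.aligned_fraction:.2f} identity {inst.identity_to_consensus:.1f}% "
        f"deletions: {dels}"
    )

print("\nperiod-internal motifs:")
for m in find_direct_repeats(truth.consensus, min_unit=10, max_unit=30):
    print(f"  direct repeat: {m.unit_length} bp unit at {m.positions}")
for m in find_dyads(truth.consensus, min_stem=5, max_loop=10):
    print(f"  hairpin: {m.stem_len} bp stem, {m.loop_len} bp loop ({m.span} bp) at {m.positions[0]}")
# A full copy counts 1.0, a copy with a >=20 bp internal deletion 0.5,
# and the terminal partial its aligned fraction (42/141 -> 0.3), so
# this locus reads 4 + 0.3 = 4.3 copies.
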
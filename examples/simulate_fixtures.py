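"""Generate ground-truth-annotated synthetic fixtures.

Writes a VNTR locus, an ANK gene and a small genome to FASTA with their
truth annotations (JSON + GFF3), demonstrating that regeneration with
the same seed is byte-identical. Outputs go under ./fixtures_demo/.
"""

from pathlib import Path

from wolmlva.seqio import write_fasta
from wolmlva.synthgen import (
    AnkGeneSpec,
    VntrSpec,
    make_ank_gene,
    make_genome,
    make_vntr_locus,
    truth_to_gff3,
)

out = Path("fixtures_demo")
out.mkdir(exist_ok=True)

locus, locus_truth = make_vntr_locus(VntrSpec(period_len=105, n_full=4, n_half=2, seed=1))
write_fasta([locus], out / "vntr.fa")
locus_truth.to_json(out / "vntr.truth.json")
print(f"VNTR locus: {len(locus)} bp, truth {locus_truth.copy_string} copies")

gene, gene_truth = make_ank_gene(AnkGeneSpec(n_units=8, tm_tail=True, seed=2))
write_fasta([gene], out / "ank.fa")
gene_truth.to_json(out / "ank.truth.json")
print(f"ANK gene: {len(gene)} bp CDS, {gene_truth.n_units} planted units")

genome, genome_truth = make_genome(
    [VntrSpec(seed=3), VntrSpec(period_len=105, seed=4)], 20_000, seed=5
)
write_fasta([genome], out / "genome.fa")
genome_truth.to_json(out / "genome.truth.json")
truth_to_gff3(genome_truth, genome.id, out / "genome.truth.gff3")
print(f"genome: {len(genome)} bp with {len(genome_truth.loci)} planted loci")

again, _ = make_genome([VntrSpec(seed=3), VntrSpec(period_len=105, seed=4)], 20_000, seed=5)
print("regeneration byte-identical:", again.residues == genome.residues)
# The truth files carry planted intervals, copy strings, motif positions
# and expected amplicon lengths, so any analysis result can be checked
# against what was actually planted.
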
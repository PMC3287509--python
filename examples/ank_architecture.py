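"""ANK gene architecture and repeat-unit evolution across three strains.

Builds three orthologous ankyrin-repeat genes from one unit stock: a
reference, a strain with a tandem duplication of unit 3, and a strain
with a premature stop ahead of its transmembrane tail. Prints each
architecture and the cluster/event report, then the repeat-unit
neighbor-joining tree.
"""

import numpy as np

from wolmlva.ank import (
    align_repeat_units,
    analyze_architecture,
    cluster_positions,
    repeat_unit_tree,
)
from wolmlva.synthgen import AnkGeneSpec, make_ank_gene

genes = {
    "ref": AnkGeneSpec(n_units=6, tm_tail=True, per_unit_mutation_rate=0.25, seed=9),
    "dup": AnkGeneSpec(
        n_units=6, tm_tail=True, per_unit_mutation_rate=0.25, duplicate_indices=(3,), seed=9
    ),
    "stop": AnkGeneSpec(
        n_units=6, tm_tail=True, per_unit_mutation_rate=0.25,
        premature_stop_codon=2 + 6 * 33, seed=9,
    ),
}

units = []
for name, spec in genes.items():
    cds, _ = make_ank_gene(spec)
    arch = analyze_architecture(cds.residues, protein_id=name)
    stop = f"premature stop at codon {arch.premature_stop}" if arch.premature_stop else "intact"
    print(
        f"{name:>5}: {len(arch.repeats)} ANK units, {len(arch.tm_segments)} TM segment(s), "
        f"{arch.mass_kda} kDa, {stop}"
    )
    units.extend((name, r.index, r.unit_seq) for r in arch.repeats)

report = cluster_positions(units)
print(f"\n{len(report.clusters)} orthologous-position clusters")
for strain, cluster, idxs in report.duplications:
    print(f"duplication: {strain} contributes adjacent units {idxs} to cluster {cluster}")
for a, b, c1, c2 in report.shufflings:
    print(f"shuffling: clusters {c1}/{c2} in different order between {a} and {b}")

aligned = align_repeat_units([u for _, _, u in units])
tree = repeat_unit_tree(aligned, [f"{s}_{i}" for s, i, _ in units])
print("\nrepeat-unit NJ tree (newick):")
print(tree.newick)
# Units at the same position in different orthologs cluster together
# (ref_1 with dup_1 and stop_1, and so on); the duplicated unit pair
# sits as a zero-length cherry inside its position cluster.
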
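"""ANK architecture: translation, unit detection, TMs, mass, trees, events."""

import numpy as np
import pytest

from wolmlva.ank import (
    WATER_MASS,
    NotOrthologousError,
    align_repeat_units,
    analyze_architecture,
    cluster_positions,
    default_profile,
    detect_insertion,
    find_ank_repeats,
    nj_tree,
    p_distance_matrix,
    predict_tm,
    protein_mass,
    protein_mass_da,
    repeat_unit_tree,
    translate_cds,
)
from wolmlva.synthgen import AnkGeneSpec, back_translate, make_ank_gene

from _oracles import random_additive_tree
from conftest import random_dna

AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class TestTranslate:
    def test_terminal_stop_not_premature(self):
        assert translate_cds("ATGAAATAA") == ("MK", None)

    def test_mid_cds_stop_is_premature(self):
        cds = "ATG" + "GAA" * 148 + "TAA" + "GAA" * 150 + "TAA"
        protein, stop = translate_cds(cds)
        assert stop == 150
        assert len(protein) == 149

    def test_n_codon_translates_to_x(self):
        assert translate_cds("ATGANAAAA")[0] == "MXK"

    def test_planted_units_round_trip(self):
        rec, truth = make_ank_gene(AnkGeneSpec(n_units=3, seed=1))
        protein, stop = translate_cds(rec.residues)
        assert protein == truth.protein
        assert stop is None

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            translate_cds("AT")


class TestAnkDetection:
    def test_three_exact_consensus_copies(self):
        cons = default_profile().consensus
        units = find_ank_repeats(cons * 3)
        assert [u.aa_start for u in units] == [0, 33, 66]
        assert [u.index for u in units] == [1, 2, 3]

    def test_random_protein_yields_nothing(self):
        rng = np.random.default_rng(0)
        protein = "".join(rng.choice(AAS, 500))
        assert find_ank_repeats(protein) == []

    def test_short_protein_empty(self):
        assert find_ank_repeats("MKLV") == []

    @pytest.mark.parametrize("u", [2, 5, 8, 11, 14])
    def test_unit_recovery_across_sizes(self, u):
        rec, truth = make_ank_gene(AnkGeneSpec(n_units=u, seed=u))
        protein, _ = translate_cds(rec.residues)
        assert len(find_ank_repeats(protein)) == u

    def test_units_non_overlapping_and_ordered(self):
        rec, _ = make_ank_gene(AnkGeneSpec(n_units=6, seed=3))
        protein, _ = translate_cds(rec.residues)
        units = find_ank_repeats(protein)
        for a, b in zip(units, units[1:]):
            assert a.aa_end <= b.aa_start


class TestTm:
    def test_poly_leucine(self):
        segs = predict_tm("L" * 30)
        assert len(segs) == 1
        assert segs[0][1] - segs[0][0] >= 15

    def test_poly_aspartate(self):
        assert predict_tm("D" * 30) == []

    def test_two_planted_c_terminal_segments(self):
        rec, _ = make_ank_gene(AnkGeneSpec(n_units=4, tm_tail=True, seed=5))
        protein, _ = translate_cds(rec.residues)
        segs = predict_tm(protein)
        assert len(segs) == 2
        assert all(s >= 4 * 33 for s, _ in segs)  # C-terminal, after the units

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            predict_tm("L" * 40, window=18)


class TestMass:
    def test_glycine_dipeptide(self):
        assert protein_mass_da("GG") == pytest.approx(132.1191, abs=1e-3)
        assert protein_mass("GG") == 0.1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            protein_mass("")

    def test_mass_additivity(self):
        rng = np.random.default_rng(9)
        p1 = "".join(rng.choice(AAS, 40))
        p2 = "".join(rng.choice(AAS, 60))
        assert protein_mass_da(p1 + p2) == pytest.approx(
            protein_mass_da(p1) + protein_mass_da(p2) - WATER_MASS
        )


class TestInsertion:
    def test_planted_918bp_block(self, make_dna):
        ref = make_dna(1400, seed=30)
        gene = ref[:700] + make_dna(918, seed=31) + ref[700:]
        hits = detect_insertion(gene, ref)
        assert len(hits) == 1
        pos, length = hits[0]
        assert length == 918  # length is exact
        assert abs(pos - 700) <= 3  # boundary bases may chance-match context

    def test_identical_sequences(self, make_dna):
        ref = make_dna(900, seed=32)
        assert detect_insertion(ref, ref) == []

    def test_two_insertions_exact_lengths(self, make_dna):
        ref = make_dna(1200, seed=33)
        gene = ref[:300] + make_dna(150, seed=34) + ref[300:800] + make_dna(300, seed=35) + ref[800:]
        assert detect_insertion(gene, ref, min_len=100) == [(300, 150), (800, 300)]

    def test_unrelated_sequences_error(self, make_dna):
        with pytest.raises(NotOrthologousError):
            detect_insertion(make_dna(600, seed=36), make_dna(600, seed=37))


class TestUnitAlignment:
    def test_identical_units_no_gaps(self):
        cons = default_profile().consensus
        aligned = align_repeat_units([cons, cons, cons])
        assert aligned == [cons, cons, cons]

    def test_33_vs_34_one_gap_column(self):
        cons = default_profile().consensus
        longer = cons[:15] + "G" + cons[15:]
        aligned = align_repeat_units([cons, longer])
        assert len(aligned[0]) == 34
        assert aligned[0].count("-") == 1
        assert aligned[1].count("-") == 0

    def test_degapping_restores_inputs(self):
        rng = np.random.default_rng(40)
        cons = default_profile().consensus
        units = []
        for _ in range(5):
            u = list(cons)
            for k in range(33):
                if rng.random() < 0.2:
                    u[k] = str(rng.choice(AAS))
            if rng.random() < 0.5:
                u.insert(int(rng.integers(33)), str(rng.choice(AAS)))
            units.append("".join(u))
        aligned = align_repeat_units(units)
        assert [a.replace("-", "") for a in aligned] == units
        assert len({len(a) for a in aligned}) == 1
        assert len(aligned[0]) <= 40

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            align_repeat_units([default_profile().consensus])


class TestNeighborJoining:
    def test_two_cherries(self):
        d = np.array(
            [[0, 0.02, 0.5, 0.5], [0.02, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.04], [0.5, 0.5, 0.04, 0]]
        )
        t = nj_tree(d, ["A1", "A2", "B1", "B2"])
        # unrooted 4-leaf tree: the internal edge must induce the
        # bipartition {A1,A2} | {B1,B2}
        clades = {
            frozenset(tip.name for tip in node.tips())
            for node in t.tree.non_tips()
        }
        assert frozenset({"A1", "A2"}) in clades or frozenset({"B1", "B2"}) in clades

    @pytest.mark.parametrize("seed", range(6))
    def test_recovers_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels, dm = random_additive_tree(rng, n)
        t = nj_tree(dm, labels)
        # additive matrices have a unique tree: NJ patristic distances
        # must reproduce the input exactly
        tip_dists = t.tree.tip_tip_distances(labels)
        got = np.asarray(tip_dists.data)
        order = [tip_dists.ids.index(l) for l in labels]
        got = got[np.ix_(order, order)]
        assert np.allclose(got, dm, atol=1e-8)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(77)
        d = np.zeros((5, 5))
        for i in range(5):
            for j in range(i + 1, 5):
                d[i, j] = d[j, i] = rng.uniform(0.01, 0.6)
        t = nj_tree(d, list("abcde"))
        assert all((n.length or 0) >= 0 for n in t.tree.traverse())

    def test_identical_units_star_tree(self):
        cons = default_profile().consensus
        t = repeat_unit_tree([cons] * 4, ["a", "b", "c", "d"])
        assert t.n_leaves == 4
        assert all((n.length or 0) == 0 for n in t.tree.tips())

    def test_duplicated_unit_copies_are_siblings(self):
        rec, truth = make_ank_gene(
            AnkGeneSpec(n_units=6, duplicate_indices=(3,), per_unit_mutation_rate=0.2, seed=50)
        )
        protein, _ = translate_cds(rec.residues)
        units = find_ank_repeats(protein)
        assert len(units) == 7
        aligned = align_repeat_units([u.unit_seq for u in units])
        t = repeat_unit_tree(aligned, [f"u{u.index}" for u in units])
        # planted duplicate of unit 3 sits at index 4; the two copies are
        # identical, so they must form a cherry
        dup = t.tree.find("u3")
        assert {tip.name for tip in dup.parent.tips()} == {"u3", "u4"}


class TestClusterPositions:
    def _panel(self, seed=60):
        """Three strains from a shared unit stock, one duplication, one swap."""
        rng = np.random.default_rng(seed)
        cons = default_profile().consensus
        stock = []
        for _ in range(5):
            u = list(cons)
            for k in range(33):
                if rng.random() < 0.3:
                    u[k] = str(rng.choice(AAS))
            stock.append("".join(u))
        units = []
        for i, u in enumerate(stock, 1):  # reference strain
            units.append(("ref", i, u))
        order_dup = stock[:3] + [stock[2]] + stock[3:]  # duplication of unit 3
        for i, u in enumerate(order_dup, 1):
            units.append(("dup_strain", i, u))
        order_swap = stock[:3] + [stock[4], stock[3]]  # last two swapped
        for i, u in enumerate(order_swap, 1):
            units.append(("swap_strain", i, u))
        return units

    def test_duplication_flagged(self):
        report = cluster_positions(self._panel())
        assert any(s == "dup_strain" and idxs == (3, 4) for s, _, idxs in report.duplications)
        assert not any(s == "ref" for s, _, _ in report.duplications)

    def test_shuffling_flagged_between_swapped_and_reference(self):
        report = cluster_positions(self._panel())
        pairs = {(a, b) for a, b, _, _ in report.shufflings}
        assert ("ref", "swap_strain") in pairs or ("swap_strain", "ref") in pairs
        assert ("ref", "dup_strain") not in pairs

    def test_identical_architectures_no_events(self):
        rng = np.random.default_rng(61)
        cons = default_profile().consensus
        stock = []
        for _ in range(4):
            u = list(cons)
            for k in range(33):
                if rng.random() < 0.3:
                    u[k] = str(rng.choice(AAS))
            stock.append("".join(u))
        units = [(s, i, u) for s in ("x", "y") for i, u in enumerate(stock, 1)]
        report = cluster_positions(units)
        assert report.duplications == []
        assert report.shufflings == []
        # orthologous positions cluster across strains
        assert len(report.clusters) == 4


class TestArchitecture:
    def test_full_architecture(self):
        rec, truth = make_ank_gene(AnkGeneSpec(n_units=8, tm_tail=True, seed=70))
        arch = analyze_architecture(rec.residues, protein_id="g1")
        assert len(arch.repeats) == 8
        assert len(arch.tm_segments) == 2
        assert arch.premature_stop is None
        assert arch.mass_kda > 25

    def test_premature_stop_ablates_tm_segments(self):
        stop_at = 2 + 8 * 33  # right after the last unit, before the tail
        rec, _ = make_ank_gene(
            AnkGeneSpec(n_units=8, tm_tail=True, premature_stop_codon=stop_at, seed=70)
        )
        arch = analyze_architecture(rec.residues)
        assert arch.premature_stop == stop_at
        assert arch.tm_segments == []
        assert len(arch.repeats) == 8

    def test_is_element_insertion_reported(self, make_dna):
        ref, _ = make_ank_gene(AnkGeneSpec(n_units=10, seed=71))
        mutant, _ = make_ank_gene(AnkGeneSpec(n_units=10, insertion=(3 + 33 * 9 * 3 + 50, 918), seed=71))
        arch = analyze_architecture(mutant.residues, reference_cds=ref.residues)
        assert [(p, l) for p, l, _ in arch.insertions] == [(3 + 33 * 9 * 3 + 50, 918)]
        assert arch.insertions[0][2] == "IS-element-sized insertion"
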
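"""In-silico PCR, allele calling and MLVA profiles."""

import numpy as np
import pytest

from wolmlva.seqio import IUPAC, SeqRecord, revcomp
from wolmlva.mlva import (
    PrimerPair,
    build_profile,
    call_allele,
    default_primers,
    find_primer_sites,
    gel_report,
    in_silico_pcr,
    profile_distance,
    profiles_to_tsv,
)
from wolmlva.synthgen import VntrSpec, make_vntr_locus

from _oracles import brute_force_primer_sites
from conftest import random_dna


PRIMER_F = "GGAGTATTATTGATATGCGAT"[:19]
WSP_TEMPLATE_F = "TGGTCCAATAAGTGATGAAGAAAC"
WSP_TEMPLATE_R = "AAAAATTAAACGCTACTCCA"


def _wsp_template(seed=0):
    rng = np.random.default_rng(seed)
    return WSP_TEMPLATE_F + random_dna(rng, 560) + revcomp(WSP_TEMPLATE_R)


class TestPrimerSites:
    def test_forward_hit(self, make_dna):
        template = make_dna(200, seed=1) + PRIMER_F + make_dna(50, seed=2)
        assert (200, "+") in find_primer_sites(template, PRIMER_F)

    def test_reverse_hit(self, make_dna):
        template = make_dna(100, seed=3) + revcomp(PRIMER_F) + make_dna(50, seed=4)
        assert (100, "-") in find_primer_sites(template, PRIMER_F)

    def test_iupac_expansion(self):
        template = "T" * 20 + "ACGTACGTACGTACGTA" + "T" * 20
        primer = "ACGTACGTWCGTACGTA"  # W matches A
        assert (20, "+") in find_primer_sites(template, primer)

    @pytest.mark.parametrize("mm", [0, 1, 2])
    def test_matches_naive_oracle(self, mm):
        rng = np.random.default_rng(50 + mm)
        template = random_dna(rng, 400, gc=0.4)
        primer = template[120:140]  # guaranteed one perfect site
        ours = find_primer_sites(template, primer, mm)
        oracle = brute_force_primer_sites(template, primer, mm, IUPAC)
        assert ours == oracle


class TestInSilicoPcr:
    def test_constructed_arithmetic(self, make_dna):
        # flank(100) + 3x141 period + flank(100), outermost 20-mers as primers
        spec = VntrSpec(period_len=141, n_full=3, flank_len_f=100, flank_len_r=100,
                        primer_len=20, seed=8)
        rec, truth = make_vntr_locus(spec)
        pair = PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse)
        amps = in_silico_pcr(rec, pair)
        assert len(amps) == 1
        assert amps[0].length == 100 + 3 * 141 + 100 == 623

    def test_no_reverse_site_no_product(self, make_dna):
        template = make_dna(100, seed=9) + PRIMER_F + make_dna(100, seed=10)
        pair = PrimerPair("x", PRIMER_F, "ACGTACGTACGTACGTACGT")
        assert in_silico_pcr(template, pair) == []

    def test_reverse_oriented_template(self, make_dna):
        spec = VntrSpec(period_len=50, n_full=2, seed=11, plant_hairpin=None,
                        plant_direct_repeat=None)
        rec, truth = make_vntr_locus(spec)
        pair = PrimerPair("x", truth.primer_forward, truth.primer_reverse)
        flipped = SeqRecord("flipped", revcomp(rec.residues))
        amps = in_silico_pcr(flipped, pair)
        assert len(amps) == 1
        assert amps[0].length == truth.amplicon_length
        assert amps[0].interval.strand == "-"

    def test_max_product_cap(self, make_dna):
        spec = VntrSpec(period_len=141, n_full=4, seed=12)
        rec, truth = make_vntr_locus(spec)
        pair = PrimerPair("x", truth.primer_forward, truth.primer_reverse, max_product=300)
        assert in_silico_pcr(rec, pair) == []


class TestAlleleCalling:
    def test_two_full_plus_half(self):
        spec = VntrSpec(period_len=105, n_full=2, n_half=1, half_deletion_len=25, seed=13)
        rec, truth = make_vntr_locus(spec)
        pair = PrimerPair("VNTR-105", truth.primer_forward, truth.primer_reverse)
        amp = in_silico_pcr(rec, pair)[0]
        allele = call_allele(amp, truth.consensus)
        assert allele.copy_string == "2+1x0.5"
        assert allele.amplicon_length == truth.amplicon_length

    def test_flanks_only_size_only_allele(self, make_dna):
        template = make_dna(400, seed=14)
        amp_seq = template[50:350]
        allele = call_allele(amp_seq, make_dna(105, seed=15))
        assert allele.copy_number is None
        assert allele.amplicon_length == 300

    def test_one_more_period_shifts_length_by_period(self):
        # the wMel/wMelCS relation: one period = one copy = period-size bp
        lengths = {}
        for n in (3, 4):
            spec = VntrSpec(period_len=141, n_full=n, seed=16)
            rec, truth = make_vntr_locus(spec)
            pair = PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse)
            amp = in_silico_pcr(rec, pair)[0]
            allele = call_allele(amp, truth.consensus)
            lengths[n] = (allele.amplicon_length, allele.copy_number)
        assert lengths[4][0] - lengths[3][0] == 141
        assert lengths[4][1] - lengths[3][1] == pytest.approx(1.0)


class TestProfiles:
    def _strain_templates(self, n_full, seed):
        spec = VntrSpec(period_len=141, n_full=n_full, seed=seed)
        rec, truth = make_vntr_locus(spec)
        return rec, truth

    def test_single_strain_no_flags(self):
        rec, truth = self._strain_templates(4, seed=17)
        pairs = [
            PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse),
            PrimerPair("wsp", WSP_TEMPLATE_F, WSP_TEMPLATE_R),
        ]
        templates = [rec, SeqRecord("wsp_locus", _wsp_template())]
        prof = build_profile("strainA", templates, pairs, {"VNTR-141": truth.consensus})
        assert not prof.qc_failed
        assert prof.multiple_infection == {"VNTR-141": False}
        assert prof.alleles["VNTR-141"][0].copy_number == 4.0

    def test_mixture_flags_multiple_infection(self):
        # two co-infecting strains differing by 2 periods -> 282 bp apart
        rec1, truth1 = self._strain_templates(4, seed=18)
        rec2, _ = self._strain_templates(6, seed=18)
        rec2.id = "strain2_locus"
        pairs = [
            PrimerPair("VNTR-141", truth1.primer_forward, truth1.primer_reverse),
            PrimerPair("wsp", WSP_TEMPLATE_F, WSP_TEMPLATE_R),
        ]
        templates = [rec1, rec2, SeqRecord("wsp_locus", _wsp_template())]
        prof = build_profile("mixed_host", templates, pairs, {"VNTR-141": truth1.consensus})
        assert prof.multiple_infection["VNTR-141"]
        lengths = sorted(a.amplicon_length for a in prof.alleles["VNTR-141"])
        assert lengths[1] - lengths[0] == 282

    def test_mixture_completeness(self):
        # k strains with distinct planted alleles -> k distinct lengths
        templates, pairs = [], None
        for k, n_full in enumerate((2, 4, 7)):
            rec, truth = self._strain_templates(n_full, seed=19)
            rec.id = f"strain{k}"
            templates.append(rec)
            pairs = [PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse)]
        prof = build_profile("triple", templates, pairs)
        assert len({a.amplicon_length for a in prof.alleles["VNTR-141"]}) == 3

    def test_qc_failure_flag(self):
        rec, truth = self._strain_templates(4, seed=20)
        pairs = [
            PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse),
            PrimerPair("wsp", WSP_TEMPLATE_F, WSP_TEMPLATE_R),
        ]
        prof = build_profile("no_dna", [rec], pairs)  # no wsp template
        assert prof.qc_failed
        assert not prof.valid

    def test_profile_distance(self):
        rec1, truth1 = self._strain_templates(4, seed=21)
        rec2, truth2 = self._strain_templates(5, seed=21)
        pairs = [PrimerPair("VNTR-141", truth1.primer_forward, truth1.primer_reverse)]
        consensi = {"VNTR-141": truth1.consensus}
        p1 = build_profile("a", [rec1], pairs, consensi)
        p2 = build_profile("b", [rec2], pairs, consensi)
        assert profile_distance(p1, p1) == (0.0, 0)
        assert profile_distance(p1, p2)[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            profile_distance(p1, build_profile("c", [rec1], [PrimerPair("other", "A" * 20, "C" * 20)]))

    def test_tsv_and_gel_outputs(self, tmp_path):
        rec, truth = self._strain_templates(4, seed=22)
        pairs = [PrimerPair("VNTR-141", truth.primer_forward, truth.primer_reverse)]
        prof = build_profile("s", [rec], pairs, {"VNTR-141": truth.consensus})
        out = tmp_path / "profiles.tsv"
        profiles_to_tsv([prof], out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["strain", "locus", "amplicon_length", "copy_number", "copy_string", "flags"]
        assert lines[1].startswith("s\tVNTR-141\t")
        report = gel_report([prof])
        assert "VNTR-141" in report and "bp" in report


class TestPackagedPrimers:
    def test_panel_contents(self):
        pairs = {p.locus_id: p for p in default_primers()}
        assert set(pairs) == {"VNTR-141", "VNTR-105", "WD0550", "WD0766", "wsp"}
        assert pairs["VNTR-141"].forward == "GGAGTATTATTGATATGCG"
        assert pairs["VNTR-105"].reverse == "ATGACACCTTACTTAACCGTC"
        assert all(len(p.forward) >= 15 and len(p.reverse) >= 15 for p in pairs.values())

    def test_primer_length_floor(self):
        with pytest.raises(ValueError):
            PrimerPair("short", "ACGTACGTACGT", "ACGTACGTACGTACGT")
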
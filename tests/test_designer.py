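"""Reporter-construct engineering: frame-preserving insertion, minimal-edit
PTC introduction, synonymous seed disruption, compensatory mimics, hairpin
insertion and splice-site disruption, with exhaustive-enumeration oracles."""

from __future__ import annotations

import itertools

import pytest

from mirsurv.designer import (
    HAIRPIN_40NT,
    LET7A_MIRE,
    DesignError,
    Intron,
    NoStopWithinTwoEditsError,
    ReporterConstruct,
    add_hairpin,
    compensatory_mimic,
    disable_splice_sites,
    disrupt_seed_synonymously,
    insert_in_frame,
    introduce_ptc,
    minimal_stop_edit,
)
from mirsurv.mire import seed_match_sites, seed_of
from mirsurv.models import STOP_CODONS, reverse_complement
from mirsurv.ptc import annotate_ptc
from mirsurv.retention import retained_isoform
from mirsurv.synth import LET7A, MIR125B

from conftest import TOY_CDS, variant_at


@pytest.fixture
def construct():
    return ReporterConstruct("rep", utr5="G" * 40, cds=TOY_CDS, utr3="TTCCAAGG")


class TestInsertInFrame:
    def test_23nt_element_padded_to_24_frame_preserved(self, construct):
        new = insert_in_frame(construct, LET7A_MIRE, 5)
        assert len(new.cds) == len(construct.cds) + 24
        assert len(new.cds) % 3 == 0
        # translation 5' of the insertion unchanged
        assert new.translate()[:5] == construct.translate()[:5]

    def test_3n_element_inserted_unchanged(self, construct):
        new = insert_in_frame(construct, "GCAGCAGCA", 4)
        assert len(new.cds) == len(construct.cds) + 9

    def test_removing_inserted_codons_restores_translation(self, construct):
        element = LET7A_MIRE
        new = insert_in_frame(construct, element, 5)
        block = 24
        restored = new.cds[:15] + new.cds[15 + block:]
        assert restored == construct.cds
        # translate-and-compare oracle on the downstream part
        assert new.translate()[5 + block // 3:] == construct.translate()[5:]


class TestIntroducePtc:
    def test_aaa_single_substitution_to_taa(self, construct):
        # toy codon 6 is AAA
        new = introduce_ptc(construct, 6)
        assert new.codon(6) == "TAA"
        assert "1 substitution" in new.edit_log[-1]

    def test_tgg_single_substitution_brute_force_oracle(self):
        stops_one_edit = {
            codon[:p] + b + codon[p + 1:]
            for codon in ["TGG"] for p in range(3) for b in "ACGT"
        } & STOP_CODONS
        got, n = minimal_stop_edit("TGG")
        assert n == 1 and got in stops_one_edit and stops_one_edit == {"TGA", "TAG"}

    def test_ccc_has_no_stop_within_two_edits(self):
        # exhaustive oracle: minimal Hamming distance from CCC to any stop
        oracle = min(
            sum(a != b for a, b in zip("CCC", stop)) for stop in STOP_CODONS
        )
        assert oracle == 3
        with pytest.raises(NoStopWithinTwoEditsError) as exc:
            minimal_stop_edit("CCC")
        assert exc.value.min_edits == 3

    def test_two_edit_codon(self):
        # CCA: single edits cannot reach a stop (enumerated), two can (TGA)
        singles = {
            "CCA"[:p] + b + "CCA"[p + 1:] for p in range(3) for b in "ACGT"
        }
        assert not (singles & STOP_CODONS)
        got, n = minimal_stop_edit("CCA")
        assert n == 2 and got in STOP_CODONS

    def test_already_stop_rejected(self, construct):
        with pytest.raises(DesignError, match="already a stop"):
            introduce_ptc(construct, 19)


class TestDisruptSeed:
    def _with_site(self):
        # CDS with the let-7a motif TACCTC spanning codons 5-7 at offset 16:
        # the motif spans codons GTT ACC TCA (Val Thr Ser) at offset 17
        cds = "ATG" + "GCA" * 4 + "GTT" "ACC" "TCA" + "CCT" * 4 + "TAA"
        c = ReporterConstruct("rep", "G" * 20, cds, "TT")
        start = cds.find("TACCTC")
        assert start == 17
        return c, start

    def test_synonymous_two_base_disruption_found(self):
        c, start = self._with_site()
        new = disrupt_seed_synonymously(c, start, "TACCTC")
        assert new is not None
        assert new.translate() == c.translate()
        assert seed_match_sites(new.cds, LET7A) == []

    def test_brute_force_oracle_confirms_a_solution_exists(self):
        c, start = self._with_site()
        found = False
        for (p1, p2) in itertools.combinations(range(6), 2):
            for b1 in "ACGT":
                for b2 in "ACGT":
                    cds = list(c.cds)
                    if b1 == cds[start + p1] or b2 == cds[start + p2]:
                        continue
                    cds[start + p1], cds[start + p2] = b1, b2
                    mutant = ReporterConstruct.__new__(ReporterConstruct)
                    mutant.name, mutant.utr5, mutant.cds, mutant.utr3 = "m", c.utr5, "".join(cds), c.utr3
                    mutant.introns, mutant.ptc_codons = [], []
                    mutant.features, mutant.edit_log = [], []
                    try:
                        same = mutant.translate() == c.translate()
                    except KeyError:
                        continue
                    if same and "TACCTC" not in mutant.cds:
                        found = True
        assert found

    def test_met_trp_seed_has_no_solution(self):
        # seed spanning ATG+TGG only: every base change alters the amino acid
        cds = "ATG" + "GCA" + "ATG" "TGG" + "CCT" + "TAA"
        c = ReporterConstruct("rep", "GG", cds, "TT")
        start = 6
        motif = c.cds[start:start + 6]
        assert motif == "ATGTGG"
        assert disrupt_seed_synonymously(c, start, motif) is None


class TestCompensatoryMimic:
    def test_identity_on_unmutated_seed(self):
        motif = seed_of(LET7A).motif
        mimic = compensatory_mimic(LET7A, motif)
        assert mimic.sequence[1:7] == LET7A.sequence[1:7]

    def test_two_nt_mutant_seed_maps_to_two_mirna_positions(self):
        motif = seed_of(MIR125B).motif            # TCAGGG
        mutant = "TGAGGC"                          # changed at motif pos 1 and 5
        mimic = compensatory_mimic(MIR125B, mutant)
        diffs = [i for i in range(22) if mimic.sequence[i] != MIR125B.sequence[i]]
        # positional mapping oracle: motif index j pairs with miRNA index
        # 1 + (5 - j), so motif changes at {1, 5} mirror to miRNA {5, 1}
        assert diffs == [1, 5]

    def test_mimic_matches_mutant_site_and_not_wild_type(self):
        motif = seed_of(MIR125B).motif
        mutant = "TGAGGC"
        mimic = compensatory_mimic(MIR125B, mutant)
        assert seed_match_sites(f"GG{mutant}GG", mimic) == [2]
        assert seed_match_sites(f"GG{motif}GG", mimic) == []
        assert seed_match_sites(f"GG{mutant}GG", MIR125B) == []


class TestHairpin:
    def test_printed_hairpin_is_perfect_inverted_repeat_of_40nt(self):
        assert len(HAIRPIN_40NT) == 40
        assert reverse_complement(HAIRPIN_40NT) == HAIRPIN_40NT

    def test_inserted_29nt_upstream_of_atg(self, construct):
        new = add_hairpin(construct)
        assert len(new.utr5) == 40 + 40
        idx = new.utr5.find(HAIRPIN_40NT)
        assert len(new.utr5) - (idx + 40) == 29
        assert new.translate() == construct.translate()

    def test_utr_too_short(self):
        c = ReporterConstruct("rep", "G" * 10, TOY_CDS, "")
        with pytest.raises(DesignError, match="too short"):
            add_hairpin(c)


class TestSpliceSites:
    def _with_intron(self):
        intron = "GT" + "C" * 20 + "AG"
        c = ReporterConstruct("rep", "G" * 12, TOY_CDS, "TTCC",
                              introns=[Intron(position=30, sequence=intron)])
        return c

    def test_donor_and_acceptor_mutated(self):
        c = self._with_intron()
        new = disable_splice_sites(c, 0)
        s = new.introns[0].sequence
        assert not s.startswith("GT") and not s.endswith("AG")
        assert new.introns[0].retained

    def test_retained_feature_propagates_to_retained_isoform(self):
        c = self._with_intron()
        new = disable_splice_sites(c, 0)
        genome, model = new.as_transcript()
        iso, _, _ = retained_isoform(model, 0, genome)
        assert iso == new.retained_sequence() == new.pre_mrna_sequence()

    def test_short_intron_rejected(self):
        c = ReporterConstruct("rep", "G" * 12, TOY_CDS, "TTCC",
                              introns=[Intron(position=30, sequence="GTAG")])
        with pytest.raises(DesignError, match="shorter than 5"):
            disable_splice_sites(c, 0)


class TestAnnotatorRoundTrip:
    @pytest.mark.parametrize("d", [9, 10, 16, 25])
    def test_ptc_distance_d_from_planted_mire(self, cfg, d):
        """A construct carrying a nonsense-editable codon d nt upstream of a
        planted miRE must come back from the annotator + scanner with
        distance exactly d and the 10-nt rule verdict."""
        from mirsurv.mire import functional_mires
        motif = seed_of(LET7A).motif
        # reference CDS: codon 6 is AAA (A->T makes TAA); site at distance d
        cds = "ATG" + "GCA" * 5 + "AAA" + "GCA" * 40 + "TAA"
        ptc_end_cds = 3 * 7
        site_cds = ptc_end_cds + d
        cds = cds[:site_cds] + motif + cds[site_cds + 6:]
        c = ReporterConstruct("rep", "G" * 15, cds, "TTTT")
        genome, t = c.as_transcript()
        v = variant_at(t, genome, c.cds_start + 18, "T")
        a = annotate_ptc(t, genome, v, cfg)
        spliced = t.spliced_sequence(genome)
        offs = [i for i in range(len(spliced) - 5) if spliced[i:i + 6] == motif]
        sites = functional_mires(a, offs, LET7A.mirna_id, cfg)
        planted = [s for s in sites if s.distance_from_ptc_nt == d]
        assert len(planted) == 1
        assert planted[0].functional is (d >= cfg.mire_min_distance_nt)
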
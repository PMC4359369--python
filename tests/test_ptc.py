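"""Consequence calling, the 50-nt EJC-NMD rule, PTC-STOP extraction and the
heterozygosity/expression/length filters, checked against brute-force
translation oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mirsurv.models import (
    AbundanceRecord,
    GenomeSequence,
    STOP_CODONS,
    SnvRecord,
    ThresholdsConfig,
    TranscriptModel,
    reverse_complement,
)
from mirsurv.ptc import (
    Consequence,
    ReferenceMismatchError,
    annotate_ptc,
    candidate_filter,
    choose_isoform,
    ejc_nmd_sensitive,
    expression_filter,
    heterozygosity_filter,
    locate_ptc,
    variant_consequence,
)
from mirsurv.synth import SENSE_CODONS

from conftest import TOY_UTR5, build_toy_transcript, variant_at as _variant_at


class TestConsequence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_aaa_to_taa_is_nonsense(self, strand):
        genome, t = build_toy_transcript(strand)
        # codon 6 of the toy CDS is AAA; A->T at its first base gives TAA
        tpos = t.cds_start + 3 * 6
        v = _variant_at(t, genome, tpos, "T")
        assert variant_consequence(t, genome, v) is Consequence.NONSENSE

    def test_native_stop_taa_to_tca_is_stop_loss(self, toy_plus):
        genome, t = toy_plus
        tpos = t.cds_end - 2   # middle base of the terminal TAA
        v = _variant_at(t, genome, tpos, "C")
        assert variant_consequence(t, genome, v) is Consequence.STOP_LOSS

    def test_fourfold_degenerate_third_position_is_synonymous(self, toy_plus):
        genome, t = toy_plus
        # codon 7 is CTG (Leu, 4-fold at position 3): CTG->CTC synonymous
        tpos = t.cds_start + 3 * 7 + 2
        v = _variant_at(t, genome, tpos, "C")
        assert variant_consequence(t, genome, v) is Consequence.SYNONYMOUS

    def test_utr_position_is_noncoding(self, toy_plus):
        genome, t = toy_plus
        v = _variant_at(t, genome, 2, "A" if t.spliced_sequence(genome)[2] != "A" else "T")
        assert variant_consequence(t, genome, v) is Consequence.NONCODING_OR_UTR

    def test_reference_mismatch_raises_with_position(self, toy_plus):
        genome, t = toy_plus
        gpos = t.transcript_to_genomic(t.cds_start)
        wrong_ref = "G" if genome.base(t.contig, gpos) != "G" else "C"
        alt = "T" if wrong_ref != "T" else "A"
        v = SnvRecord(t.contig, gpos, wrong_ref, alt)
        with pytest.raises(ReferenceMismatchError, match=str(gpos)):
            variant_consequence(t, genome, v)


class TestLocatePtc:
    def test_codon_index_arithmetic(self, toy_plus):
        genome, t = toy_plus
        tpos = t.cds_start + 3 * 6
        v = _variant_at(t, genome, tpos, "T")
        ci, interval = locate_ptc(t, genome, v)
        assert ci == 6
        assert interval == (t.cds_start + 18, t.cds_start + 21)

    def test_non_nonsense_variant_rejected(self, toy_plus):
        genome, t = toy_plus
        v = _variant_at(t, genome, t.cds_start + 3 * 7 + 2, "C")  # synonymous
        with pytest.raises(ValueError, match="not nonsense"):
            locate_ptc(t, genome, v)


class TestEjcRule:
    def _annotation_with_junction_distance(self, d: int):
        """Toy gene whose PTC codon (index 6) ends exactly d nt before the
        final junction."""
        codon_end = len(TOY_UTR5) + 3 * 7
        genome, t = build_toy_transcript("+", junctions=(codon_end + d,),
                                         intron_lengths=(12,), utr3="TTCC" * 15)
        v = _variant_at(t, genome, len(TOY_UTR5) + 18, "T")
        return annotate_ptc(t, genome, v, ThresholdsConfig())

    @pytest.mark.parametrize(
        "distance,expected",
        [(11, False), (49, False), (50, True), (51, True)],
    )
    def test_boundary(self, distance, expected):
        a = self._annotation_with_junction_distance(distance)
        assert a.junction_distance_nt == distance
        assert a.ejc_nmd_sensitive is expected

    def test_strict_reading_excludes_exactly_50(self):
        codon_end = len(TOY_UTR5) + 21
        genome, t = build_toy_transcript("+", junctions=(codon_end + 50,),
                                         intron_lengths=(12,), utr3="TTCC" * 15)
        v = _variant_at(t, genome, len(TOY_UTR5) + 18, "T")
        strict = ThresholdsConfig(ejc_inclusive=False)
        a = annotate_ptc(t, genome, v, strict)
        assert a.junction_distance_nt == 50 and not a.ejc_nmd_sensitive

    def test_ptc_in_last_exon_not_sensitive(self):
        genome, t = build_toy_transcript("+", junctions=(15,), intron_lengths=(12,))
        v = _variant_at(t, genome, len(TOY_UTR5) + 18, "T")
        a = annotate_ptc(t, genome, v, ThresholdsConfig())
        assert a.junction_distance_nt is None and not a.ejc_nmd_sensitive

    def test_single_exon_not_sensitive(self):
        genome, t = build_toy_transcript("+", junctions=(), intron_lengths=())
        v = _variant_at(t, genome, len(TOY_UTR5) + 18, "T")
        a = annotate_ptc(t, genome, v, ThresholdsConfig())
        assert a.junction_distance_nt is None and not a.ejc_nmd_sensitive

    def test_monotonic_moving_ptc_toward_junction_never_gains_sensitivity(self, cfg):
        genome, t = build_toy_transcript("+")
        flags = []
        for ci in range(1, 19):
            codon_iv = (t.cds_start + 3 * ci, t.cds_start + 3 * ci + 3)
            flags.append(ejc_nmd_sensitive(codon_iv, t, cfg)[0])
        # once False (closer to the junction), never True again
        assert all(not (not a and b) for a, b in zip(flags, flags[1:]))


class TestPtcStop:
    def test_twenty_codon_cds_ptc_at_codon_5(self, toy_plus, cfg):
        genome, t = toy_plus
        # brute-force oracle: 3 x (native stop index - ptc index - 1)
        v = _variant_at(t, genome, t.cds_start + 3 * 6, "T")
        a = annotate_ptc(t, genome, v, cfg)
        assert a.ptc_stop_length_nt == 3 * (19 - 6 - 1) == 36
        spliced = t.spliced_sequence(genome)
        assert a.ptc_stop_sequence == spliced[a.codon_interval[1]:t.cds_end - 3]

    def test_ptc_immediately_before_native_stop_empty_region(self, cfg):
        genome, t = build_toy_transcript("+")
        # codon 18 is GTG: G->T at first base gives TTG (not stop); use
        # position 2: GTG -> TGA? build directly: G T G: change pos1 G->T
        # gives TTG; the toy's codon 9 TCA->TGA works: pos 1 C->G
        v = _variant_at(t, genome, t.cds_start + 3 * 9 + 1, "G")
        a = annotate_ptc(t, genome, v, cfg)
        assert a.codon_index == 9
        assert a.ptc_stop_length_nt == 3 * (19 - 9 - 1)

    def test_interval_lies_between_codon_and_native_stop(self, toy_plus, cfg):
        genome, t = toy_plus
        v = _variant_at(t, genome, t.cds_start + 18, "T")
        a = annotate_ptc(t, genome, v, cfg)
        assert a.ptc_stop_interval[0] == a.codon_interval[1]
        assert a.ptc_stop_interval[1] == t.cds_end - 3


class TestFilters:
    @pytest.mark.parametrize(
        "ptc,wt,expected",
        [(10, 10, True), (7, 10, True), (69, 100, False), (13, 10, True), (14, 10, False)],
    )
    def test_heterozygosity_boundaries(self, cfg, ptc, wt, expected):
        v = SnvRecord("c", 0, "A", "T", ptc, wt)
        assert heterozygosity_filter(v, cfg)[0] is expected

    def test_heterozygosity_zero_wt_and_missing_depths(self, cfg):
        ok, reason = heterozygosity_filter(SnvRecord("c", 0, "A", "T", 10, 0), cfg)
        assert not ok and "undefined" in reason
        ok, reason = heterozygosity_filter(SnvRecord("c", 0, "A", "T"), cfg)
        assert not ok and "unavailable" in reason

    @pytest.mark.parametrize("value,expected", [(0.0, False), (1.0, False), (10.0, True)])
    def test_expression_strictly_greater(self, cfg, value, expected):
        assert expression_filter(AbundanceRecord("g", value), cfg) is expected

    @pytest.mark.parametrize("length,expected", [(0, False), (400, False), (401, True), (738, True)])
    def test_candidate_length_strictly_greater_than_400(self, cfg, length, expected):
        class A:   # minimal stand-in carrying only the checked field
            ptc_stop_length_nt = length
        assert candidate_filter(A, cfg) is expected

    def test_choose_isoform_prefers_longest_ptc_stop(self, cfg):
        genome, t = build_toy_transcript("+")
        v6 = _variant_at(t, genome, t.cds_start + 18, "T")
        a_long = annotate_ptc(t, genome, v6, cfg)
        v9 = _variant_at(t, genome, t.cds_start + 28, "G")
        a_short = annotate_ptc(t, genome, v9, cfg)
        assert choose_isoform([a_short, a_long]) is a_long


class TestTranslationOracle:
    """PTC codon index and PTC-STOP sequence must agree with an independent
    codon-by-codon translation oracle on random transcripts."""

    @staticmethod
    def _oracle(spliced: str, cds_start: int, cds_end: int, tpos: int, alt: str):
        """Translate the mutated CDS; report the first stop introduced."""
        cds = list(spliced[cds_start:cds_end])
        cds[tpos - cds_start] = alt
        cds = "".join(cds)
        for i in range(0, len(cds) - 3, 3):   # exclude the native stop codon
            if cds[i:i + 3] in STOP_CODONS:
                return i // 3, cds[i + 3:len(cds) - 3]
        return None, None

    def test_random_transcripts(self, cfg):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(250):
            n_codons = int(rng.integers(10, 40))
            codons = ["ATG"] + [
                SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)
            ] + ["TAA"]
            cds = "".join(codons)
            utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 20))))
            utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 20))))
            mrna = utr5 + cds + utr3
            strand = "+" if rng.integers(0, 2) else "-"
            contig = mrna if strand == "+" else reverse_complement(mrna)
            genome = GenomeSequence({"c": contig})
            exons = ((0, len(mrna)),)
            t = TranscriptModel("t", "g", "c", strand, exons,
                                len(utr5), len(utr5) + len(cds))
            # random substitution inside the CDS (never in the native stop)
            tpos = int(rng.integers(len(utr5), len(utr5) + len(cds) - 3))
            current = mrna[tpos]
            alt = "ACGT".replace(current, "")[int(rng.integers(0, 3))]
            v = _variant_at(t, genome, tpos, alt)
            expected_ci, expected_seq = self._oracle(
                mrna, t.cds_start, t.cds_end, tpos, alt
            )
            cons = variant_consequence(t, genome, v)
            if cons is Consequence.NONSENSE:
                a = annotate_ptc(t, genome, v, cfg)
                # oracle's first stop must be the variant codon itself here,
                # since the reference CDS has no internal stops
                assert a.codon_index == expected_ci
                assert a.ptc_stop_sequence == expected_seq
                checked += 1
            else:
                assert expected_ci is None or cons is not Consequence.NONSENSE
        assert checked >= 5   # the sample must actually exercise nonsense calls
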
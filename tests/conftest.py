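"""Shared fixtures: hand-built toy transcripts and the default synthetic bundle."""

from __future__ import annotations

import pytest

from mirsurv.models import (
    GenomeSequence,
    SnvRecord,
    ThresholdsConfig,
    TranscriptModel,
    complement_base,
    reverse_complement,
)
from mirsurv.synth import generate_bundle


def variant_at(t: TranscriptModel, genome: GenomeSequence, tpos: int, new_base: str,
               ptc_reads: int = 10, wt_reads: int = 10) -> SnvRecord:
    """SNV changing the transcript-sense base at tpos to new_base."""
    gpos = t.transcript_to_genomic(tpos)
    ref = genome.base(t.contig, gpos)
    alt = new_base if t.strand == "+" else complement_base(new_base)
    return SnvRecord(t.contig, gpos, ref, alt, ptc_reads, wt_reads)


@pytest.fixture(scope="session")
def cfg() -> ThresholdsConfig:
    return ThresholdsConfig()


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(1)


# A 20-codon CDS used by several toy transcripts: ATG + 18 sense codons + TAA.
TOY_CDS = (
    "ATG" "GCA" "CAG" "CCT" "ATT" "GAA" "AAA" "CTG" "GGT" "TCA"
    "CAT" "AAC" "GAC" "GAG" "TTC" "CTC" "ATC" "AAG" "GTG" "TAA"
)
TOY_UTR5 = "GGCTAGCTAG"   # 10 nt
TOY_UTR3 = "TTCCTTCC"     # 8 nt
TOY_MRNA = TOY_UTR5 + TOY_CDS + TOY_UTR3   # 78 nt


def build_toy_transcript(strand: str, junctions: tuple[int, ...] = (25, 52),
                         intron_lengths: tuple[int, ...] = (12, 15),
                         utr3: str = TOY_UTR3):
    """Lay the toy mRNA (TOY_UTR5 + TOY_CDS + utr3) on a contig as a
    multi-exon gene.

    ``junctions`` are transcript positions; introns are GT..AG fillers.
    Returns (genome, transcript); the spliced sequence equals the mRNA by
    construction, which makes every coordinate assertion checkable by hand.
    """
    assert len(junctions) == len(intron_lengths)
    mrna = TOY_UTR5 + TOY_CDS + utr3
    bounds = (0,) + tuple(junctions) + (len(mrna),)
    pieces, exon_pre, pos = [], [], 0
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        pieces.append(mrna[a:b])
        exon_pre.append((pos, pos + b - a))
        pos += b - a
        if i < len(junctions):
            n = intron_lengths[i]
            intron = "GT" + "C" * (n - 4) + "AG"
            pieces.append(intron)
            pos += n
    pre = "".join(pieces)
    pad = "ACGT" * 5   # 20-nt left flank so exon coordinates are not trivial
    if strand == "+":
        contig_seq = pad + pre
        exons = tuple((20 + s, 20 + e) for s, e in exon_pre)
    else:
        contig_seq = pad + reverse_complement(pre)
        P = len(pre)
        exons = tuple((20 + P - e, 20 + P - s) for s, e in exon_pre)
    genome = GenomeSequence({"chrT": contig_seq})
    t = TranscriptModel(
        transcript_id=f"toy_{strand}", gene_id="toy", contig="chrT", strand=strand,
        exons=exons, cds_start=len(TOY_UTR5), cds_end=len(TOY_UTR5) + len(TOY_CDS),
    )
    t.validate_against(genome)
    assert t.spliced_sequence(genome) == mrna
    return genome, t


@pytest.fixture(scope="session")
def toy_plus():
    return build_toy_transcript("+")


@pytest.fixture(scope="session")
def toy_minus():
    return build_toy_transcript("-")
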
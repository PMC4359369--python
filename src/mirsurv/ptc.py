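"""Frame-aware SNV consequence calling, PTC location, the 50-nt EJC-NMD
boundary rule, PTC-STOP region extraction and the candidate filters.

A nonsense SNV redefines the downstream portion of the coding region as
3'UTR; the stretch between the PTC and the native stop codon is the
PTC-STOP region where unmasked miRNA-responsive elements act. A PTC at
least 50 nt upstream of the final exon-exon junction additionally triggers
EJC-dependent NMD; PTCs in the last exon (or in single-exon transcripts)
escape it and are candidates for miRNA-mediated surveillance only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .models import (
    AbundanceRecord,
    GenomeSequence,
    NotExonicError,
    STOP_CODONS,
    SnvRecord,
    ThresholdsConfig,
    TranscriptModel,
    complement_base,
)

_FORWARD_TABLE = standard_dna_table.forward_table


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return _FORWARD_TABLE[codon]


class Consequence(enum.Enum):
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONCODING_OR_UTR = "noncoding_or_utr"


class ReferenceMismatchError(ValueError):
    """VCF REF base disagrees with the genome sequence."""


@dataclass
class PtcAnnotation:
    """A PTC's codon index, junction distance, NMD class and PTC-STOP region.

    All intervals are transcript coordinates (0-based half-open).
    ``junction_distance_nt`` is None when no exon-exon junction lies
    downstream of the PTC codon (last-exon or single-exon PTC).
    """

    transcript_id: str
    variant: SnvRecord
    codon_index: int
    codon_interval: tuple[int, int]
    junction_distance_nt: int | None
    ejc_nmd_sensitive: bool
    ptc_stop_interval: tuple[int, int]
    ptc_stop_length_nt: int
    native_stop_interval: tuple[int, int]
    ptc_stop_sequence: str = ""

    def __post_init__(self) -> None:
        s, e = self.ptc_stop_interval
        assert self.ptc_stop_length_nt == e - s
        assert self.codon_interval[1] <= s
        assert e <= self.native_stop_interval[0]

    @property
    def nmd_class(self) -> str:
        """EJC-NMD-sensitive PTCs are also surveillance-sensitive (additive)."""
        if self.ejc_nmd_sensitive:
            return "ejc_nmd_and_mirna_surveillance"
        return "mirna_surveillance_only"


def transcript_alt_base(t: TranscriptModel, v: SnvRecord) -> str:
    return v.alt if t.strand == "+" else complement_base(v.alt)


def variant_consequence(
    t: TranscriptModel, genome: GenomeSequence, v: SnvRecord
) -> Consequence:
    """Classify an SNV against one transcript by codon substitution."""
    if v.contig != t.contig:
        raise ValueError(
            f"variant {v.key} is on {v.contig}, transcript {t.transcript_id} "
            f"on {t.contig}"
        )
    genome_ref = genome.base(v.contig, v.pos)
    if genome_ref != v.ref:
        raise ReferenceMismatchError(
            f"variant {v.key}: genome has {genome_ref!r} at {v.contig}:{v.pos}"
        )
    try:
        tpos = t.genomic_to_transcript(v.pos)
    except NotExonicError:
        return Consequence.NONCODING_OR_UTR
    if not t.cds_start <= tpos < t.cds_end:
        return Consequence.NONCODING_OR_UTR

    spliced = t.spliced_sequence(genome)
    ci = (tpos - t.cds_start) // 3
    codon_start = t.cds_start + 3 * ci
    ref_codon = spliced[codon_start:codon_start + 3]
    offset = tpos - codon_start
    alt_codon = ref_codon[:offset] + transcript_alt_base(t, v) + ref_codon[offset + 1:]

    ref_stop, alt_stop = ref_codon in STOP_CODONS, alt_codon in STOP_CODONS
    if ref_stop and not alt_stop:
        return Consequence.STOP_LOSS
    if alt_stop and not ref_stop:
        return Consequence.NONSENSE
    if translate_codon(ref_codon) == translate_codon(alt_codon):
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE


def locate_ptc(
    t: TranscriptModel, genome: GenomeSequence, v: SnvRecord
) -> tuple[int, tuple[int, int]]:
    """Codon index and transcript-coordinate codon interval of a nonsense SNV."""
    if variant_consequence(t, genome, v) is not Consequence.NONSENSE:
        raise ValueError(f"variant {v.key} is not nonsense in {t.transcript_id}")
    tpos = t.genomic_to_transcript(v.pos)
    ci = (tpos - t.cds_start) // 3
    start = t.cds_start + 3 * ci
    return ci, (start, start + 3)


def ejc_nmd_sensitive(
    codon_interval: tuple[int, int], t: TranscriptModel, cfg: ThresholdsConfig
) -> tuple[bool, int | None]:
    """Apply the 50-nt boundary rule.

    The junction distance counts the transcript nucleotides from the base
    immediately after the PTC codon's last base up to the final exon-exon
    junction. Returns (sensitive, distance); distance is None when the PTC
    codon lies in the last exon or the transcript has a single exon.
    """
    junction = t.last_junction
    codon_end = codon_interval[1]
    if junction is None or codon_end > junction:
        return False, None
    distance = junction - codon_end
    if cfg.ejc_inclusive:
        return distance >= cfg.ejc_min_distance_nt, distance
    return distance > cfg.ejc_min_distance_nt, distance


def extract_ptc_stop(
    codon_interval: tuple[int, int], t: TranscriptModel, genome: GenomeSequence
) -> tuple[tuple[int, int], str]:
    """PTC-STOP interval [first nt after the PTC codon, native stop) + sequence."""
    native_stop_start = t.cds_end - 3
    start = codon_interval[1]
    if start >= native_stop_start:
        return (start, start), ""
    interval = (start, native_stop_start)
    seq = t.spliced_sequence(genome)[start:native_stop_start]
    return interval, seq


def annotate_ptc(
    t: TranscriptModel, genome: GenomeSequence, v: SnvRecord, cfg: ThresholdsConfig
) -> PtcAnnotation:
    """Full PTC annotation for a nonsense variant on one transcript."""
    ci, codon_iv = locate_ptc(t, genome, v)
    sensitive, distance = ejc_nmd_sensitive(codon_iv, t, cfg)
    stop_iv, stop_seq = extract_ptc_stop(codon_iv, t, genome)
    return PtcAnnotation(
        transcript_id=t.transcript_id,
        variant=v,
        codon_index=ci,
        codon_interval=codon_iv,
        junction_distance_nt=distance,
        ejc_nmd_sensitive=sensitive,
        ptc_stop_interval=stop_iv,
        ptc_stop_length_nt=stop_iv[1] - stop_iv[0],
        native_stop_interval=(t.cds_end - 3, t.cds_end),
        ptc_stop_sequence=stop_seq,
    )


def heterozygosity_filter(v: SnvRecord, cfg: ThresholdsConfig) -> tuple[bool, str]:
    """Pass iff het_ratio_low <= PTC/WT reads <= het_ratio_high (inclusive)."""
    if v.ptc_allele_reads is None or v.wt_allele_reads is None:
        return False, "depths unavailable"
    if v.wt_allele_reads == 0:
        return False, "ratio undefined"
    ratio = v.ptc_allele_reads / v.wt_allele_reads
    if cfg.het_ratio_low <= ratio <= cfg.het_ratio_high:
        return True, f"ratio {ratio:g}"
    return False, f"ratio {ratio:g} outside [{cfg.het_ratio_low}, {cfg.het_ratio_high}]"


def expression_filter(rec: AbundanceRecord, cfg: ThresholdsConfig) -> bool:
    """Pass iff abundance strictly exceeds expression_min."""
    return rec.abundance > cfg.expression_min


def candidate_filter(a: PtcAnnotation, cfg: ThresholdsConfig) -> bool:
    """Pass iff the PTC-STOP region is strictly longer than the threshold."""
    return a.ptc_stop_length_nt > cfg.min_ptc_stop_len_nt


def choose_isoform(annotations: list[PtcAnnotation]) -> PtcAnnotation:
    """Among isoforms carrying the same variant, keep the longest PTC-STOP
    region (ties broken by transcript id for determinism)."""
    if not annotations:
        raise ValueError("no annotations to choose from")
    return max(annotations, key=lambda a: (a.ptc_stop_length_nt, a.transcript_id))
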
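"""Domain model: genomes, transcripts, variants, miRNAs, intervals, thresholds.

All coordinates are 0-based, half-open. Transcript coordinates run 5'->3' in
mRNA orientation regardless of genomic strand. The CDS interval of a
transcript INCLUDES the native stop codon (``cds_end`` is the position just
past the stop), which keeps PTC-STOP arithmetic explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (ACGTN)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def rna_reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (ACGUN)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_DNA_COMPLEMENT)


class ValidationError(ValueError):
    """Raised when a record violates a model invariant."""


@dataclass
class GenomeSequence:
    """A set of named DNA contigs (uppercase ACGTN)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValidationError(f"contig {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def base(self, contig: str, pos: int) -> str:
        seq = self._contig(contig)
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
        return seq[pos]

    def fragment(self, contig: str, start: int, end: int) -> str:
        seq = self._contig(contig)
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"interval [{start}, {end}) outside contig {contig!r} (length {len(seq)})"
            )
        return seq[start:end]

    def _contig(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None


class NotExonicError(ValueError):
    """A genomic position does not fall inside any exon of the transcript."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of a transcript on a genome.

    ``exons`` are genomic intervals ordered 5'->3' in transcript orientation:
    ascending genomic start on the plus strand, descending on the minus
    strand. ``cds_start``/``cds_end`` are transcript coordinates and include
    the native stop codon.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: empty exon collection")
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty/inverted exon [{s}, {e})")
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if e1 > s2:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        expected = by_start if self.strand == "+" else by_start[::-1]
        if tuple(expected) != self.exons:
            raise ValidationError(
                f"{self.transcript_id}: exons not ordered 5'->3' in transcript orientation"
            )
        if not 0 <= self.cds_start < self.cds_end <= self.length:
            raise ValidationError(f"{self.transcript_id}: CDS interval outside transcript")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def last_junction(self) -> int | None:
        """Transcript position of the final exon-exon junction, or None."""
        if len(self.exons) == 1:
            return None
        return self.length - self.exon_lengths[-1]

    def genomic_to_transcript(self, gpos: int) -> int:
        acc = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return acc + (gpos - s if self.strand == "+" else e - 1 - gpos)
            acc += e - s
        raise NotExonicError(
            f"position {gpos} is not exonic in transcript {self.transcript_id}"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        if tpos < 0:
            raise IndexError(f"negative transcript position {tpos}")
        acc = 0
        for s, e in self.exons:
            n = e - s
            if tpos < acc + n:
                off = tpos - acc
                return s + off if self.strand == "+" else e - 1 - off
            acc += n
        raise IndexError(
            f"transcript position {tpos} outside transcript {self.transcript_id} "
            f"(length {self.length})"
        )

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        pieces = []
        for s, e in self.exons:
            frag = genome.fragment(self.contig, s, e)
            pieces.append(frag if self.strand == "+" else reverse_complement(frag))
        return "".join(pieces)

    def intron_genomic(self, index: int) -> tuple[int, int]:
        """Genomic interval of intron ``index`` (transcript orientation)."""
        if not 0 <= index < self.n_introns:
            raise IndexError(
                f"intron index {index} out of range for {self.transcript_id} "
                f"({self.n_introns} introns)"
            )
        a, b = self.exons[index], self.exons[index + 1]
        return (a[1], b[0]) if self.strand == "+" else (b[1], a[0])

    def intron_sequence(self, genome: GenomeSequence, index: int) -> str:
        """Intron sequence in transcript orientation (donor GT ... acceptor AG)."""
        s, e = self.intron_genomic(index)
        frag = genome.fragment(self.contig, s, e)
        return frag if self.strand == "+" else reverse_complement(frag)

    def coding_sequence(self, genome: GenomeSequence) -> str:
        return self.spliced_sequence(genome)[self.cds_start:self.cds_end]

    def validate_against(self, genome: GenomeSequence) -> None:
        cds = self.coding_sequence(genome)
        if not cds.startswith(START_CODON):
            raise ValidationError(f"{self.transcript_id}: CDS does not start with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValidationError(f"{self.transcript_id}: CDS does not end with a stop codon")


@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide variant with PTC/WT per-allele read depths."""

    contig: str
    pos: int
    ref: str
    alt: str
    ptc_allele_reads: int | None = None
    wt_allele_reads: int | None = None
    variant_id: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"SNV at {self.contig}:{self.pos}: ref equals alt")
        for b in (self.ref, self.alt):
            if len(b) != 1 or b not in "ACGT":
                raise ValidationError(
                    f"SNV at {self.contig}:{self.pos}: alleles must be single ACGT bases"
                )
        for d in (self.ptc_allele_reads, self.wt_allele_reads):
            if d is not None and d < 0:
                raise ValidationError(f"SNV at {self.contig}:{self.pos}: negative read depth")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA (RNA alphabet, 5'->3') with an abundance count."""

    mirna_id: str
    sequence: str
    abundance: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(f"{self.mirna_id}: non-ACGUN characters {sorted(bad)}")
        if len(self.sequence) < 7:
            raise ValidationError(
                f"{self.mirna_id}: mature sequence shorter than 7 nt (no 2-7 seed)"
            )
        if self.abundance < 0:
            raise ValidationError(f"{self.mirna_id}: negative abundance")


@dataclass(frozen=True)
class ClipInterval:
    """An Ago-CLIP binding footprint (BED6 semantics)."""

    contig: str
    start: int
    end: int
    strand: str
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"CLIP interval {self.name}: start >= end")
        if self.strand not in "+-":
            raise ValidationError(f"CLIP interval {self.name}: strand must be + or -")


@dataclass(frozen=True)
class AbundanceRecord:
    feature_id: str
    abundance: float

    def __post_init__(self) -> None:
        if not (self.abundance >= 0 and self.abundance == self.abundance):
            raise ValidationError(f"{self.feature_id}: abundance must be finite and >= 0")


@dataclass(frozen=True)
class RetentionRecord:
    transcript_id: str
    intron_index: int
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError(
                f"{self.transcript_id} intron {self.intron_index}: "
                f"retention level {self.level} outside [0, 1]"
            )
        if self.intron_index < 0:
            raise ValidationError(f"{self.transcript_id}: negative intron index")


@dataclass
class ThresholdsConfig:
    """The pipeline's numeric rules as one explicit record.

    ejc_min_distance_nt
        A PTC at least this many nt upstream of the final exon-exon junction
        triggers EJC-NMD (inclusive by default; ``ejc_inclusive`` switches to
        a strict reading).
    mire_min_distance_nt
        A seed-match site must sit at least this many nt downstream of the
        PTC to be functional.
    het_ratio_low / het_ratio_high
        Inclusive bounds on the PTC/WT allele read ratio for a site to be
        called heterozygous.
    retention_min_level
        Retained-intron isoforms need a retention level strictly above this.
    top_n_mirnas
        Number of most-abundant miRNAs used for miRE prediction.
    min_ptc_stop_len_nt
        Candidates need a PTC-STOP region strictly longer than this.
    expression_min
        Strict lower bound on abundance for "actively expressed".
    """

    ejc_min_distance_nt: int = 50
    ejc_inclusive: bool = True
    mire_min_distance_nt: int = 10
    het_ratio_low: float = 0.7
    het_ratio_high: float = 1.3
    retention_min_level: float = 0.05
    top_n_mirnas: int = 150
    min_ptc_stop_len_nt: int = 400
    expression_min: float = 1.0
    ad_order: str = "ref_first"

    def __post_init__(self) -> None:
        numeric = (
            self.ejc_min_distance_nt,
            self.mire_min_distance_nt,
            self.het_ratio_low,
            self.het_ratio_high,
            self.retention_min_level,
            self.top_n_mirnas,
            self.min_ptc_stop_len_nt,
            self.expression_min,
        )
        if any(x < 0 for x in numeric):
            raise ValidationError("all thresholds must be >= 0")
        if self.het_ratio_low > self.het_ratio_high:
            raise ValidationError("het_ratio_low must be <= het_ratio_high")
        if self.ad_order not in ("ref_first", "alt_first"):
            raise ValidationError("ad_order must be 'ref_first' or 'alt_first'")
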
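"""Reporter-construct engineering: in-frame element insertion, PTC
introduction, synonymous seed disruption, compensatory miRNA mimics,
5'UTR hairpin insertion and splice-site disruption for intron retention.

A construct is held as mature-mRNA parts (5'UTR, CDS including its stop
codon, 3'UTR) plus introns anchored at mature-coordinate junctions; the
pre-mRNA and retained-intron isoform sequences are derived views. Every
edit is logged, and constructs can be lowered to a toy genome + transcript
model so the annotation/scanning pipeline can run on them directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .models import (
    GenomeSequence,
    MiRNA,
    STOP_CODONS,
    TranscriptModel,
    reverse_complement,
)
from .ptc import translate_codon

BASES = "ACGT"

#: The stable hairpin placed in the 5'UTR to block translation initiation --
#: a perfect 40-nt inverted repeat.
HAIRPIN_40NT = "GGGGCGCGTGGTGGCGGCTGCAGCCGCCACCACGCGCCCC"

#: let-7a miRE cassette (from human LIN-28) used by the in-frame insertion
#: examples; its single seed match sits at offset 16.
LET7A_MIRE = "GCACAGCCTATTGAACTACCTCA"


class DesignError(ValueError):
    pass


class NoStopWithinTwoEditsError(DesignError):
    def __init__(self, codon: str, min_edits: int):
        self.codon = codon
        self.min_edits = min_edits
        super().__init__(
            f"codon {codon} cannot become a stop with <=2 substitutions "
            f"(minimum found by enumeration: {min_edits})"
        )


@dataclass
class Intron:
    position: int          # junction offset in mature-mRNA coordinates
    sequence: str          # pre-mRNA sense (donor GT ... acceptor AG)
    retained: bool = False


@dataclass
class ReporterConstruct:
    name: str
    utr5: str
    cds: str               # includes the native stop codon
    utr3: str
    introns: list[Intron] = field(default_factory=list)
    ptc_codons: list[int] = field(default_factory=list)
    features: list[tuple[int, int, str]] = field(default_factory=list)
    edit_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived views ----------------------------------------------------

    @property
    def mature_sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_start(self) -> int:
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)

    def pre_mrna_sequence(self) -> str:
        """Mature sequence with every intron inserted at its junction."""
        return self._with_introns(self.introns)

    def retained_sequence(self) -> str:
        """Mature sequence with only retained-flagged introns inserted."""
        return self._with_introns([i for i in self.introns if i.retained])

    def _with_introns(self, introns: list[Intron]) -> str:
        seq = self.mature_sequence
        out, prev = [], 0
        for intron in sorted(introns, key=lambda i: i.position):
            out.append(seq[prev:intron.position])
            out.append(intron.sequence)
            prev = intron.position
        out.append(seq[prev:])
        return "".join(out)

    def codon(self, index: int) -> str:
        return self.cds[3 * index:3 * index + 3]

    def translate(self) -> str:
        """Translation of the CDS up to (not including) its terminal stop."""
        return "".join(
            translate_codon(self.cds[i:i + 3]) for i in range(0, len(self.cds) - 3, 3)
        )

    def validate(self) -> None:
        if len(self.cds) % 3 != 0:
            raise DesignError(f"{self.name}: CDS length not divisible by 3")
        if self.cds[-3:] not in STOP_CODONS:
            raise DesignError(f"{self.name}: CDS does not end with a stop codon")
        n = len(self.mature_sequence)
        for s, e, label in self.features:
            if not 0 <= s <= e <= n:
                raise DesignError(f"{self.name}: feature {label} outside sequence")
        internal = [
            i for i in range(len(self.cds) // 3 - 1)
            if self.codon(i) in STOP_CODONS and i > 0
        ]
        unlogged = [i for i in internal if i not in self.ptc_codons]
        if unlogged:
            raise DesignError(
                f"{self.name}: internal stop at codon(s) {unlogged} without a PTC edit"
            )

    # ---- pipeline bridge --------------------------------------------------

    def as_transcript(
        self, contig: str | None = None
    ) -> tuple[GenomeSequence, TranscriptModel]:
        """Lower to a single-contig toy genome (the pre-mRNA, plus strand)
        and a TranscriptModel whose introns are the construct's introns."""
        contig = contig or self.name
        genome = GenomeSequence({contig: self.pre_mrna_sequence()})
        exons, prev_mature, prev_pre = [], 0, 0
        for intron in sorted(self.introns, key=lambda i: i.position):
            exon_len = intron.position - prev_mature
            exons.append((prev_pre, prev_pre + exon_len))
            prev_pre += exon_len + len(intron.sequence)
            prev_mature = intron.position
        exons.append((prev_pre, prev_pre + len(self.mature_sequence) - prev_mature))
        model = TranscriptModel(
            transcript_id=self.name, gene_id=self.name, contig=contig, strand="+",
            exons=tuple(exons), cds_start=self.cds_start, cds_end=self.cds_end,
        )
        return genome, model


# -------------------------------------------------------------- operations

def _pad_to_frame(element: str) -> str:
    """Pad a non-3n element at its 3' end: A's unless that creates an
    in-frame stop in the padded block, else C's."""
    pad = (-len(element)) % 3
    if pad == 0:
        return element
    for base in ("A", "C"):
        candidate = element + base * pad
        if candidate[-3:] not in STOP_CODONS:
            return candidate
    raise DesignError("padding impossible without creating a stop")  # unreachable


def insert_in_frame(
    c: ReporterConstruct, element: str, codon_index: int
) -> ReporterConstruct:
    """Insert an element at a codon boundary, 3'-padded to preserve frame."""
    if not 0 <= codon_index <= len(c.cds) // 3 - 1:
        raise DesignError(f"codon index {codon_index} outside CDS")
    block = _pad_to_frame(element)
    pos = 3 * codon_index
    new = _clone(
        c,
        cds=c.cds[:pos] + block + c.cds[pos:],
        shift_at=c.cds_start + pos,
        shift_by=len(block),
    )
    mstart = new.cds_start + pos
    new.features.append((mstart, mstart + len(block), "inserted_element"))
    new.ptc_codons = [i if i < codon_index else i + len(block) // 3 for i in c.ptc_codons]
    new.edit_log.append(
        f"insert_in_frame: {len(element)} nt (+{len(block) - len(element)} pad) "
        f"at codon {codon_index}"
    )
    new.validate()
    return new


def minimal_stop_edit(codon: str) -> tuple[str, int]:
    """Minimal-substitution path from ``codon`` to a stop codon.

    Enumerates 1- then 2-base substitutions, positions left to right and
    bases in A<C<G<T order; the first stop reached wins. Raises
    NoStopWithinTwoEditsError (carrying the enumerated minimum, possibly 3)
    when no 1- or 2-edit path exists.
    """
    if codon in STOP_CODONS:
        raise DesignError(f"codon {codon} is already a stop")
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                return mutant, 1
    for p1, p2 in itertools.combinations(range(3), 2):
        for b1 in BASES:
            if b1 == codon[p1]:
                continue
            for b2 in BASES:
                if b2 == codon[p2]:
                    continue
                mutant = list(codon)
                mutant[p1], mutant[p2] = b1, b2
                mutant = "".join(mutant)
                if mutant in STOP_CODONS:
                    return mutant, 2
    # Exhaustive check: any stop is reachable in <=3 edits.
    min_edits = min(
        sum(a != b for a, b in zip(codon, stop)) for stop in STOP_CODONS
    )
    raise NoStopWithinTwoEditsError(codon, min_edits)


def introduce_ptc(c: ReporterConstruct, codon_index: int) -> ReporterConstruct:
    """Convert a CDS codon to a stop by the minimal number of substitutions."""
    codon = c.codon(codon_index)
    if not codon:
        raise DesignError(f"codon index {codon_index} outside CDS")
    stop, n_edits = minimal_stop_edit(codon)
    pos = 3 * codon_index
    new = _clone(c, cds=c.cds[:pos] + stop + c.cds[pos + 3:])
    new.ptc_codons = sorted(set(c.ptc_codons) | {codon_index})
    mstart = new.cds_start + pos
    new.features.append((mstart, mstart + 3, "PTC"))
    new.edit_log.append(
        f"introduce_ptc: codon {codon_index} {codon}->{stop} ({n_edits} substitution(s))"
    )
    new.validate()
    return new


def disrupt_seed_synonymously(
    c: ReporterConstruct, seed_start_in_cds: int, motif: str
) -> ReporterConstruct | None:
    """Two-base substitution inside a 6-mer seed match that leaves the
    translation unchanged and abolishes the match, or None if no solution.

    All C(6,2) x 9 substitution pairs are enumerated; solutions confined to
    a single codon are preferred; ordering is deterministic.
    """
    if c.cds[seed_start_in_cds:seed_start_in_cds + 6] != motif:
        raise DesignError("seed motif not present at the stated CDS offset")
    solutions = []
    for p1, p2 in itertools.combinations(range(6), 2):
        i1, i2 = seed_start_in_cds + p1, seed_start_in_cds + p2
        for b1 in BASES:
            if b1 == c.cds[i1]:
                continue
            for b2 in BASES:
                if b2 == c.cds[i2]:
                    continue
                cds = list(c.cds)
                cds[i1], cds[i2] = b1, b2
                cds = "".join(cds)
                if not _same_translation(c.cds, cds, (i1, i2)):
                    continue
                # the match must be gone, including shifted re-creations
                window_lo = max(0, seed_start_in_cds - 5)
                window = cds[window_lo:seed_start_in_cds + 11]
                if motif in window:
                    continue
                single_codon = i1 // 3 == i2 // 3
                solutions.append((not single_codon, p1, p2, b1, b2, cds))
    if not solutions:
        return None
    *_, cds = sorted(solutions)[0]
    new = _clone(c, cds=cds)
    new.edit_log.append(
        f"disrupt_seed_synonymously: 2-nt synonymous change in seed at CDS "
        f"offset {seed_start_in_cds}"
    )
    new.validate()
    return new


def _same_translation(old_cds: str, new_cds: str, changed: tuple[int, ...]) -> bool:
    for ci in {i // 3 for i in changed}:
        a, b = old_cds[3 * ci:3 * ci + 3], new_cds[3 * ci:3 * ci + 3]
        if (a in STOP_CODONS) != (b in STOP_CODONS):
            return False
        if a in STOP_CODONS:
            continue
        if translate_codon(a) != translate_codon(b):
            return False
    return True


def compensatory_mimic(m: MiRNA, mutant_motif: str) -> MiRNA:
    """miRNA mimic whose 2-7 seed restores complementarity with a mutated
    seed-match motif (motif given in mRNA-sense DNA)."""
    if len(mutant_motif) != 6 or not set(mutant_motif) <= set(BASES):
        raise DesignError("mutant motif must be a 6-mer in ACGT")
    seed_rna = reverse_complement(mutant_motif).replace("T", "U")
    return MiRNA(
        mirna_id=f"{m.mirna_id}-mimic",
        sequence=m.sequence[0] + seed_rna + m.sequence[7:],
        abundance=m.abundance,
    )


def add_hairpin(
    c: ReporterConstruct,
    hairpin: str = HAIRPIN_40NT,
    distance_upstream_of_start: int = 29,
) -> ReporterConstruct:
    """Insert a hairpin so its 3' end sits ``distance_upstream_of_start`` nt
    upstream of the initiation codon."""
    idx = len(c.utr5) - distance_upstream_of_start
    if idx < 0:
        raise DesignError(
            f"5'UTR ({len(c.utr5)} nt) too short for a hairpin "
            f"{distance_upstream_of_start} nt upstream of ATG"
        )
    new = _clone(
        c, utr5=c.utr5[:idx] + hairpin + c.utr5[idx:],
        shift_at=idx, shift_by=len(hairpin),
    )
    new.features.append((idx, idx + len(hairpin), "hairpin"))
    new.edit_log.append(
        f"add_hairpin: {len(hairpin)} nt, 3' end {distance_upstream_of_start} nt "
        f"upstream of ATG"
    )
    new.validate()
    return new


def disable_splice_sites(c: ReporterConstruct, intron_index: int) -> ReporterConstruct:
    """Mutate 2 nt of the donor and 3 nt of the acceptor of one intron
    (each to its complement) and mark the intron retained."""
    if not 0 <= intron_index < len(c.introns):
        raise DesignError(f"no intron with index {intron_index}")
    intron = c.introns[intron_index]
    if len(intron.sequence) < 5:
        raise DesignError(f"intron {intron_index} shorter than 5 nt")
    s = intron.sequence
    mutated = (
        _complement2(s[:2]) + s[2:-3] + _complement2(s[-3:])
    )
    introns = [
        Intron(i.position, mutated if k == intron_index else i.sequence,
               retained=(k == intron_index) or i.retained)
        for k, i in enumerate(c.introns)
    ]
    new = _clone(c, introns=introns)
    new.edit_log.append(
        f"disable_splice_sites: intron {intron_index} donor {s[:2]}->{mutated[:2]}, "
        f"acceptor {s[-3:]}->{mutated[-3:]}; intron marked retained"
    )
    new.validate()
    return new


def _complement2(seq: str) -> str:
    return "".join(reverse_complement(b) for b in seq)


def _clone(
    c: ReporterConstruct,
    *,
    utr5: str | None = None,
    cds: str | None = None,
    utr3: str | None = None,
    introns: list[Intron] | None = None,
    shift_at: int | None = None,
    shift_by: int = 0,
) -> ReporterConstruct:
    """Copy a construct, optionally shifting mature-coordinate anchors for
    an insertion at ``shift_at`` of ``shift_by`` bases."""

    def shift(x: int) -> int:
        return x + shift_by if shift_at is not None and x >= shift_at else x

    new = ReporterConstruct.__new__(ReporterConstruct)
    new.name = c.name
    new.utr5 = c.utr5 if utr5 is None else utr5
    new.cds = c.cds if cds is None else cds
    new.utr3 = c.utr3 if utr3 is None else utr3
    new.introns = (
        [Intron(shift(i.position), i.sequence, i.retained) for i in c.introns]
        if introns is None else list(introns)
    )
    new.ptc_codons = list(c.ptc_codons)
    new.features = [(shift(s), shift(e), label) for s, e, label in c.features]
    new.edit_log = list(c.edit_log)
    return new
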
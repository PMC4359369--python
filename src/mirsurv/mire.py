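"""Perfect 2-7 seed-match miRE scanning with the 10-nt downstream rule.

A miRE is called wherever the reverse complement of miRNA nucleotides 2-7
(the seed) occurs verbatim in the mRNA sense strand -- a pure 6-mer match,
no wobble pairing, no 7mer-m8/8mer classes and no 3'-supplementary pairing.
A site is functional only when it lies in the redefined 3'UTR (the PTC-STOP
region, or the annotated 3'UTR) at least ``mire_min_distance_nt`` (default
10) nucleotides downstream of the PTC; sites upstream of the PTC stay
masked by translating ribosomes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .models import (
    GenomeSequence,
    MiRNA,
    ThresholdsConfig,
    TranscriptModel,
    rna_reverse_complement,
)
from .ptc import PtcAnnotation

SEED_LENGTH = 6


@dataclass(frozen=True)
class Seed:
    """6-mer match motif (DNA, mRNA sense) for one miRNA's 2-7 seed."""

    mirna_id: str
    motif: str

    def __post_init__(self) -> None:
        assert len(self.motif) == SEED_LENGTH and set(self.motif) <= set("ACGT")


class Region(enum.Enum):
    PTC_STOP = "PTC_STOP"
    THREE_PRIME_UTR = "THREE_PRIME_UTR"
    ORF_UPSTREAM_OF_PTC = "ORF_UPSTREAM_OF_PTC"


@dataclass(frozen=True)
class MireSite:
    transcript_id: str
    mirna_id: str
    start: int                 # transcript coords, 6-nt match
    end: int
    distance_from_ptc_nt: int  # nt strictly between PTC codon end and match start
    region: Region
    functional: bool


def seed_of(m: MiRNA) -> Seed:
    """Reverse complement of miRNA positions 2-7, written 5'->3' in DNA."""
    if len(m.sequence) < 7:
        raise ValueError(f"{m.mirna_id}: sequence shorter than 7 nt")
    seed_rna = m.sequence[1:7]
    motif = rna_reverse_complement(seed_rna).replace("U", "T")
    return Seed(m.mirna_id, motif)


def seed_match_sites(seq: str, m: MiRNA) -> list[int]:
    """All 0-based offsets of the perfect seed match, overlapping included."""
    motif = seed_of(m).motif
    offsets = []
    i = seq.find(motif)
    while i != -1:
        offsets.append(i)
        i = seq.find(motif, i + 1)
    return offsets


def functional_mires(
    a: PtcAnnotation,
    offsets: list[int],
    mirna_id: str,
    cfg: ThresholdsConfig,
    *,
    require_fully_inside: bool = True,
) -> list[MireSite]:
    """Label seed-match offsets (transcript coordinates) and gate by distance.

    Distance is the number of nucleotides strictly between the PTC codon's
    last base and the match's first base (negative for upstream sites). With
    ``require_fully_inside`` (default) a match overlapping the native stop
    codon is kept but never functional.
    """
    codon_end = a.codon_interval[1]
    stop_s, stop_e = a.ptc_stop_interval
    native_start = a.native_stop_interval[0]
    sites = []
    for off in offsets:
        end = off + SEED_LENGTH
        distance = off - codon_end
        if off < codon_end:
            region = Region.ORF_UPSTREAM_OF_PTC
            functional = False
        elif off >= a.native_stop_interval[1]:
            region = Region.THREE_PRIME_UTR
            functional = distance >= cfg.mire_min_distance_nt
        else:
            region = Region.PTC_STOP
            inside = stop_s <= off and end <= stop_e
            ok = inside or (not require_fully_inside and off < native_start)
            functional = ok and distance >= cfg.mire_min_distance_nt
        sites.append(
            MireSite(a.transcript_id, mirna_id, off, end, distance, region, functional)
        )
    return sites


def select_top_mirnas(mirnas: list[MiRNA], cfg: ThresholdsConfig) -> list[MiRNA]:
    """The top_n_mirnas highest-abundance miRNAs; ties at the cutoff broken
    by lexicographic id; all returned if fewer than N supplied."""
    ranked = sorted(mirnas, key=lambda m: (-m.abundance, m.mirna_id))
    return ranked[:cfg.top_n_mirnas]


def scan_transcriptome(
    annotations: list[PtcAnnotation],
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
    mirnas: list[MiRNA],
    cfg: ThresholdsConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every annotated transcript with the top-N miRNAs.

    Returns (sites, summary): one row per seed-match site, and a
    per-transcript summary with functional-site and distinct-miRNA counts.
    """
    selected = select_top_mirnas(mirnas, cfg)
    rows = []
    for a in annotations:
        t = transcripts[a.transcript_id]
        seq = t.spliced_sequence(genome)
        for m in selected:
            for site in functional_mires(a, seed_match_sites(seq, m), m.mirna_id, cfg):
                rows.append(
                    {
                        "transcript_id": site.transcript_id,
                        "mirna_id": site.mirna_id,
                        "offset_transcript": site.start,
                        "offset_in_ptc_stop": site.start - a.ptc_stop_interval[0],
                        "distance_from_ptc_nt": site.distance_from_ptc_nt,
                        "region": site.region.value,
                        "functional": site.functional,
                    }
                )
    sites = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "mirna_id", "offset_transcript", "offset_in_ptc_stop",
            "distance_from_ptc_nt", "region", "functional",
        ],
    ).sort_values(
        ["transcript_id", "offset_transcript", "mirna_id"], kind="stable"
    ).reset_index(drop=True)

    if sites.empty:
        summary = pd.DataFrame(
            columns=["transcript_id", "n_functional_mires", "n_distinct_mirnas"]
        )
    else:
        functional = sites[sites["functional"]]
        summary = (
            functional.groupby("transcript_id")
            .agg(
                n_functional_mires=("mirna_id", "size"),
                n_distinct_mirnas=("mirna_id", "nunique"),
            )
            .reindex(sorted({a.transcript_id for a in annotations}), fill_value=0)
            .reset_index()
            .rename(columns={"index": "transcript_id"})
        )
    return sites, summary
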
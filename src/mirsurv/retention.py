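"""Retained-intron isoforms: PTC discovery by reading-frame translation,
the >0.05 retention-level filter, and Ago-CLIP overlap of PTC-STOP regions.

A retained intron either carries an in-frame stop, shifts the frame so a
downstream stop is reached, or (for 3n introns without stops) preserves the
reading through to the native stop. The "native stop" of a frame-shifted
isoform is the annotated stop's coordinate position, not a frame-correct
stop, so the PTC-STOP region of a retained-intron isoform can span both
exonic and intronic sequence; CLIP overlap uses the full genomic projection
of that region, strand-matched.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import (
    ClipInterval,
    GenomeSequence,
    MiRNA,
    RetentionRecord,
    STOP_CODONS,
    ThresholdsConfig,
    TranscriptModel,
)


@dataclass
class RetentionIsoform:
    """A retained-intron isoform with its discovered PTC and CLIP hits.

    All intervals/positions are isoform coordinates (0-based half-open).
    """

    transcript_id: str
    intron_index: int
    level: float
    length: int
    ptc_codon_index: int | None
    ptc_interval: tuple[int, int] | None
    ptc_stop_interval: tuple[int, int] | None
    native_stop_start: int
    clip_hit_count: int = 0


def retained_isoform(
    t: TranscriptModel, intron_index: int, genome: GenomeSequence
) -> tuple[str, int, int]:
    """Isoform sequence with intron ``intron_index`` retained.

    Returns (sequence, insert_pos, intron_length): base-transcript positions
    >= insert_pos shift 3' by intron_length in isoform coordinates.
    """
    intron = t.intron_sequence(genome, intron_index)
    insert_pos = sum(t.exon_lengths[:intron_index + 1])
    spliced = t.spliced_sequence(genome)
    return spliced[:insert_pos] + intron + spliced[insert_pos:], insert_pos, len(intron)


def base_to_isoform(pos: int, insert_pos: int, intron_length: int) -> int:
    """Map a base-transcript coordinate to the retained-isoform coordinate."""
    return pos if pos < insert_pos else pos + intron_length


def retention_filter(r: RetentionRecord, cfg: ThresholdsConfig) -> bool:
    """Pass iff the retention level strictly exceeds the threshold."""
    return r.level > cfg.retention_min_level


def find_first_inframe_stop(
    iso_seq: str, cds_start: int, native_stop_start: int
) -> int | None:
    """First stop codon reached translating from cds_start, as a PTC.

    Returns the 0-based codon index of the first stop whose codon starts
    strictly 5' of ``native_stop_start`` (the annotated stop's isoform
    position), or None when the first stop reached is the native stop (or,
    for frame-shifted isoforms, lies at/after it, or no stop exists).
    """
    for ci, pos in enumerate(range(cds_start, len(iso_seq) - 2, 3)):
        if iso_seq[pos:pos + 3] in STOP_CODONS:
            return ci if pos < native_stop_start else None
    return None


def retention_ptc_stop(iso: RetentionIsoform) -> tuple[int, int]:
    """[first nt after the PTC codon, native stop start) in isoform coords."""
    if iso.ptc_interval is None:
        raise ValueError(f"{iso.transcript_id}: isoform has no discovered PTC")
    start = iso.ptc_interval[1]
    return (start, max(start, iso.native_stop_start))


def isoform_blocks(
    t: TranscriptModel, intron_index: int | None
) -> list[tuple[int, int, int, int]]:
    """Colinear (iso_start, iso_end, genomic_start, genomic_end) blocks of a
    transcript, optionally with one intron retained."""
    blocks = []
    iso_pos = 0

    def add(gs: int, ge: int) -> None:
        nonlocal iso_pos
        blocks.append((iso_pos, iso_pos + (ge - gs), gs, ge))
        iso_pos += ge - gs

    for i, (s, e) in enumerate(t.exons):
        add(s, e)
        if intron_index is not None and i == intron_index:
            add(*t.intron_genomic(intron_index))
    return blocks


def project_to_genome(
    t: TranscriptModel, interval: tuple[int, int], intron_index: int | None = None
) -> list[tuple[int, int]]:
    """Genomic intervals covered by an isoform-coordinate interval (may be
    split across exons and a retained intron)."""
    lo, hi = interval
    pieces = []
    for iso_s, iso_e, gs, ge in isoform_blocks(t, intron_index):
        a, b = max(lo, iso_s), min(hi, iso_e)
        if a >= b:
            continue
        if t.strand == "+":
            pieces.append((gs + (a - iso_s), gs + (b - iso_s)))
        else:
            pieces.append((ge - (b - iso_s), ge - (a - iso_s)))
    return sorted(pieces)


def clip_overlap(
    t: TranscriptModel,
    interval: tuple[int, int],
    clip: list[ClipInterval],
    intron_index: int | None = None,
) -> int:
    """Number of strand-matched CLIP peaks overlapping >=1 nt of the genomic
    projection of an isoform interval. Each peak is counted at most once,
    even when it spans several projected pieces."""
    pieces = project_to_genome(t, interval, intron_index)
    hits = 0
    for peak in clip:
        if peak.contig != t.contig or peak.strand != t.strand:
            continue
        if any(peak.start < e and s < peak.end for s, e in pieces):
            hits += 1
    return hits


def build_retention_isoform(
    t: TranscriptModel,
    record: RetentionRecord,
    genome: GenomeSequence,
    clip: list[ClipInterval] | None = None,
) -> RetentionIsoform:
    """Construct one retained-intron isoform and discover its PTC."""
    if record.intron_index >= t.n_introns:
        raise IndexError(
            f"{t.transcript_id}: intron index {record.intron_index} out of range"
        )
    iso_seq, insert_pos, ilen = retained_isoform(t, record.intron_index, genome)
    cds_start = base_to_isoform(t.cds_start, insert_pos, ilen)
    native_stop_start = base_to_isoform(t.cds_end - 3, insert_pos, ilen)
    ptc_ci = find_first_inframe_stop(iso_seq, cds_start, native_stop_start)
    ptc_iv = None
    if ptc_ci is not None:
        start = cds_start + 3 * ptc_ci
        ptc_iv = (start, start + 3)
    iso = RetentionIsoform(
        transcript_id=t.transcript_id,
        intron_index=record.intron_index,
        level=record.level,
        length=len(iso_seq),
        ptc_codon_index=ptc_ci,
        ptc_interval=ptc_iv,
        ptc_stop_interval=None,
        native_stop_start=native_stop_start,
    )
    if ptc_iv is not None:
        iso.ptc_stop_interval = retention_ptc_stop(iso)
        if clip:
            iso.clip_hit_count = clip_overlap(
                t, iso.ptc_stop_interval, clip, record.intron_index
            )
    return iso


def _functional_mire_count(
    iso_seq: str, region: tuple[int, int], mirnas: list[MiRNA], cfg: ThresholdsConfig
) -> int:
    """Functional seed-match sites fully inside an isoform PTC-STOP region;
    the distance from the PTC equals the offset inside the region."""
    from .mire import SEED_LENGTH, seed_match_sites, select_top_mirnas

    lo, hi = region
    seq = iso_seq[lo:hi]
    count = 0
    for m in select_top_mirnas(mirnas, cfg):
        count += sum(
            1 for off in seed_match_sites(seq, m)
            if off >= cfg.mire_min_distance_nt and off + SEED_LENGTH <= hi - lo
        )
    return count


def analyze_retention(
    transcripts: dict[str, TranscriptModel],
    genome: GenomeSequence,
    records: list[RetentionRecord],
    clip: list[ClipInterval],
    cfg: ThresholdsConfig,
    mirnas: list[MiRNA] | None = None,
) -> pd.DataFrame:
    """Level-filter retention records, discover PTCs, count CLIP hits and
    (when miRNAs are supplied) functional miREs in the isoform PTC-STOP."""
    rows = []
    for rec in records:
        t = transcripts[rec.transcript_id]
        passes = retention_filter(rec, cfg)
        iso = build_retention_isoform(t, rec, genome, clip)
        n_mires = 0
        if mirnas and iso.ptc_stop_interval is not None:
            iso_seq, _, _ = retained_isoform(t, rec.intron_index, genome)
            n_mires = _functional_mire_count(iso_seq, iso.ptc_stop_interval, mirnas, cfg)
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "intron_index": rec.intron_index,
                "level": rec.level,
                "level_pass": passes,
                "isoform_length": iso.length,
                "ptc_codon_index": iso.ptc_codon_index,
                "ptc_stop_start": None if iso.ptc_stop_interval is None else iso.ptc_stop_interval[0],
                "ptc_stop_end": None if iso.ptc_stop_interval is None else iso.ptc_stop_interval[1],
                "ptc_stop_length_nt": (
                    0 if iso.ptc_stop_interval is None
                    else iso.ptc_stop_interval[1] - iso.ptc_stop_interval[0]
                ),
                "clip_hit_count": iso.clip_hit_count,
                "n_functional_mires": n_mires,
                "candidate": bool(
                    passes and iso.ptc_codon_index is not None and iso.clip_hit_count > 0
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "intron_index", "level", "level_pass", "isoform_length",
            "ptc_codon_index", "ptc_stop_start", "ptc_stop_end", "ptc_stop_length_nt",
            "clip_hit_count", "n_functional_mires", "candidate",
        ],
    ).sort_values(["transcript_id", "intron_index"], kind="stable").reset_index(drop=True)
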
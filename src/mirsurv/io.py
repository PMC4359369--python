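"""Readers and writers for FASTA, GTF, VCF, BED6 and TSV tables.

Internal coordinates are 0-based half-open everywhere; GTF's native 1-based
inclusive convention is converted at the parser boundary only. The GTF
dialect written (and expected) here carries ``exon`` and ``CDS`` features
with ``gene_id``/``transcript_id`` attributes, and its CDS records include
the native stop codon.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .models import (
    AbundanceRecord,
    ClipInterval,
    DNA_ALPHABET,
    GenomeSequence,
    MiRNA,
    RetentionRecord,
    SnvRecord,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------- FASTA

def read_genome(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA into a GenomeSequence (uppercased)."""
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValidationError(f"{path}: duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValidationError(f"{path}: no FASTA records found")
    for name, seq in contigs.items():
        bad = set(seq) - DNA_ALPHABET
        if bad:
            char = sorted(bad)[0]
            line_no = _find_fasta_line(path, char)
            raise ValidationError(
                f"{path}: contig {name!r} contains invalid character {char!r} "
                f"(line {line_no})"
            )
    return GenomeSequence(contigs)


def _find_fasta_line(path: Path, char: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith(">") and char in line.upper():
                return i
    return -1


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_mirna_fasta(path: str | Path) -> dict[str, str]:
    """Mature miRNA FASTA; T normalized to U."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate miRNA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("T", "U")
    return out


def read_mirnas(fasta_path: str | Path, counts_path: str | Path) -> list[MiRNA]:
    """Combine a mature-sequence FASTA with an abundance-count TSV."""
    seqs = read_mirna_fasta(fasta_path)
    counts = pd.read_csv(counts_path, sep="\t")
    if counts.shape[1] < 2:
        raise ValidationError(f"{counts_path}: expected at least 2 columns")
    id_col, count_col = counts.columns[:2]
    mirnas = []
    for _, row in counts.iterrows():
        mid = str(row[id_col])
        count = float(row[count_col])
        if count < 0:
            raise ValidationError(f"{counts_path}: negative count for {mid}")
        if mid not in seqs:
            raise ValidationError(f"{counts_path}: {mid} missing from {fasta_path}")
        mirnas.append(MiRNA(mid, seqs[mid], count))
    return mirnas


def write_mirnas(mirnas: list[MiRNA], fasta_path: str | Path, counts_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")
    with open(counts_path, "w") as fh:
        fh.write("mirna_id\tcount\n")
        for m in mirnas:
            fh.write(f"{m.mirna_id}\t{m.abundance:g}\n")


# ------------------------------------------------------------------------ GTF

def read_annotation(path: str | Path, genome: GenomeSequence) -> list[TranscriptModel]:
    """Parse a GTF with exon/CDS features into validated TranscriptModels."""
    db = gffutils.create_db(
        str(path), ":memory:",
        force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ValidationError(f"{path}: {feat.featuretype} line missing transcript_id")
        tid = tids[0]
        gene = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        # GTF is 1-based inclusive; convert here and nowhere else.
        interval = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(interval)

    models = []
    for tid, (gene, contig, strand) in meta.items():
        if tid not in exons:
            raise ValidationError(f"transcript {tid}: no exon records")
        if tid not in cds:
            raise ValidationError(f"transcript {tid}: no CDS records")
        ordered = sorted(exons[tid], reverse=(strand == "-"))
        try:
            t = TranscriptModel(
                transcript_id=tid, gene_id=gene, contig=contig, strand=strand,
                exons=tuple(ordered),
                **_cds_transcript_interval(tuple(ordered), strand, cds[tid], tid),
            )
            t.validate_against(genome)
        except ValidationError as exc:
            raise ValidationError(f"transcript {tid}: {exc}") from exc
        models.append(t)
    return models


def _cds_transcript_interval(exons, strand, cds_intervals, tid) -> dict[str, int]:
    gmin = min(s for s, _ in cds_intervals)
    gmax = max(e for _, e in cds_intervals)
    probe = TranscriptModel(
        transcript_id=tid, gene_id=tid, contig="_", strand=strand,
        exons=exons, cds_start=0, cds_end=3,
    )
    if strand == "+":
        start = probe.genomic_to_transcript(gmin)
        end = probe.genomic_to_transcript(gmax - 1) + 1
    else:
        start = probe.genomic_to_transcript(gmax - 1)
        end = probe.genomic_to_transcript(gmin) + 1
    return {"cds_start": start, "cds_end": end}


def write_annotation(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write exon + CDS GTF lines (1-based inclusive; CDS includes the stop)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(_gtf_line(t.contig, "exon", s, e, t.strand, attrs))
            for s, e in _cds_genomic_pieces(t):
                fh.write(_gtf_line(t.contig, "CDS", s, e, t.strand, attrs))


def _gtf_line(contig, feature, start0, end0, strand, attrs) -> str:
    return f"{contig}\tmirsurv\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def _cds_genomic_pieces(t: TranscriptModel) -> list[tuple[int, int]]:
    """Project the transcript CDS interval onto genomic exon pieces."""
    pieces = []
    acc = 0
    for s, e in t.exons:
        n = e - s
        lo = max(t.cds_start, acc)
        hi = min(t.cds_end, acc + n)
        if lo < hi:
            if t.strand == "+":
                pieces.append((s + (lo - acc), s + (hi - acc)))
            else:
                pieces.append((e - (hi - acc), e - (lo - acc)))
        acc += n
    return sorted(pieces)


# ------------------------------------------------------------------------ VCF

def read_variants(
    path: str | Path, ad_order: str = "ref_first"
) -> tuple[list[SnvRecord], int]:
    """Read SNVs from a VCF; returns (records, n_skipped_indels).

    Multi-allelic rows are split into one record per ALT. Indel alleles are
    skipped with a logged warning. A missing AD field loads the record with
    depths marked unavailable (None).
    """
    records: list[SnvRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for i, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    skipped += 1
                    logger.warning(
                        "skipping non-SNV allele %s>%s at %s:%d",
                        rec.ref, alt, rec.contig, rec.pos,
                    )
                    continue
                ad = _allele_depths(rec)
                if ad is None:
                    wt = ptc = None
                else:
                    wt, ptc = ad[0], ad[1 + i]
                    if ad_order == "alt_first":
                        wt, ptc = ptc, wt
                records.append(
                    SnvRecord(
                        contig=rec.contig, pos=rec.pos - 1, ref=rec.ref, alt=alt,
                        ptc_allele_reads=ptc, wt_allele_reads=wt,
                        variant_id=rec.id or ".",
                    )
                )
    return records, skipped


def _allele_depths(rec) -> tuple[int, ...] | None:
    for sample in rec.samples.values():
        ad = sample.get("AD")
        if ad is not None and ad[0] is not None:
            return tuple(int(x) for x in ad)
    try:
        ad = rec.info.get("AD")
    except (KeyError, ValueError):   # AD not declared as an INFO field
        return None
    if ad is not None:
        return tuple(int(x) for x in ad)
    return None


def write_variants(
    snvs: list[SnvRecord], contig_lengths: dict[str, int], path: str | Path
) -> None:
    """Write a minimal single-sample VCF 4.2 with AD (REF-first) depths."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n")
        for v in sorted(snvs, key=lambda r: (r.contig, r.pos, r.alt)):
            if v.wt_allele_reads is None or v.ptc_allele_reads is None:
                fmt, val = "GT", "0/1"
            else:
                fmt, val = "GT:AD", f"0/1:{v.wt_allele_reads},{v.ptc_allele_reads}"
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\t{fmt}\t{val}\n"
            )


# ------------------------------------------------------------------------ BED

BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_clip(path: str | Path) -> list[ClipInterval]:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    out = []
    for row in df.itertuples(index=False):
        score = None if pd.isna(row.score) or row.score == "." else float(row.score)
        out.append(
            ClipInterval(
                contig=str(row.contig), start=int(row.start), end=int(row.end),
                strand=str(row.strand), name=str(row.name), score=score,
            )
        )
    return out


def write_clip(intervals: list[ClipInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(intervals, key=lambda x: (x.contig, x.start, x.end, x.name)):
            score = "." if c.score is None else f"{c.score:g}"
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.name}\t{score}\t{c.strand}\n")


# ------------------------------------------------------------------------ TSV

def read_abundance(path: str | Path) -> list[AbundanceRecord]:
    df = pd.read_csv(path, sep="\t")
    id_col, val_col = df.columns[:2]
    return [
        AbundanceRecord(str(r[id_col]), float(r[val_col])) for _, r in df.iterrows()
    ]


def write_abundance(records: list[AbundanceRecord], path: str | Path, unit: str = "fpkm") -> None:
    with open(path, "w") as fh:
        fh.write(f"feature_id\t{unit}\n")
        for r in records:
            fh.write(f"{r.feature_id}\t{r.abundance:g}\n")


def read_retention(path: str | Path) -> list[RetentionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        RetentionRecord(str(r["transcript_id"]), int(r["intron_index"]), float(r["level"]))
        for _, r in df.iterrows()
    ]


def write_retention(records: list[RetentionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tintron_index\tlevel\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.intron_index}\t{r.level:g}\n")
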
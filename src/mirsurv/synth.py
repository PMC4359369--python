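"""Deterministic, seeded generator of toy genomes with planted ground truth.

The generator emulates the study conditions every pipeline stage needs:
multi-exon protein-coding genes on both strands, heterozygous nonsense SNVs
with exact integer allele ratios, perfect seed-match miRE sites planted at
controlled distances from the PTC, retained introns with controlled
retention levels and in-frame stops, Ago-CLIP peaks placed inside/outside
PTC-STOP projections, and a miRNA population straddling the top-N abundance
cutoff. Every planted item carries an expected pipeline verdict in a
machine-readable truth manifest.

The default plan probes each numeric rule at its boundary: junction
distances 11/49/50 and last-exon/single-exon PTCs for the 50-nt EJC-NMD
rule, miRE distances 9/10/16 plus an upstream site for the 10-nt rule,
allele ratios 0.69/0.7/1.0/1.3/1.4 for the 0.7-1.3 heterozygosity window,
retention levels 0.05/0.051/0.2 for the >0.05 cut, PTC-STOP lengths
399/402/738 nt for the >400 nt candidate filter, and 300 miRNAs for the
top-150 selection. One retention gene reproduces the geometry of a
retained last intron creating a PTC 505 nt upstream of a let-7a site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .mire import seed_of
from .models import (
    AbundanceRecord,
    ClipInterval,
    GenomeSequence,
    MiRNA,
    RetentionRecord,
    STOP_CODONS,
    SnvRecord,
    TranscriptModel,
    reverse_complement,
)
from .retention import project_to_genome, retained_isoform

SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS and "".join(c) != "ATG"
)

LET7A = MiRNA("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU", 0)
MIR125B = MiRNA("hsa-miR-125b-5p", "UCCCUGAGACCCUAACUUGUGA", 0)
MIR21 = MiRNA("hsa-miR-21-5p", "UAGCUUAUCAGACUGAUGUUGA", 0)


@dataclass
class PtcPlant:
    codon_index: int
    junction_distance: int | None   # None with last_exon/single_exon flags below
    ratio: tuple[int, int]          # (ptc_reads, wt_reads), exact integers
    last_exon: bool = False
    single_exon: bool = False


@dataclass
class MirePlant:
    mirna: MiRNA
    distance: int                   # nt between PTC codon end and site start


@dataclass
class RetentionPlant:
    level: float
    inframe_stop: bool
    codons_before_intron: int = 10
    intron_codons: int = 20
    stop_codon_in_intron: int = 5
    mire: MirePlant | None = None   # distance measured on the isoform
    clips: tuple[str, ...] = ()     # subset of {"inside", "antisense", "outside"}


@dataclass
class GenePlan:
    name: str
    strand: str
    n_codons: int                   # coding codons including the native stop
    utr5_len: int = 60
    utr3_len: int = 90
    ptc: PtcPlant | None = None
    mires: tuple[MirePlant, ...] = ()
    retention: RetentionPlant | None = None
    abundance: float | None = None
    n_exons: int | None = None      # background genes only; plants set geometry


@dataclass
class Bundle:
    """Everything one pipeline run needs, plus the ground-truth manifest."""

    seed: int
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    snvs: list[SnvRecord]
    mirnas: list[MiRNA]
    abundance: list[AbundanceRecord]
    retention: list[RetentionRecord]
    clip: list[ClipInterval]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_genome(self.genome, outdir / "genome.fa")
        mio.write_annotation(self.transcripts, outdir / "genes.gtf")
        lengths = {k: len(v) for k, v in self.genome.contigs.items()}
        mio.write_variants(self.snvs, lengths, outdir / "variants.vcf")
        mio.write_mirnas(self.mirnas, outdir / "mirnas.fa", outdir / "mirna_counts.tsv")
        mio.write_abundance(self.abundance, outdir / "abundance.tsv")
        mio.write_retention(self.retention, outdir / "retention.tsv")
        mio.write_clip(self.clip, outdir / "clip.bed")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, lineterminator="\n")


def default_plan() -> list[GenePlan]:
    """The standard study-condition plan (see module docstring)."""
    return [
        # 50-nt rule boundaries + PTC-STOP length boundaries + het ratios
        GenePlan("g01", "+", 200,
                 ptc=PtcPlant(64, 50, (10, 10)),               # d=50 sensitive; len 402
                 mires=(MirePlant(LET7A, 16),), abundance=10.0),
        GenePlan("g02", "-", 200,
                 ptc=PtcPlant(65, 49, (7, 10)),                    # d=49; len 399
                 mires=(MirePlant(LET7A, 10),), abundance=10.0),
        GenePlan("g03", "+", 261,
                 ptc=PtcPlant(13, 11, (69, 100)), abundance=1.0),  # d=11; len 738
        GenePlan("g04", "+", 200,
                 ptc=PtcPlant(64, None, (13, 10), last_exon=True), abundance=0.0),
        GenePlan("g05", "+", 200,
                 ptc=PtcPlant(64, None, (14, 10), single_exon=True), abundance=10.0),
        # 10-nt rule boundaries + upstream site
        GenePlan("g06", "-", 200,
                 ptc=PtcPlant(40, 55, (10, 10)),
                 mires=(MirePlant(MIR125B, 9), MirePlant(MIR21, -20)),
                 abundance=10.0),
        # intron retention: the 505-nt geometry, level boundaries, CLIP placement
        GenePlan("g07", "-", 180,
                 retention=RetentionPlant(0.2, True,
                                          mire=MirePlant(LET7A, 505),
                                          clips=("inside", "antisense", "outside"))),
        GenePlan("g08", "+", 80,
                 retention=RetentionPlant(0.05, True, clips=("inside",))),
        GenePlan("g09", "+", 80,
                 retention=RetentionPlant(0.051, True, clips=("inside",))),
        GenePlan("g10", "+", 80, retention=RetentionPlant(0.2, False)),
        # background genes
        GenePlan("g11", "+", 120),
        GenePlan("g12", "-", 90),
    ]


def generate_reference(
    seed: int,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (1, 4),
    codons_per_gene: tuple[int, int] = (40, 200),
    outdir: str | Path | None = None,
) -> Bundle:
    """Plain reference bundle: n_genes random valid genes, nothing planted.

    Exon counts and CDS sizes are drawn uniformly from the given inclusive
    ranges; deterministic for a given seed. With ``outdir`` the FASTA/GTF
    (and empty companion tables) are written out.
    """
    if n_genes < 0 or exons_per_gene[0] < 1 or codons_per_gene[0] < 10:
        raise ValueError("infeasible generator parameters")
    rng = np.random.default_rng(seed)
    plans = []
    for i in range(n_genes):
        n_codons = int(rng.integers(codons_per_gene[0], codons_per_gene[1] + 1))
        strand = "+" if rng.integers(0, 2) else "-"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        plans.append(GenePlan(f"ref{i + 1:03d}", strand, n_codons, n_exons=n_exons))
    bundle = generate_bundle(seed, plans=plans)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def generate_bundle(
    seed: int,
    plans: list[GenePlan] | None = None,
    n_mirnas: int = 300,
    top_boundary_rank: int = 150,
) -> Bundle:
    """Build a complete synthetic bundle with its truth manifest."""
    rng = np.random.default_rng(seed)
    plans = default_plan() if plans is None else plans
    mirnas = _generate_mirnas(rng, n_mirnas)
    truth_rows: list[dict] = []

    chunks: dict[str, list[str]] = {"chr1": [], "chr2": []}
    offsets = {"chr1": 0, "chr2": 0}
    transcripts, snvs, retention, clip, abundance = [], [], [], [], []

    for gi, plan in enumerate(plans):
        contig = "chr1" if gi % 2 == 0 else "chr2"
        spacer = _random_seq(rng, 100)
        chunks[contig].append(spacer)
        offsets[contig] += 100
        built = _build_gene(rng, plan, contig, offsets[contig], truth_rows)
        chunks[contig].append(built.genomic_chunk)
        offsets[contig] += len(built.genomic_chunk)
        transcripts.append(built.model)
        snvs.extend(built.snvs)
        retention.extend(built.retention)
        clip.extend(built.clip)
        if plan.abundance is not None:
            abundance.append(AbundanceRecord(plan.name, plan.abundance))
            truth_rows.append(
                {
                    "kind": "expression_status", "id": plan.name,
                    "param": "abundance", "value": plan.abundance,
                    "expected": "pass" if plan.abundance > 1.0 else "fail",
                }
            )

    genome = GenomeSequence({k: "".join(v) for k, v in chunks.items() if v})
    # CLIP peaks need final genome coordinates; planted during gene build.

    ranked = sorted(mirnas, key=lambda m: (-m.abundance, m.mirna_id))
    for rank in (top_boundary_rank - 1, top_boundary_rank):
        if rank < len(ranked):
            truth_rows.append(
                {
                    "kind": "mirna_selected", "id": ranked[rank].mirna_id,
                    "param": "rank", "value": rank + 1,
                    "expected": "true" if rank < top_boundary_rank else "false",
                }
            )
    truth_rows.append(
        {
            "kind": "mirna_selected", "id": "_total_", "param": "n_selected",
            "value": min(top_boundary_rank, len(mirnas)),
            "expected": str(min(top_boundary_rank, len(mirnas))),
        }
    )

    truth = pd.DataFrame(truth_rows, columns=["kind", "id", "param", "value", "expected"])
    bundle = Bundle(seed, genome, transcripts, snvs, mirnas, abundance,
                    retention, clip, truth)
    for t in transcripts:
        t.validate_against(genome)
    return bundle


def _generate_mirnas(rng, n: int) -> list[MiRNA]:
    """Three real miRNAs at the top of the abundance ladder plus synthetic
    22-mers with strictly distinct abundances spanning the top-N cutoff."""
    out = [
        MiRNA(LET7A.mirna_id, LET7A.sequence, 10000.0),
        MiRNA(MIR125B.mirna_id, MIR125B.sequence, 9000.0),
        MiRNA(MIR21.mirna_id, MIR21.sequence, 8000.0),
    ]
    for i in range(max(0, n - len(out))):
        seq = "".join(rng.choice(list("ACGU"), size=22))
        out.append(MiRNA(f"syn-mir-{i + 1:03d}", seq, float(5000 - i)))
    return out


# ------------------------------------------------------------- gene builder

@dataclass
class _BuiltGene:
    model: TranscriptModel
    genomic_chunk: str
    snvs: list[SnvRecord] = field(default_factory=list)
    retention: list[RetentionRecord] = field(default_factory=list)
    clip: list[ClipInterval] = field(default_factory=list)


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng, n_codons: int) -> str:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _build_gene(
    rng, plan: GenePlan, contig: str, offset: int, truth_rows: list[dict]
) -> _BuiltGene:
    utr5 = _random_seq(rng, plan.utr5_len)
    cds = _random_cds(rng, plan.n_codons)
    utr3 = _random_seq(rng, plan.utr3_len)
    cds_start = plan.utr5_len
    cds_len = 3 * plan.n_codons
    length = plan.utr5_len + cds_len + plan.utr3_len

    junctions: list[int] = []
    ptc = plan.ptc
    if ptc is not None:
        cds = _set_codon(cds, ptc.codon_index, "AAA")
        codon_end = cds_start + 3 * (ptc.codon_index + 1)
        if ptc.single_exon:
            pass
        elif ptc.last_exon:
            junctions = [codon_end - 3 - 20]
        else:
            junctions = [codon_end + ptc.junction_distance]
    retent = plan.retention
    if retent is not None:
        junctions = [cds_start + 3 * retent.codons_before_intron]
    elif ptc is None and plan.n_exons and plan.n_exons > 1:
        junctions = sorted(
            int(x) for x in rng.choice(
                np.arange(1, length - 1), size=plan.n_exons - 1, replace=False
            )
        )

    mrna = utr5 + cds + utr3
    native_stop_start = cds_start + cds_len - 3
    protected = [(cds_start, cds_start + 3), (native_stop_start, native_stop_start + 3)]
    if ptc is not None:
        protected.append((cds_start + 3 * ptc.codon_index, cds_start + 3 * ptc.codon_index + 3))

    planted_sites: list[tuple[str, int]] = []  # (motif, mRNA offset)
    if ptc is not None:
        codon_end = cds_start + 3 * (ptc.codon_index + 1)
        for mp in plan.mires:
            motif = seed_of(mp.mirna).motif
            pos = codon_end + mp.distance
            mrna = _plant_motif(mrna, pos, motif, cds_start, cds_len, protected)
            protected.append((pos, pos + 6))
            planted_sites.append((motif, pos))
            region = (
                "ORF_UPSTREAM_OF_PTC" if mp.distance < 0
                else ("PTC_STOP" if pos + 6 <= native_stop_start else "THREE_PRIME_UTR")
            )
            truth_rows.append(
                {
                    "kind": "mire_site",
                    "id": f"{plan.name}:{mp.mirna.mirna_id}",
                    "param": "distance", "value": mp.distance,
                    "expected": f"{region}:"
                                + ("functional" if mp.distance >= 10 and region != "ORF_UPSTREAM_OF_PTC"
                                   else "nonfunctional"),
                }
            )
        # rejection: remove accidental extra matches inside the PTC-STOP region
        mrna = _scrub_accidental_matches(
            mrna, codon_end, native_stop_start, planted_sites, cds_start, cds_len, protected
        )

    intron_seqs: dict[int, str] = {}
    if retent is not None:
        intron = _retention_intron(rng, retent)
        intron_seqs[0] = intron
    else:
        for i in range(len(junctions)):
            n = int(rng.integers(60, 121))
            intron_seqs[i] = "GT" + _random_seq(rng, n - 4) + "AG"

    model, chunk = _assemble(plan, contig, offset, mrna, junctions, intron_seqs,
                             cds_start, cds_len)
    built = _BuiltGene(model=model, genomic_chunk=chunk)

    if ptc is not None:
        built.snvs.append(_make_variant(model, chunk, offset, cds_start, ptc, plan,
                                        truth_rows))
    if retent is not None:
        _plant_retention(rng, built, retent, plan, truth_rows)
    return built


def _set_codon(cds: str, index: int, codon: str) -> str:
    return cds[:3 * index] + codon + cds[3 * index + 3:]


def _plant_motif(
    mrna: str, pos: int, motif: str, cds_start: int, cds_len: int,
    protected: list[tuple[int, int]],
) -> str:
    """Write a 6-mer motif at an exact mRNA offset without touching protected
    intervals or creating an in-frame stop in the reference ORF."""
    if pos < 0 or pos + 6 > len(mrna):
        raise ValueError(f"motif placement [{pos}, {pos + 6}) outside mRNA")
    for s, e in protected:
        if pos < e and s < pos + 6:
            raise ValueError(f"motif placement collides with feature [{s}, {e})")
    seq = mrna[:pos] + motif + mrna[pos + 6:]
    return _repair_frame_stops(seq, pos, pos + 6, cds_start, cds_len)


def _repair_frame_stops(seq: str, lo: int, hi: int, cds_start: int, cds_len: int) -> str:
    """Fix in-frame stops in reference codons overlapping [lo, hi) by editing
    a base outside the motif (C kills any stop codon)."""
    native_stop = cds_start + cds_len - 3
    first_ci = max(0, (lo - cds_start) // 3)
    last_ci = min(cds_len // 3 - 1, (hi - 1 - cds_start) // 3)
    out = list(seq)
    for ci in range(first_ci, last_ci + 1):
        a = cds_start + 3 * ci
        if a == native_stop:
            continue
        codon = "".join(out[a:a + 3])
        if codon not in STOP_CODONS:
            continue
        free = [p for p in range(a, a + 3) if not lo <= p < hi]
        if not free:
            raise ValueError("planted motif itself forms an in-frame stop codon")
        out[free[0]] = "C"
        if "".join(out[a:a + 3]) in STOP_CODONS:  # cannot happen: stops lack C
            raise ValueError("unable to repair in-frame stop next to motif")
    return "".join(out)


def _scrub_accidental_matches(
    mrna: str, region_start: int, region_end: int,
    planted: list[tuple[str, int]], cds_start: int, cds_len: int,
    protected: list[tuple[int, int]],
) -> str:
    """Remove chance occurrences of planted motifs inside the PTC-STOP region
    (only the intentionally planted offsets survive)."""
    motifs = {m for m, _ in planted}
    wanted = set(planted)
    for _ in range(64):
        region = mrna[region_start:region_end]
        accidental = [
            (m, region_start + off)
            for m in sorted(motifs)
            for off in _find_all(region, m)
            if (m, region_start + off) not in wanted
        ]
        accidental = [
            (m, pos) for m, pos in accidental
            if not any(pos < e and s < pos + 6 for s, e in protected)
        ]
        if not accidental:
            return mrna
        m, pos = accidental[0]
        mid = pos + 2
        for base in "CGAT":
            if base == mrna[mid]:
                continue
            candidate = mrna[:mid] + base + mrna[mid + 1:]
            candidate = _repair_frame_stops(candidate, mid, mid + 1, cds_start, cds_len)
            window = candidate[max(0, pos - 5):pos + 11]
            if not any(mm in window for mm in motifs):
                mrna = candidate
                break
        else:
            raise ValueError("could not scrub accidental seed match")
    raise ValueError("accidental-match scrub did not converge")


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _retention_intron(rng, retent: RetentionPlant) -> str:
    """Frame-aligned (3n) GT..AG intron, sense codons except an optional
    planted in-frame TAA."""
    q = retent.intron_codons
    p = retent.stop_codon_in_intron
    if not 1 <= p <= q - 2:
        raise ValueError("stop codon index outside intron body")
    codons = ["GTA"]
    for i in range(1, q - 1):
        if retent.inframe_stop and i == p:
            codons.append("TAA")
        else:
            c = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
            while c in STOP_CODONS or (i == q - 2 and c[2] == "T"):
                c = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
            codons.append(c)
    codons.append("CAG")
    return "".join(codons)


def _assemble(
    plan: GenePlan, contig: str, offset: int, mrna: str,
    junctions: list[int], intron_seqs: dict[int, str],
    cds_start: int, cds_len: int,
) -> tuple[TranscriptModel, str]:
    """Split the mature mRNA at the junctions, insert introns, and lay the
    gene on the genome in the requested orientation."""
    bounds = [0] + sorted(junctions) + [len(mrna)]
    exon_tx = list(zip(bounds, bounds[1:]))
    pre_parts, exon_pre = [], []
    pre_pos = 0
    for i, (a, b) in enumerate(exon_tx):
        pre_parts.append(mrna[a:b])
        exon_pre.append((pre_pos, pre_pos + (b - a)))
        pre_pos += b - a
        if i < len(exon_tx) - 1:
            intron = intron_seqs[i]
            pre_parts.append(intron)
            pre_pos += len(intron)
    pre = "".join(pre_parts)
    if plan.strand == "+":
        chunk = pre
        exons = [(offset + s, offset + e) for s, e in exon_pre]
    else:
        chunk = reverse_complement(pre)
        P = len(pre)
        exons = [(offset + P - e, offset + P - s) for s, e in exon_pre]
    model = TranscriptModel(
        transcript_id=f"{plan.name}.t1", gene_id=plan.name, contig=contig,
        strand=plan.strand, exons=tuple(exons),
        cds_start=cds_start, cds_end=cds_start + cds_len,
    )
    return model, chunk


def _make_variant(
    model: TranscriptModel, chunk: str, offset: int, cds_start: int,
    ptc: PtcPlant, plan: GenePlan, truth_rows: list[dict],
) -> SnvRecord:
    tx_pos = cds_start + 3 * ptc.codon_index  # first base of the AAA codon
    gpos = model.transcript_to_genomic(tx_pos)
    ref = chunk[gpos - offset]
    alt = "T" if model.strand == "+" else "A"
    ptc_reads, wt_reads = ptc.ratio
    snv = SnvRecord(
        contig=model.contig, pos=gpos, ref=ref, alt=alt,
        ptc_allele_reads=ptc_reads, wt_allele_reads=wt_reads,
        variant_id=f"{plan.name}_ptc",
    )
    ratio = ptc_reads / wt_reads if wt_reads else float("inf")
    het = wt_reads > 0 and 0.7 <= ratio <= 1.3
    if ptc.single_exon or ptc.last_exon:
        nmd = False
    else:
        nmd = ptc.junction_distance >= 50
    stop_len = 3 * (plan.n_codons - 1 - ptc.codon_index - 1)
    truth_rows.extend(
        [
            {
                "kind": "ptc_variant", "id": snv.variant_id,
                "param": "junction_distance",
                "value": -1 if ptc.junction_distance is None else ptc.junction_distance,
                "expected": "ejc_sensitive" if nmd else "ejc_insensitive",
            },
            {
                "kind": "het_status", "id": snv.variant_id,
                "param": "ratio", "value": round(ratio, 6),
                "expected": "pass" if het else "fail",
            },
            {
                "kind": "ptc_stop_length", "id": snv.variant_id,
                "param": "length_nt", "value": stop_len,
                "expected": "pass" if stop_len > 400 else "fail",
            },
        ]
    )
    return snv


def _plant_retention(
    rng, built: _BuiltGene, retent: RetentionPlant, plan: GenePlan,
    truth_rows: list[dict],
) -> None:
    model = built.model
    built.retention.append(
        RetentionRecord(model.transcript_id, 0, retent.level)
    )
    offset = min(s for s, _ in model.exons)
    genome = GenomeSequence({model.contig: "N" * offset + built.genomic_chunk})
    iso_seq, insert_pos, ilen = retained_isoform(model, 0, genome)
    cds_start_iso = model.cds_start if model.cds_start < insert_pos else model.cds_start + ilen
    has_ptc = retent.inframe_stop
    ptc_end_iso = None
    if has_ptc:
        m, p = retent.codons_before_intron, retent.stop_codon_in_intron
        ptc_end_iso = cds_start_iso + 3 * (m + p + 1)

    if retent.mire is not None and has_ptc:
        site_iso = ptc_end_iso + retent.mire.distance
        motif = seed_of(retent.mire.mirna).motif
        built.genomic_chunk, ok = _write_iso_motif(
            built, genome, model, site_iso, insert_pos, ilen, motif
        )
        assert ok
        truth_rows.append(
            {
                "kind": "retention_mire",
                "id": f"{plan.name}:{retent.mire.mirna.mirna_id}",
                "param": "iso_distance", "value": retent.mire.distance,
                "expected": "functional" if retent.mire.distance >= 10 else "nonfunctional",
            }
        )

    # CLIP peaks relative to the isoform PTC-STOP genomic projection
    native_stop_iso = (
        model.cds_end - 3 + (ilen if model.cds_end - 3 >= insert_pos else 0)
    )
    if has_ptc:
        region_iso = (ptc_end_iso, native_stop_iso)
        pieces = project_to_genome(model, region_iso, 0)
        for kind in retent.clips:
            name = f"{plan.name}_clip_{kind}"
            if kind in ("inside", "antisense"):
                s, e = pieces[0]
                mid = (s + e) // 2
                peak = ClipInterval(
                    model.contig, max(s, mid - 10), min(e, mid + 10),
                    model.strand if kind == "inside" else ("-" if model.strand == "+" else "+"),
                    name=name, score=5.0,
                )
                expected = 1 if kind == "inside" else 0
            else:
                gene_start = min(s for s, _ in model.exons)
                peak = ClipInterval(
                    model.contig, max(0, gene_start - 80), gene_start - 40,
                    model.strand, name=name, score=5.0,
                )
                expected = 0
            built.clip.append(peak)
            truth_rows.append(
                {
                    "kind": "clip_peak", "id": name, "param": "placement",
                    "value": 0, "expected": str(expected),
                }
            )

    level_pass = retent.level > 0.05
    truth_rows.append(
        {
            "kind": "retention_ptc", "id": model.transcript_id,
            "param": "level", "value": retent.level,
            "expected": ";".join(
                [
                    "level_pass" if level_pass else "level_fail",
                    "has_ptc" if has_ptc else "no_ptc",
                ]
            ),
        }
    )


def _write_iso_motif(
    built: _BuiltGene, genome: GenomeSequence, model: TranscriptModel,
    site_iso: int, insert_pos: int, ilen: int, motif: str,
) -> tuple[str, bool]:
    """Write a motif at an isoform coordinate that falls in exonic sequence
    3' of the retained intron (so it also exists on the spliced transcript)."""
    base_pos = site_iso - ilen
    if base_pos < insert_pos:
        raise ValueError("isoform miRE placement inside or 5' of the intron")
    offset = min(s for s, _ in model.exons)
    chunk = built.genomic_chunk
    for k, ch in enumerate(motif):
        g = model.transcript_to_genomic(base_pos + k)
        b = ch if model.strand == "+" else reverse_complement(ch)
        i = g - offset
        chunk = chunk[:i] + b + chunk[i + 1:]
    built.genomic_chunk = chunk
    return chunk, True


def write_bundle(seed: int, outdir: str | Path) -> Bundle:
    """Generate the default bundle and write it to a directory."""
    bundle = generate_bundle(seed)
    bundle.write(outdir)
    return bundle


# ----------------------------------------------------------- truth checking

def verify_recovery(bundle: Bundle, result: dict, cfg) -> pd.DataFrame:
    """Compare every manifest verdict with the pipeline's output.

    Returns one row per planted item with columns (kind, id, expected,
    observed, match); a full recovery has match == True everywhere.
    """
    from .mire import select_top_mirnas

    candidates = result["candidates"].set_index("variant_id", drop=False)
    sites = result["sites"]
    retention = result["retention"].set_index("transcript_id", drop=False)
    selected_ids = {m.mirna_id for m in select_top_mirnas(bundle.mirnas, cfg)}
    gene_to_variant = {
        row.gene_id: row.variant_id for row in candidates.itertuples()
    }

    clip_expected: dict[str, int] = {}
    for row in bundle.truth.itertuples():
        if row.kind == "clip_peak":
            gene = row.id.split("_clip_")[0]
            clip_expected[gene] = clip_expected.get(gene, 0) + int(row.expected)

    rows = []

    def emit(kind, ident, expected, observed):
        rows.append(
            {
                "kind": kind, "id": ident, "expected": str(expected),
                "observed": str(observed), "match": str(expected) == str(observed),
            }
        )

    seen_clip_genes = set()
    for row in bundle.truth.itertuples():
        kind, ident, expected = row.kind, row.id, row.expected
        if kind == "ptc_variant":
            obs = "absent"
            if ident in candidates.index:
                obs = (
                    "ejc_sensitive"
                    if bool(candidates.loc[ident, "ejc_nmd_sensitive"])
                    else "ejc_insensitive"
                )
            emit(kind, ident, expected, obs)
        elif kind == "het_status":
            obs = "absent"
            if ident in candidates.index:
                obs = "pass" if bool(candidates.loc[ident, "het_pass"]) else "fail"
            emit(kind, ident, expected, obs)
        elif kind == "ptc_stop_length":
            obs = "absent"
            if ident in candidates.index:
                length_ok = bool(candidates.loc[ident, "length_pass"])
                length_match = int(candidates.loc[ident, "ptc_stop_length_nt"]) == int(row.value)
                obs = ("pass" if length_ok else "fail") if length_match else "length_mismatch"
            emit(kind, ident, expected, obs)
        elif kind == "expression_status":
            variant = gene_to_variant.get(ident)
            obs = "absent"
            if variant is not None:
                obs = "pass" if bool(candidates.loc[variant, "expression_pass"]) else "fail"
            emit(kind, ident, expected, obs)
        elif kind == "mire_site":
            gene, mirna_id = ident.split(":")
            tid = f"{gene}.t1"
            hit = sites[
                (sites["transcript_id"] == tid)
                & (sites["mirna_id"] == mirna_id)
                & (sites["distance_from_ptc_nt"] == int(row.value))
            ]
            if len(hit) == 1:
                obs = (
                    f"{hit['region'].iloc[0]}:"
                    + ("functional" if bool(hit["functional"].iloc[0]) else "nonfunctional")
                )
            else:
                obs = f"{len(hit)}_sites_at_distance"
            emit(kind, ident, expected, obs)
        elif kind == "retention_ptc":
            obs = "absent"
            if ident in retention.index:
                level = "level_pass" if bool(retention.loc[ident, "level_pass"]) else "level_fail"
                has = (
                    "has_ptc"
                    if pd.notna(retention.loc[ident, "ptc_codon_index"])
                    else "no_ptc"
                )
                obs = f"{level};{has}"
            emit(kind, ident, expected, obs)
        elif kind == "retention_mire":
            gene, _ = ident.split(":")
            tid = f"{gene}.t1"
            n = int(retention.loc[tid, "n_functional_mires"]) if tid in retention.index else 0
            emit(kind, ident, expected, "functional" if n >= 1 else "nonfunctional")
        elif kind == "clip_peak":
            gene = ident.split("_clip_")[0]
            if gene in seen_clip_genes:
                continue
            seen_clip_genes.add(gene)
            tid = f"{gene}.t1"
            obs = int(retention.loc[tid, "clip_hit_count"]) if tid in retention.index else "absent"
            emit("clip_total", gene, clip_expected[gene], obs)
        elif kind == "mirna_selected":
            if ident == "_total_":
                emit(kind, ident, expected, len(selected_ids))
            else:
                emit(kind, ident, expected, "true" if ident in selected_ids else "false")
    return pd.DataFrame(rows, columns=["kind", "id", "expected", "observed", "match"])
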
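"""End-to-end survey orchestration, the repression-ratio utility and final
candidate reporting.

The survey runs annotate -> filter -> scan -> retention -> join over a
bundle of input files and reports, per variant, the chosen isoform (the one
with the longest PTC-STOP region), its NMD class, the filter verdicts, and
the functional miRE count; the overall surveillance-candidate flag is true
iff every applicable filter passes and at least one functional miRE exists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as mio
from .mire import scan_transcriptome
from .models import (
    AbundanceRecord,
    ClipInterval,
    GenomeSequence,
    MiRNA,
    RetentionRecord,
    SnvRecord,
    ThresholdsConfig,
    TranscriptModel,
)
from .ptc import (
    Consequence,
    PtcAnnotation,
    annotate_ptc,
    candidate_filter,
    choose_isoform,
    expression_filter,
    heterozygosity_filter,
    variant_consequence,
)
from .retention import analyze_retention

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RepressionMeasurement:
    """Normalized reporter levels with and without the cognate miRNA."""

    protein_without: float
    protein_with: float
    mrna_without: float
    mrna_with: float

    def __post_init__(self) -> None:
        if min(self.protein_without, self.protein_with,
               self.mrna_without, self.mrna_with) <= 0:
            raise ValueError("all measurement values must be > 0")


def repression_ratios(m: RepressionMeasurement) -> tuple[float, float, float]:
    """(protein ratio, mRNA ratio, translation-efficiency ratio).

    Each repression ratio is level-without / level-with miRNA. Dividing the
    protein ratio by the mRNA ratio gives the repression ratio for
    translation efficiency (protein yield per mRNA molecule); a TE ratio
    > 1 indicates that part of the repression is translational inhibition.
    """
    protein = m.protein_without / m.protein_with
    mrna = m.mrna_without / m.mrna_with
    return protein, mrna, protein / mrna


def translational_inhibition_contributes(m: RepressionMeasurement) -> bool:
    return repression_ratios(m)[2] > 1.0


# ----------------------------------------------------------------- survey

@dataclass
class SurveyInputs:
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    snvs: list[SnvRecord]
    mirnas: list[MiRNA]
    abundance: list[AbundanceRecord] | None = None
    retention: list[RetentionRecord] | None = None
    clip: list[ClipInterval] | None = None

    @classmethod
    def from_directory(cls, indir: str | Path, cfg: ThresholdsConfig) -> "SurveyInputs":
        indir = Path(indir)
        genome = mio.read_genome(indir / "genome.fa")
        transcripts = mio.read_annotation(indir / "genes.gtf", genome)
        snvs, skipped = mio.read_variants(indir / "variants.vcf", cfg.ad_order)
        if skipped:
            logger.info("skipped %d non-SNV allele(s)", skipped)
        mirnas = mio.read_mirnas(indir / "mirnas.fa", indir / "mirna_counts.tsv")
        opt = lambda p, reader: reader(p) if p.exists() else None
        return cls(
            genome=genome, transcripts=transcripts, snvs=snvs, mirnas=mirnas,
            abundance=opt(indir / "abundance.tsv", mio.read_abundance),
            retention=opt(indir / "retention.tsv", mio.read_retention),
            clip=opt(indir / "clip.bed", mio.read_clip),
        )


def annotate_variants(
    inputs: SurveyInputs, cfg: ThresholdsConfig
) -> list[PtcAnnotation]:
    """Nonsense-annotate every SNV against every overlapping transcript and
    keep, per variant, the isoform with the longest PTC-STOP region."""
    by_contig: dict[str, list[TranscriptModel]] = {}
    for t in inputs.transcripts:
        by_contig.setdefault(t.contig, []).append(t)
    chosen = []
    for v in inputs.snvs:
        hits = []
        for t in by_contig.get(v.contig, []):
            lo = min(s for s, _ in t.exons)
            hi = max(e for _, e in t.exons)
            if not lo <= v.pos < hi:
                continue
            if variant_consequence(t, inputs.genome, v) is Consequence.NONSENSE:
                hits.append(annotate_ptc(t, inputs.genome, v, cfg))
        if hits:
            chosen.append(choose_isoform(hits))
    return chosen


def run_survey(
    inputs: SurveyInputs,
    cfg: ThresholdsConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage in order and return {candidates, sites, retention,
    summary}; optionally write the TSV/JSON report files."""
    cfg = cfg or ThresholdsConfig()
    transcripts = {t.transcript_id: t for t in inputs.transcripts}
    abundance = {a.feature_id: a for a in (inputs.abundance or [])}

    annotations = annotate_variants(inputs, cfg)
    logger.info("stage annotate: %d nonsense variants", len(annotations))

    sites, mire_summary = scan_transcriptome(
        annotations, transcripts, inputs.genome, inputs.mirnas, cfg
    )
    functional_counts = dict(
        zip(mire_summary.get("transcript_id", []), mire_summary.get("n_functional_mires", []))
    )

    rows = []
    for a in annotations:
        t = transcripts[a.transcript_id]
        het_ok, het_reason = heterozygosity_filter(a.variant, cfg)
        expr_rec = abundance.get(t.gene_id) or abundance.get(t.transcript_id)
        expr_applicable = expr_rec is not None
        expr_ok = expression_filter(expr_rec, cfg) if expr_applicable else True
        len_ok = candidate_filter(a, cfg)
        n_mires = int(functional_counts.get(a.transcript_id, 0))
        overall = bool(het_ok and expr_ok and len_ok and n_mires >= 1)
        rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": a.transcript_id,
                "variant": a.variant.key,
                "variant_id": a.variant.variant_id,
                "codon_index": a.codon_index,
                "junction_distance_nt": a.junction_distance_nt,
                "nmd_class": a.nmd_class,
                "ejc_nmd_sensitive": a.ejc_nmd_sensitive,
                "het_pass": het_ok,
                "het_reason": het_reason,
                "expression_pass": expr_ok,
                "expression_applicable": expr_applicable,
                "ptc_stop_start": a.ptc_stop_interval[0],
                "ptc_stop_end": a.ptc_stop_interval[1],
                "ptc_stop_length_nt": a.ptc_stop_length_nt,
                "length_pass": len_ok,
                "n_functional_mires": n_mires,
                "surveillance_candidate": overall,
            }
        )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "transcript_id", "variant", "variant_id", "codon_index",
            "junction_distance_nt", "nmd_class", "ejc_nmd_sensitive", "het_pass",
            "het_reason", "expression_pass", "expression_applicable",
            "ptc_stop_start", "ptc_stop_end", "ptc_stop_length_nt", "length_pass",
            "n_functional_mires", "surveillance_candidate",
        ],
    ).sort_values(["gene_id", "transcript_id", "variant"], kind="stable").reset_index(drop=True)
    logger.info(
        "stage filter: %d het, %d expressed, %d length, %d candidates",
        int(candidates.get("het_pass", pd.Series(dtype=bool)).sum()),
        int(candidates.get("expression_pass", pd.Series(dtype=bool)).sum()),
        int(candidates.get("length_pass", pd.Series(dtype=bool)).sum()),
        int(candidates.get("surveillance_candidate", pd.Series(dtype=bool)).sum()),
    )

    retention_df = analyze_retention(
        transcripts, inputs.genome, inputs.retention or [], inputs.clip or [], cfg,
        mirnas=inputs.mirnas,
    )
    logger.info("stage retention: %d isoforms, %d candidates",
                len(retention_df), int(retention_df["candidate"].sum()) if len(retention_df) else 0)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_snvs": len(inputs.snvs),
        "n_nonsense": len(annotations),
        "n_het_pass": int(candidates["het_pass"].sum()) if len(candidates) else 0,
        "n_expression_pass": int(candidates["expression_pass"].sum()) if len(candidates) else 0,
        "n_length_pass": int(candidates["length_pass"].sum()) if len(candidates) else 0,
        "n_ejc_nmd_sensitive": int(candidates["ejc_nmd_sensitive"].sum()) if len(candidates) else 0,
        "n_functional_mire_sites": int(sites["functional"].sum()) if len(sites) else 0,
        "n_surveillance_candidates": int(candidates["surveillance_candidate"].sum()) if len(candidates) else 0,
        "n_retention_isoforms": len(retention_df),
        "n_retention_candidates": int(retention_df["candidate"].sum()) if len(retention_df) else 0,
    }

    result = {
        "candidates": candidates,
        "sites": sites,
        "retention": retention_df,
        "summary": summary,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False, lineterminator="\n")
        sites.to_csv(outdir / "mire_sites.tsv", sep="\t", index=False, lineterminator="\n")
        retention_df.to_csv(outdir / "retention.tsv", sep="\t", index=False, lineterminator="\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result


def load_config(path: str | Path) -> ThresholdsConfig:
    """Flat key=value config file -> ThresholdsConfig (unknown keys error)."""
    kwargs: dict = {}
    fields = ThresholdsConfig.__dataclass_fields__
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{i}: expected key=value")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{i}: unknown threshold {key!r}")
            ftype = fields[key].type
            if ftype == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return ThresholdsConfig(**kwargs)
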
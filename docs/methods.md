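# Methods

## Model

A transcript is an ordered set of exons on a genome with a CDS interval in
transcript coordinates. All coordinates are 0-based half-open; transcript
coordinates run 5′→3′ in mRNA orientation on both strands; the CDS interval
*includes* the native stop codon (`cds_end` is just past it). This last
convention makes the PTC-STOP arithmetic explicit: for a PTC at codon
index *k* in a CDS of *n* codons (native stop at index *n* − 1), the
PTC-STOP region is `[cds_start + 3(k+1), cds_end − 3)` with length
3(*n* − 1 − *k* − 1) nt.

A nonsense SNV is one whose strand-adjusted substitution converts a sense
codon into TAA/TAG/TGA. Classification compares the reference and mutated
codon: stop→non-stop is a stop loss, non-stop→stop is nonsense, equal
translation is synonymous, otherwise missense; positions outside the CDS
(including intronic positions) are noncoding/UTR. A VCF REF base that
disagrees with the genome is an error, never silently reinterpreted.

### EJC-NMD 50-nt rule

The junction distance is the number of transcript nucleotides from the
base immediately after the PTC codon's last base up to the final exon–exon
junction. A PTC is EJC-NMD-sensitive iff this distance is ≥ 50 nt
(`ejc_min_distance_nt`) and the codon ends at or before the junction;
PTCs in the last exon and single-exon transcripts are never sensitive
(there is no junction downstream, reported as distance `None`). The
measurement anchor (codon end) and the inclusivity of the boundary are
genuinely underdetermined choices; the anchor is fixed at the codon end
and the boundary is inclusive by default, with `ejc_inclusive=False`
switching to a strict reading (> 50). Every EJC-NMD-sensitive PTC is also
surveillance-sensitive — the two mechanisms are additive, so `nmd_class`
partitions annotations into `ejc_nmd_and_mirna_surveillance` versus
`mirna_surveillance_only`.

### Seed matching and the 10-nt rule

The seed of a miRNA is its 5′ nucleotides 2–7; the match motif is their
reverse complement written 5′→3′ in mRNA-sense DNA (let-7a
UGAGGUAGUAGGUUGUAUAGUU → motif TACCTC). A miRE is any exact 6-mer
occurrence of the motif — overlapping occurrences are all reported,
wobble pairing and longer site classes are deliberately out of scope
because the screen is defined by the perfect 2–7 match. Site distance is
the number of nucleotides strictly between the PTC codon's last base and
the match's first base. A site is functional iff it lies in the redefined
3′UTR (fully inside the PTC-STOP region, or in the annotated 3′UTR) at a
distance ≥ 10 nt (`mire_min_distance_nt`). Sites 5′ of the PTC are
labeled `ORF_UPSTREAM_OF_PTC` and never functional (masked by translating
ribosomes); a site overlapping the PTC codon itself is treated as
upstream; a site overlapping the native stop codon keeps the `PTC_STOP`
label but is not functional under the default fully-inside rule.
Scanning is mRNA-sense only, over the `top_n_mirnas` (default 150) most
abundant miRNAs, ties at the cutoff broken by lexicographic id.

### Filters

* Heterozygosity: PTC-allele reads / WT-allele reads within
  [0.7, 1.3], both bounds inclusive. WT depth 0 or unavailable depths
  fail with an explicit reason.
* Expression: abundance strictly greater than `expression_min`
  (default 1.0, in the input table's unit). The cutoff is configurable
  because "actively expressed" has no canonical value; when no abundance
  table is supplied the filter is recorded as not applicable and does not
  veto a candidate.
* Candidate length: PTC-STOP region strictly longer than 400 nt.
* When several isoforms carry the same variant, the one with the longest
  PTC-STOP region is reported (ties by transcript id for determinism).

A surveillance candidate passes every applicable filter and carries at
least one functional miRE.

### Intron retention

A retained-intron isoform is the spliced transcript with one intron's
sequence inserted at its junction; positions 3′ of the junction shift by
the intron length. The isoform's PTC is the first stop codon reached by
translating from the start codon — inside the intron (in-frame stop),
in the shifted downstream frame (non-3n intron), or absent (3n intron
with no stop, reading through to the native stop). The "native stop" of
a frame-shifted isoform is the annotated stop's coordinate position, not
a frame-correct stop; this matches how the retained-intron PTC-STOP
length is used downstream. Isoforms pass with retention level strictly
above 0.05. CLIP support counts strand-matched peaks overlapping ≥ 1 nt
of the genomic projection of the isoform PTC-STOP region — the
projection spans exonic and intronic pieces, and a peak crossing a piece
boundary counts once. Retention levels are consumed as input; one
retained intron per isoform is modeled.

### Reporter designer

Constructs are mature-mRNA parts (5′UTR, CDS with stop, 3′UTR) plus
introns anchored at junctions; every edit is logged and constructs can be
lowered to a toy genome + transcript so the annotation pipeline runs on
them directly. Numerical/design choices:

* Non-3n in-frame inserts are 3′-padded with A's, or C's if the pad would
  create a stop in the padded codon (the flanking cloning bases of real
  constructs are not specified anywhere, so the padding is this package's
  choice).
* `introduce_ptc` enumerates 1- then 2-base substitutions, positions left
  to right, bases A<C<G<T; the first stop wins. Codons that need three
  edits (e.g. CCC — no stop codon contains C) raise an error carrying the
  enumerated minimum.
* Synonymous seed disruption enumerates all C(6,2)×9 two-base
  substitutions in the 6-mer, keeps those with unchanged translation that
  abolish the match (including shifted re-creations in a ±5-nt window),
  prefers single-codon solutions, and is deterministic; seeds spanning
  only Met/Trp codons correctly return "no solution".
* A compensatory mimic replaces miRNA bases 2–7 with the reverse
  complement of the mutated motif, restoring the mutant match and losing
  the wild-type one.
* Splice-site disruption complements the first 2 (donor GT) and last 3
  (acceptor ..AG) intron bases and marks the intron retained.

### Repression ratios

For reporter measurements normalized to internal standards, the
repression ratio is level-without-miRNA / level-with-miRNA, computed for
protein and mRNA; their quotient is the translation-efficiency ratio
(protein yield per mRNA molecule). TE > 1 flags a translational-inhibition
contribution.

## Synthetic data: what it emulates and what it does not

The generator builds multi-exon protein-coding genes (ATG…stop, no
internal stops, GT..AG introns) on both strands of toy contigs, and plants
items whose expected verdicts straddle every rule boundary; the defaults
are the study conditions and include the characteristic geometries (a
miRE 16 nt downstream of a last-exon PTC; a PTC 11 nt upstream of the
final junction; a 738-nt PTC-STOP region; a retained intron creating a
PTC 505 nt upstream of a let-7a site). Allele depths are exact integer
pairs realizing the target ratios (e.g. 69/100), with no sampling noise,
so the heterozygosity boundary is probed exactly. Motif planting rejects
accidental extra matches of the planted miRNA inside the PTC-STOP region
and repairs any in-frame stop a placement would create in the reference
ORF.

What passing on this data does **not** show: the toy genome has none of
the complications of a real one — no overlapping genes or isoform
ambiguity beyond what is planted, no alignment or variant-calling error
(depths are given, not estimated), no sequencing noise in retention
levels, uniform base composition, and miRNA abundances with clean,
distinct ranks. Chance seed matches of the 150 random background miRNAs
do occur in PTC-STOP regions, as they would in real sequence; the
ground-truth check therefore verifies every planted verdict exactly
rather than forbidding unplanted sites.

Problem sizes: the default bundle has 12 genes (~200 codons each), 300
miRNAs, 6 variants and 4 retention isoforms; the oracle suites use 1,000
random scanner pairs and 500 random transcripts/isoforms; end-to-end
recovery runs 5 seeds. These sizes make every rule boundary observable
while keeping the full suite fast and deterministic.

## File formats

FASTA (multi-record, lowercase normalized), GTF (1-based inclusive,
converted at the parser boundary; exon + CDS features; the dialect
written here includes the stop codon in CDS records, and a GTF whose CDS
excludes it is rejected by the ATG/stop validation rather than
mis-annotated), VCF 4.x with AD-style depths (REF-first by default,
`ad_order` switches; multi-allelic rows split; indels skipped with a
warning), BED6, and header-bearing TSVs. All output is LF-terminated with
stable sort keys, so identical inputs yield byte-identical outputs.

## Known limitations

Long-3′UTR and uORF NMD triggers are not modeled; frameshift indels are
out of scope (SNVs only); thermodynamic duplex stability and conservation
play no part in site calling; only one retained intron per isoform; no
read-level simulation. The expression cutoff and the exact 50-nt anchor
are documented choices, configurable where the underlying definition is
underdetermined.
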
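# Methods

## Model and procedure

`majorref` treats a population VCF as a catalogue of sites where a linear
reference assembly may carry the population minor allele. The pipeline has
four stages, each a pure function of its inputs.

**Selection.** Records are classified into SNP, INDEL, SNP_INDEL (a site
mixing a single-base substitution allele with a length-changing allele),
MNP (equal-length multi-base substitution) and SV (any symbolic or
breakend allele). Per-allele alternate frequencies come from INFO `AF`;
when absent they are derived from genotype columns as alternate-allele
count over called alleles (records with neither are skipped and tallied).
The single allele with AF strictly greater than the threshold (default
0.5; equality is never selected) is extracted and minimized: shared
trailing bases are trimmed, then shared leading bases, always retaining
one anchor base when an allele would otherwise empty. Because frequencies
sum to at most 1, at most one allele per record can exceed 0.5; a record
claiming two is rejected as corrupted. SV records are counted but never
applied — replacing structural alleles is not attempted.

**Conflict resolution.** Accepted edits whose minimal REF intervals
(0-based, half-open) overlap cannot both be applied. Candidates are ranked
by allele frequency descending, then single-base substitutions before
equal-length substitutions before length-changing edits, then position;
each winner suppresses every remaining overlapping candidate. For the
common pairwise case this is exactly "highest AF wins"; in a chain
A–B–C where the winner overlaps only one loser, the far member survives,
keeping the output non-overlapping and the procedure idempotent. Every
drop is logged with the losing allele and frequency.

**Application.** Edits are applied in one left-to-right pass with a
running offset. REF must match the genome case-insensitively
(soft-masking tolerated); replacement text is written uppercase with
surrounding case preserved (`--uppercase-all` fully unmasks, for
workflows that want a case-free output). Complex substitutions are applied
natively rather than decomposed. The edit log records, for every edit,
the replaced span in the source assembly and the replacement span in the
output, and `verify_edits` independently re-checks every logged span and
every inter-edit segment against both genomes before anything downstream
runs. Edits falling inside assembly N runs would be applied literally
with a warning; the synthetic genomes contain no N bases.

**Coordinate map and chain.** The edit log fully determines the pairwise
alignment of the two assemblies. An edit with REF length r and ALT length
a keeps its first min(r, a) bases aligned (substitutions live inside
aligned blocks, as chain alignments tolerate mismatches) and breaks the
block for the remaining |r − a| one-sided bases. The map is the resulting
list of ungapped blocks per chromosome, strictly increasing on both axes;
lifting is binary search plus a constant offset. One-sided gaps return an
explicit UNMAPPED outcome (reason `INSERTED_IN_SOURCE`); out-of-range
positions raise. The chain file is serialized in the UCSC dialect with
target = new (normalized) assembly and query = old, both strands `+`
(this edit model can never produce inversions or translocations, hence
the strand restriction is lossless); `--swap` writes the reverse chain.
The chain score is not meaningful for analytically constructed chains and
is set to the total aligned length; chain consumers ignore it. A
deliberately independent `ChainLifter` reconstructs intervals purely from
the serialized header and body triplets, the way a generic liftOver
consumer would, and `concordance_check` compares it against the direct
map position-by-position, requiring agreement on unmapped outcomes too.

**VCF liftover semantics.** Only positions are lifted; REF/ALT text is
never rewritten, so records lifted onto the other assembly may disagree
with its sequence — that is deliberate, and the comparator reconciles it
downstream. A record whose anchor base is unmapped goes to the unmapped
set; a deletion whose anchor maps but whose REF span crosses a one-sided
gap is lifted with a `partial` warning flag rather than dropped (the
conservative choice: the event is still anchored in both frames).

## Annotation migration

Gene models are genePred-extended rows (optional leading bin column
auto-detected and preserved; comma-terminated list dialect kept on
output). Lifting moves every boundary through the map; a boundary inside
a deleted region snaps toward the feature interior — starts right, ends
left — and flags the model (`snapped`). An exon losing all bases is
removed (`exon_lost`); a transcript losing all exons is reported
unmapped. Two repair rules follow:

1. A 2–8 bp insertion present in the source assembly relative to the true
   mRNA is typically annotated as a tiny intron. When the corresponding
   major deletion removes those bases, the lifted intron length becomes 0
   and the flanking exons are merged (`merge_threshold` 0 by default;
   `--min-intron N` also merges residual 1..N bp introns, for data where
   the deletion and the annotated intron do not coincide exactly).
2. The mirror case — source assembly missing bases mid-exon, annotated as
   two abutting exons — is detected by a zero-length *source* intron:
   bases inserted between abutting exons are absorbed into the upstream
   exon during lifting, producing the same zero-length lifted intron for
   the merge pass.

Frames are then recomputed: walking exons in transcription order, a
coding exon's frame is the cumulative count of preceding CDS bases mod 3;
non-coding exons get −1. The sanity check extracts each transcript
(concatenated exon slices, reverse-complemented on the − strand) and
translates its CDS with the standard code from the first coding exon's
frame offset (trailing stop removed, internal stop truncates with a log
line, ambiguous bases translate to X), then compares both levels
case-insensitively against reference mRNA/protein sets. Transcripts
absent from the reference sets are SKIPPED and excluded from the
percentages; models that still mismatch after the repair pass can be
labeled UNFIXED — mirroring real annotation curation, where a residue of
out-of-frame cases resists mechanical repair and the honest output is an
explicit label rather than a silent fix.

## Variant-set comparison

Calls are kept when QUAL > 10 and DP > 3, both strict, a missing field
failing the filter. Normalization trims shared trailing bases, extending
left through the genome whenever an allele would empty — which left-shifts
indels through repeats — then trims shared leading bases to one anchor;
the result is minimal and leftmost. Complex records are decomposed along
a minimum-unit-cost alignment (match 0, mismatch −1, gap −1) into SNP
components and simple INDEL components; indel components anchor on the
true reference base adjacent to the gap (following base when the gap
opens the alignment), so a component's REF always matches the reference
even when a SNP shares the anchor position. Decomposition conserves total
edit distance, which the tests verify against an independent
sequence-alignment library.

Matching is per class and one-to-one. SNPs match on chromosome+position
(position mode) or additionally on alleles, where an exchanged REF/ALT
pair counts as the same variant — a heterozygous site called against two
references that differ at that base appears exactly so. INDELs match when
their REF intervals, padded by `indel_window` (default 0: plain interval
overlap; the vicinity radius is exposed rather than hard-coded because
overlapping placements already capture the common case), overlap; each
record pairs greedily with the nearest-position unmatched partner,
leftmost on ties. The report gives, per class, totals, common and unique
counts, FP% = 100·unique_I/total_I and FN% = 100·unique_II/total_II,
rounded to 2 decimals by default (`--decimals 3` for finer tables); a
zero total reports NA.

## Synthetic scenarios

The generator emulates the structure of a population resource applied to
a reference, not its scale. A scenario (all parameters in
`ScenarioSpec`, everything a deterministic function of `seed`) contains:

- a random multi-chromosome genome (default 12 kb + 8 kb) with ~5%
  soft-masked runs;
- a population VCF whose per-record winning frequencies are allocated
  exactly (not sampled Bernoulli): a fraction above 0.5 (default 0.5,
  drawn U(0.55, 0.95)), of which a sub-fraction near fixation
  (U(0.985, 0.999), emulating residual assembly errors that population
  data exposes), the rest below (U(0.05, 0.45)); ~15% multi-allelic
  records (second allele U(0.01, min(0.3, headroom)), never violating
  Σf ≤ 1); mixed SNP+insertion sites; symbolic SV records; and co-located
  SNP-inside-deletion conflict pairs with distinct above-threshold
  frequencies;
- gene cassettes written into the genome: a designed ORF (ATG + non-stop
  codons + TAA, 40–70 codons) with UTRs, 2–4 exons and real introns, on
  both strands, carrying planted defects — 2–8 bp junk insertions inside
  the CDS (annotated as introns, each paired with a major deletion) and
  missing-base gaps (annotated as abutting exons, paired with a major
  insertion). Companion mRNA/protein files are the designed sequences,
  i.e. the post-edit truth by construction;
- two call sets with exact planted per-class common/unique counts,
  including REF/ALT-swap pairs and overlapping-INDEL pairs.

Every output carries a truth manifest (expected edit set after conflict
resolution, per-class counts, planted callset counts) computed from
generation intent, so tests assert against construction, never against a
re-derivation. What the generator does **not** emulate: linkage and
haplotype structure, realistic allele-frequency spectra, N gaps,
alternative/patch contigs, splice-site motifs, read-level errors, or the
scale of a real genome — so passing tests demonstrate the correctness of
the bookkeeping (selection, editing, coordinate algebra, frame repair,
set reconciliation), not performance or robustness on full-size
real-world inputs.

## Numerical and design choices

- Coordinates are 0-based half-open internally; VCF I/O is 1-based; chain
  files follow the 0-based UCSC convention. Frequencies are compared with
  strict inequalities exactly as stated; the Σf ≤ 1 check tolerates 1e-6.
- Multi-allelic table counting uses per-allele frequencies (a record is
  selected if *its winning allele* exceeds the threshold), matching the
  per-allele extraction wording of the construction procedure.
- Tie-breaks are total orders everywhere (documented in each function) so
  reruns are byte-identical; the generators allocate category counts
  exactly and avoid ties by redrawing.
- Problem sizes: the shared test scenario uses a 20 kb genome with ~240
  population records and 6 gene models; the selector/oracle equivalence
  test uses 10⁴ records on 400 kb; the liftover cross-validation uses a
  100 kb genome, >1,000 applied edits and 12,000 lifted positions. These
  sizes exercise every code path (multi-chromosome, multi-allelic,
  co-location chains, both strands, both defect kinds) while keeping the
  whole suite around ten seconds.

## Known limitations

- Structural variants are never applied; the chain model forbids strand
  flips and inter-chromosomal events by construction.
- The comparator implements only the stated reconciliation rules
  (position, allele swap, INDEL vicinity); genuinely ambiguous borderline
  cases remain unique rather than being adjudicated heuristically.
- Annotation repair is mechanical; transcripts that remain inconsistent
  after intron collapse and frame recomputation are labeled UNFIXED, not
  edited further.
- Genotype-level concordance (GT comparison) and multi-sample VCFs are
  out of scope.
- Applying the toolkit to a full-size population release (tens of
  millions of records) is supported by design — every stage is linear or
  n log n — but exercised here only at synthetic scale.
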
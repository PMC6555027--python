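"""Selection of population major alleles from a variant call file.

A linear reference assembly carries a single base (or sequence) at every
position; at polymorphic sites that base is sometimes the *minor* allele of
the population.  This module parses a population VCF carrying per-allele
alternate allele frequencies (INFO ``AF``), classifies each record into the
five-way taxonomy SNP / INDEL / SNP_INDEL / MNP / SV, and extracts the set of
alternate alleles with AF strictly greater than a threshold (default 0.5) —
the positions where the reference harbors the minor allele.  Overlapping
candidate replacements (e.g. a SNP inside the span of a deletion) are
resolved by keeping the highest-frequency allele, so the final edit set is
non-overlapping and can be applied to the genome in one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

# Variant classes
SNP = "SNP"
INDEL = "INDEL"
SNP_INDEL = "SNP_INDEL"
MNP = "MNP"
SV = "SV"
CLASSES = (SNP, INDEL, SNP_INDEL, MNP, SV)

AF_TOLERANCE = 1e-6


class MalformedRecordError(ValueError):
    """Record violates basic VCF shape (empty ALT list, symbolic REF...)."""


class ImpossibleFrequenciesError(ValueError):
    """Two alternate alleles both exceed 0.5 — frequencies cannot sum > 1."""


def is_symbolic(allele: str) -> bool:
    """True for symbolic / breakend / overlap-placeholder alleles."""
    return (
        allele.startswith("<")
        or "[" in allele
        or "]" in allele
        or allele in ("*", ".")
    )


@dataclass(frozen=True)
class PopulationVariant:
    """One population VCF record with per-allele alternate frequencies."""

    chrom: str
    pos: int  # 1-based
    vid: str
    ref: str
    alts: tuple[str, ...]
    alt_freqs: tuple[float, ...]
    vclass: str

    def __post_init__(self):
        if len(self.alts) != len(self.alt_freqs):
            raise MalformedRecordError(
                f"{self.chrom}:{self.pos}: {len(self.alts)} ALTs but "
                f"{len(self.alt_freqs)} frequencies"
            )
        if self.pos < 1:
            raise MalformedRecordError(f"position {self.pos} < 1")
        if not self.ref or is_symbolic(self.ref):
            raise MalformedRecordError(f"bad REF {self.ref!r}")
        if sum(self.alt_freqs) > 1 + AF_TOLERANCE:
            raise MalformedRecordError(
                f"{self.chrom}:{self.pos}: allele frequencies sum to "
                f"{sum(self.alt_freqs):.6f} > 1"
            )

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1


@dataclass(frozen=True)
class MajorAlleleEdit:
    """A single accepted replacement, in minimal (trimmed) representation."""

    chrom: str
    pos: int  # 1-based position of the minimal edit
    ref: str
    alt: str
    af: float
    source_class: str
    source_id: str = "."

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open span of the minimal REF allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)

    def shape_rank(self) -> int:
        """Tie-break order: SNP < MNP < length-changing."""
        if len(self.ref) == len(self.alt):
            return 0 if len(self.ref) == 1 else 1
        return 2


@dataclass
class SelectionSummary:
    """Per-class bookkeeping mirroring a selection-count table."""

    totals: dict[str, int] = field(default_factory=dict)
    multiallelic_totals: dict[str, int] = field(default_factory=dict)
    selected: dict[str, int] = field(default_factory=dict)
    multiallelic_selected: dict[str, int] = field(default_factory=dict)
    dropped_conflicts: int = 0
    no_frequency: int = 0

    def as_dict(self) -> dict:
        return {
            "totals": dict(self.totals),
            "multiallelic_totals": dict(self.multiallelic_totals),
            "selected": dict(self.selected),
            "multiallelic_selected": dict(self.multiallelic_selected),
            "dropped_conflicts": self.dropped_conflicts,
            "no_frequency": self.no_frequency,
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class\ttotal\tmultiallelic_total\tselected\t"
                     "multiallelic_selected\n")
            for c in CLASSES:
                fh.write(
                    f"{c}\t{self.totals.get(c, 0)}\t"
                    f"{self.multiallelic_totals.get(c, 0)}\t"
                    f"{self.selected.get(c, 0)}\t"
                    f"{self.multiallelic_selected.get(c, 0)}\n"
                )
            fh.write(f"#dropped_conflicts\t{self.dropped_conflicts}\n")
            fh.write(f"#no_frequency\t{self.no_frequency}\n")


def classify_variant(ref: str, alts) -> str:
    """Classify a record into SNP / INDEL / SNP_INDEL / MNP / SV.

    SV wins if any ALT is symbolic; SNP_INDEL marks sites mixing a
    single-base substitution allele with a length-changing allele; MNP is an
    equal-length multi-base substitution; INDEL any length change; SNP else.
    """
    alts = list(alts)
    if not alts:
        raise MalformedRecordError("empty ALT list")
    if any(is_symbolic(a) for a in alts):
        return SV
    snp_like = any(len(a) == len(ref) == 1 for a in alts)
    len_changing = any(len(a) != len(ref) for a in alts)
    if snp_like and len_changing:
        return SNP_INDEL
    if any(len(a) == len(ref) > 1 for a in alts):
        return MNP
    if len_changing:
        return INDEL
    return SNP


def trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimize a REF/ALT pair: trim shared suffix then prefix, keeping one
    anchor base when either allele would otherwise become empty (VCF style).
    Returns the (possibly advanced) 1-based position with trimmed alleles."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def select_major_allele(v: PopulationVariant,
                        threshold: float = 0.5) -> MajorAlleleEdit | None:
    """Return the minimized edit for the single ALT with AF > ``threshold``,
    or None when no allele exceeds it.  SV-class records are never selected
    (structural replacement is deferred).  With threshold >= 0.5 two
    qualifying alleles are impossible and raise."""
    if v.vclass == SV:
        return None
    winners = [
        (a, f) for a, f in zip(v.alts, v.alt_freqs)
        if f > threshold and not is_symbolic(a)
    ]
    if not winners:
        return None
    if len(winners) > 1:
        if threshold >= 0.5:
            raise ImpossibleFrequenciesError(
                f"{v.chrom}:{v.pos}: {len(winners)} alleles with AF > "
                f"{threshold}"
            )
        winners.sort(key=lambda w: -w[1])
    alt, af = winners[0]
    pos, ref, alt = trim_allele(v.pos, v.ref.upper(), alt.upper())
    if ref == alt:
        log.warning("%s:%s: ALT identical to REF after trimming; skipped",
                    v.chrom, v.pos)
        return None
    return MajorAlleleEdit(v.chrom, pos, ref, alt, af, v.vclass, v.vid)


def resolve_colocated(
    edits: list[MajorAlleleEdit],
) -> tuple[list[MajorAlleleEdit], list[MajorAlleleEdit]]:
    """Resolve overlapping candidate edits on one chromosome.

    Candidates are ranked by allele frequency (descending), then SNP-shape
    before MNP before length-changing, then lowest position; each winner
    suppresses every remaining candidate whose minimal REF interval overlaps
    it.  Returns (kept sorted by position, dropped)."""
    order = sorted(
        edits, key=lambda e: (-e.af, e.shape_rank(), e.pos, len(e.ref))
    )
    tree = IntervalTree()
    kept: list[MajorAlleleEdit] = []
    dropped: list[MajorAlleleEdit] = []
    for e in order:
        s, t = e.interval
        if tree.overlap(s, t):
            dropped.append(e)
            log.info("dropped colocated edit %s:%s %s>%s (af %.3f)",
                     e.chrom, e.pos, e.ref, e.alt, e.af)
        else:
            tree.addi(s, t, e)
            kept.append(e)
    kept.sort(key=lambda e: e.pos)
    dropped.sort(key=lambda e: e.pos)
    return kept, dropped


def resolve_all(
    edits: list[MajorAlleleEdit],
) -> tuple[list[MajorAlleleEdit], list[MajorAlleleEdit]]:
    """Chromosome-grouping wrapper around :func:`resolve_colocated`."""
    by_chrom: dict[str, list[MajorAlleleEdit]] = {}
    for e in edits:
        by_chrom.setdefault(e.chrom, []).append(e)
    kept, dropped = [], []
    for chrom in sorted(by_chrom):
        k, d = resolve_colocated(sorted(by_chrom[chrom], key=lambda e: e.pos))
        kept.extend(k)
        dropped.extend(d)
    return kept, dropped


def summarize_selection(variants, edits, dropped=(),
                        no_frequency: int = 0) -> SelectionSummary:
    """Tabulate per-class totals and selected counts.

    ``edits`` are the kept edits; a record counts as selected when one of its
    alleles survived into the kept set (matched by source record id)."""
    s = SelectionSummary(no_frequency=no_frequency,
                         dropped_conflicts=len(list(dropped)))
    for c in CLASSES:
        s.totals[c] = 0
        s.multiallelic_totals[c] = 0
        s.selected[c] = 0
        s.multiallelic_selected[c] = 0
    multi_by_id: set[tuple[str, str]] = set()
    multi_by_pos: set[tuple[str, int]] = set()
    for v in variants:
        s.totals[v.vclass] += 1
        if v.multiallelic:
            s.multiallelic_totals[v.vclass] += 1
            if v.vid != ".":
                multi_by_id.add((v.chrom, v.vid))
            else:
                multi_by_pos.add((v.chrom, v.pos))
    for e in edits:
        s.selected[e.source_class] += 1
        # trimming may advance pos, so prefer record-id matching
        if (e.chrom, e.source_id) in multi_by_id or \
           (e.source_id == "." and (e.chrom, e.pos) in multi_by_pos):
            s.multiallelic_selected[e.source_class] += 1
    return s


# ---------------------------------------------------------------------------
# VCF I/O


def read_population_vcf(path) -> tuple[list[PopulationVariant], int]:
    """Read a population VCF into :class:`PopulationVariant` records.

    Per-allele frequencies come from INFO ``AF``; when absent they are
    derived from genotype columns (alt allele count / called allele count).
    Records with neither are skipped and tallied; returns
    (variants, n_no_frequency)."""
    import pysam

    variants: list[PopulationVariant] = []
    no_freq = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = tuple(rec.alts or ())
            if not alts:
                log.warning("%s:%s: record without ALT skipped",
                            rec.chrom, rec.pos)
                no_freq += 1
                continue
            afs = rec.info.get("AF")
            if afs is not None:
                if not isinstance(afs, tuple):
                    afs = (afs,)
                freqs = tuple(float(a) for a in afs)
            else:
                freqs = _freqs_from_genotypes(rec, len(alts))
                if freqs is None:
                    log.warning("%s:%s: no AF and no genotypes; skipped",
                                rec.chrom, rec.pos)
                    no_freq += 1
                    continue
            if len(freqs) != len(alts):
                log.warning("%s:%s: AF arity mismatch; skipped",
                            rec.chrom, rec.pos)
                no_freq += 1
                continue
            variants.append(PopulationVariant(
                chrom=rec.chrom, pos=rec.pos,
                vid=rec.id or ".",
                ref=rec.ref, alts=alts, alt_freqs=freqs,
                vclass=classify_variant(rec.ref, alts),
            ))
    return variants, no_freq


def _freqs_from_genotypes(rec, n_alts: int) -> tuple[float, ...] | None:
    counts = [0] * (n_alts + 1)
    called = 0
    for sample in rec.samples.values():
        for a in sample.get("GT", ()):
            if a is None:
                continue
            called += 1
            if 0 <= a <= n_alts:
                counts[a] += 1
    if called == 0:
        return None
    return tuple(counts[i + 1] / called for i in range(n_alts))


def select_from_vcf(path, threshold: float = 0.5, classes=None):
    """End-to-end selection: parse, select, resolve, summarize.

    Returns (kept_edits, dropped_edits, variants, SelectionSummary)."""
    classes = set(classes) if classes else None
    variants, no_freq = read_population_vcf(path)
    candidates = []
    for v in variants:
        if classes is not None and v.vclass not in classes:
            continue
        e = select_major_allele(v, threshold)
        if e is not None:
            candidates.append(e)
    kept, dropped = resolve_all(candidates)
    summary = summarize_selection(variants, kept, dropped, no_freq)
    return kept, dropped, variants, summary


def write_edits_vcf(edits, path, contig_lengths=None) -> None:
    """Write the kept edit set as a single-ALT VCF (the combined file)."""
    from . import io as _io

    rows = [
        (e.chrom, e.pos, e.source_id, e.ref, [e.alt], {"AF": f"{e.af:.6g}"})
        for e in sorted(edits, key=lambda e: (e.chrom, e.pos))
    ]
    _io.write_vcf(path, rows, contig_lengths=contig_lengths)


def write_class_vcfs(variants, out_dir, contig_lengths=None) -> dict:
    """Write one VCF per variant class; returns {class: path}."""
    import os

    from . import io as _io

    paths = {}
    by_class: dict[str, list] = {c: [] for c in CLASSES}
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        af = ",".join(f"{f:.6g}" for f in v.alt_freqs)
        by_class[v.vclass].append(
            (v.chrom, v.pos, v.vid, v.ref, list(v.alts), {"AF": af}))
    os.makedirs(out_dir, exist_ok=True)
    for c, rows in by_class.items():
        p = os.path.join(out_dir, f"{c.lower()}.vcf")
        _io.write_vcf(p, rows, contig_lengths=contig_lengths)
        paths[c] = p
    return paths
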
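"""Migrating genePred gene models onto an edited assembly.

Lifting transcript/exon/CDS boundaries through the coordinate map is only
the first step: a small insertion (2-8 bp) in the source assembly relative
to the true mRNA is typically annotated as a tiny intron, and when the
major-allele edit deletes those bases the intron's lifted length collapses
to zero.  Such spurious introns are removed by merging the flanking exons,
per-exon reading frames are recomputed from the CDS, and the result is
validated by extracting every transcript from the new genome and comparing
mRNA and translated protein against reference sequence sets (the same kind
of sanity check an annotation-database builder runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .liftover import OLD2NEW, CoordinateMap, lift_point

log = logging.getLogger(__name__)


class MalformedRowError(ValueError):
    pass


class UnmappedModelError(ValueError):
    """The whole transcript lies inside a deleted region."""


class NoCdsError(ValueError):
    pass


@dataclass
class GeneModel:
    """A genePred-extended transcript (0-based half-open coordinates)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: list[int]
    exon_ends: list[int]
    score: int = 0
    name2: str = ""
    cds_start_stat: str = "cmpl"
    cds_end_stat: str = "cmpl"
    exon_frames: list[int] = field(default_factory=list)
    bin: int | None = None
    flags: tuple[str, ...] = ()  # migration provenance, not serialized

    @property
    def exon_count(self) -> int:
        return len(self.exon_starts)

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    def exons(self):
        return list(zip(self.exon_starts, self.exon_ends))

    def cds_exon_lengths(self) -> list[int]:
        """Coding bases per exon (exon order, not transcription order)."""
        return [
            max(0, min(e, self.cds_end) - max(s, self.cds_start))
            for s, e in self.exons()
        ]

    def validate(self) -> None:
        if len(self.exon_starts) != len(self.exon_ends):
            raise MalformedRowError(f"{self.name}: ragged exon lists")
        prev = -1
        for s, e in self.exons():
            if not (prev <= s < e):
                raise MalformedRowError(
                    f"{self.name}: exons unsorted or overlapping")
            prev = e
        if not (self.tx_start <= self.cds_start <= self.cds_end
                <= self.tx_end):
            raise MalformedRowError(f"{self.name}: CDS outside transcript")


# ---------------------------------------------------------------------------
# genePred-extended I/O (comma-terminated list dialect, optional bin column)


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def read_genepred(path) -> list[GeneModel]:
    """Read a 15/16-column genePred-extended table; a leading integer bin
    column is auto-detected and preserved."""
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) == 16:
                bin_, f = int(f[0]), f[1:]
            elif len(f) == 15:
                bin_ = None
            else:
                raise MalformedRowError(
                    f"line {ln}: {len(f)} columns (expected 15 or 16)")
            m = GeneModel(
                name=f[0], chrom=f[1], strand=f[2],
                tx_start=int(f[3]), tx_end=int(f[4]),
                cds_start=int(f[5]), cds_end=int(f[6]),
                exon_starts=_parse_int_list(f[8]),
                exon_ends=_parse_int_list(f[9]),
                score=int(f[10]), name2=f[11],
                cds_start_stat=f[12], cds_end_stat=f[13],
                exon_frames=_parse_int_list(f[14]),
                bin=bin_,
            )
            if m.exon_count != int(f[7]):
                raise MalformedRowError(
                    f"line {ln}: exonCount {f[7]} != {m.exon_count} exons")
            m.validate()
            models.append(m)
    return models


def write_genepred(models, path) -> None:
    with open(path, "w") as fh:
        for m in models:
            cols = [
                m.name, m.chrom, m.strand, str(m.tx_start), str(m.tx_end),
                str(m.cds_start), str(m.cds_end), str(m.exon_count),
                "".join(f"{s}," for s in m.exon_starts),
                "".join(f"{e}," for e in m.exon_ends),
                str(m.score), m.name2, m.cds_start_stat, m.cds_end_stat,
                "".join(f"{f}," for f in m.exon_frames),
            ]
            if m.bin is not None:
                cols.insert(0, str(m.bin))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Lifting and error correction


def _lift_start(cmap, chrom, pos0, direction):
    return lift_point(cmap, chrom, pos0, direction, snap="right")


def _lift_end(cmap, chrom, end0, direction):
    """Lift an exclusive end by lifting its last base, snapping left."""
    lifted, snapped = lift_point(cmap, chrom, end0 - 1, direction,
                                 snap="left")
    if lifted is None:
        return None, snapped
    return lifted + 1, snapped


def lift_gene_model(m: GeneModel, cmap: CoordinateMap,
                    direction: str = OLD2NEW) -> GeneModel:
    """Lift all boundary coordinates of a gene model.

    Boundaries falling in a deleted (one-sided) region snap toward the
    feature interior — starts to the next aligned base, ends to the
    previous — and the model is flagged ``snapped``.  Exons whose lifted
    span collapses below one base are removed (flagged ``exon_lost``);
    a transcript wholly inside a deleted region raises
    :class:`UnmappedModelError`."""
    flags: set[str] = set()
    tx_s, sn1 = _lift_start(cmap, m.chrom, m.tx_start, direction)
    tx_e, sn2 = _lift_end(cmap, m.chrom, m.tx_end, direction)
    if tx_s is None or tx_e is None or tx_s >= tx_e:
        raise UnmappedModelError(
            f"{m.name}: transcript has no aligned bases")
    if sn1 or sn2:
        flags.add("snapped")
    starts, ends = [], []
    prev_old_end = None
    for s, e in m.exons():
        ls, sn3 = _lift_start(cmap, m.chrom, s, direction)
        le, sn4 = _lift_end(cmap, m.chrom, e, direction)
        if sn3 or sn4:
            flags.add("snapped")
        if ls is None or le is None or ls >= le:
            flags.add("exon_lost")
            log.warning("%s: exon %d-%d fully deleted; removed", m.name, s, e)
            continue
        # abutting source exons (an exon broken in two by the source
        # assembly): bases inserted between them belong to the exon, so
        # stitch the lifted boundary before the collapse pass
        if prev_old_end is not None and s == prev_old_end and ends:
            ends[-1] = ls
        starts.append(ls)
        ends.append(le)
        prev_old_end = e
    if not starts:
        raise UnmappedModelError(f"{m.name}: all exons deleted")
    if m.coding:
        cds_s, sn5 = _lift_start(cmap, m.chrom, m.cds_start, direction)
        cds_e, sn6 = _lift_end(cmap, m.chrom, m.cds_end, direction)
        if sn5 or sn6:
            flags.add("snapped")
        if cds_s is None or cds_e is None or cds_s >= cds_e:
            cds_s = cds_e = starts[0]
            flags.add("cds_lost")
        cds_s = max(cds_s, starts[0])
        cds_e = min(cds_e, ends[-1])
    else:
        cds_s = cds_e = starts[0]
    lifted = replace(
        m, tx_start=min(tx_s, starts[0]), tx_end=max(tx_e, ends[-1]),
        cds_start=cds_s, cds_end=cds_e,
        exon_starts=starts, exon_ends=ends,
        exon_frames=list(m.exon_frames),
        flags=tuple(sorted(flags)),
    )
    lifted.validate()
    return lifted


def collapse_spurious_introns(m: GeneModel,
                              merge_threshold: int = 0) -> GeneModel:
    """Merge flanking exons across introns of length <= ``merge_threshold``.

    A spurious insertion in the source assembly that a major deletion
    removed leaves a 0-length lifted intron; merging absorbs any inserted
    bases between the abutting exons into one exon.  Merge events are
    logged and flagged on the returned model."""
    starts, ends = [], []
    merges = 0
    for s, e in m.exons():
        if ends and s - ends[-1] <= merge_threshold:
            log.info("%s: merged %d bp intron at %d", m.name, s - ends[-1],
                     ends[-1])
            ends[-1] = e
            merges += 1
        else:
            starts.append(s)
            ends.append(e)
    if merges == 0:
        return m
    out = replace(m, exon_starts=starts, exon_ends=ends,
                  exon_frames=list(m.exon_frames)[:len(starts)],
                  flags=m.flags + (f"merged_introns={merges}",))
    out.validate()
    return out


def recompute_frames(m: GeneModel) -> GeneModel:
    """Recompute per-exon frames: walking exons in transcription order, a
    coding exon's frame is (cumulative CDS bases in preceding exons) mod 3;
    non-coding exons get -1.  Non-coding transcripts get all -1."""
    n = m.exon_count
    frames = [-1] * n
    if m.coding:
        order = range(n) if m.strand == "+" else range(n - 1, -1, -1)
        cds_lens = m.cds_exon_lengths()
        cum = 0
        for i in order:
            if cds_lens[i] > 0:
                frames[i] = cum % 3
                cum += cds_lens[i]
    return replace(m, exon_frames=frames)


# ---------------------------------------------------------------------------
# Sequence extraction and translation


def extract_transcript(m: GeneModel, genome: dict[str, str]) -> str:
    """Concatenate exon slices (reverse-complemented for '-' strand)."""
    chrom = genome[m.chrom]
    if m.tx_end > len(chrom):
        raise MalformedRowError(f"{m.name}: exceeds chromosome bounds")
    seq = "".join(chrom[s:e] for s, e in m.exons()).upper()
    if m.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_sequence(m: GeneModel, genome: dict[str, str]) -> str:
    chrom = genome[m.chrom]
    seq = "".join(
        chrom[max(s, m.cds_start):min(e, m.cds_end)]
        for s, e in m.exons()
        if min(e, m.cds_end) > max(s, m.cds_start)
    ).upper()
    if m.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def first_coding_frame(m: GeneModel) -> int:
    """Frame offset of the first coding exon in transcription order."""
    order = range(m.exon_count) if m.strand == "+" else \
        range(m.exon_count - 1, -1, -1)
    cds_lens = m.cds_exon_lengths()
    for i in order:
        if cds_lens[i] > 0:
            f = m.exon_frames[i] if i < len(m.exon_frames) else 0
            return f if f >= 0 else 0
    return 0


def translate_cds(m: GeneModel, genome: dict[str, str]) -> str:
    """Standard-code translation of the CDS, honoring the first exon's
    frame offset.  The trailing stop is removed; an internal stop truncates
    the protein there (logged).  Ambiguous bases translate to X."""
    if not m.coding:
        raise NoCdsError(f"{m.name}: CDS length 0")
    cds = _cds_sequence(m, genome)
    offset = first_coding_frame(m)
    cds = cds[offset:]
    cds = cds[: len(cds) - len(cds) % 3]
    if not cds:
        return ""
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        log.info("%s: internal stop codon; translation truncated", m.name)
        aa = aa.split("*", 1)[0]
    return aa


# ---------------------------------------------------------------------------
# Sanity check and the migration pipeline


@dataclass
class SanityReport:
    """Exact-match tallies between annotation-derived and reference
    sequences, mirroring an annotation-database build check."""

    n_transcripts: int
    mrna_exact_matches: int
    protein_exact_matches: int
    n_mrna_compared: int
    n_protein_compared: int
    statuses: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def mrna_match_pct(self):
        if self.n_mrna_compared == 0:
            return None
        return round(100 * self.mrna_exact_matches / self.n_mrna_compared, 2)

    @property
    def protein_match_pct(self):
        if self.n_protein_compared == 0:
            return None
        return round(
            100 * self.protein_exact_matches / self.n_protein_compared, 2)

    def as_dict(self) -> dict:
        return {
            "n_transcripts": self.n_transcripts,
            "mrna_exact_matches": self.mrna_exact_matches,
            "protein_exact_matches": self.protein_exact_matches,
            "mrna_match_pct": self.mrna_match_pct
            if self.mrna_match_pct is not None else "NA",
            "protein_match_pct": self.protein_match_pct
            if self.protein_match_pct is not None else "NA",
        }

    def to_tsv(self, path) -> None:
        d = self.as_dict()
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in d.items():
                fh.write(f"{k}\t{v}\n")
            fh.write("transcript\tstatus\treason\n")
            for name, (status, reason) in sorted(self.statuses.items()):
                fh.write(f"{name}\t{status}\t{reason}\n")


def sanity_check(models, genome: dict[str, str], mrna: dict[str, str],
                 proteins: dict[str, str],
                 unfixable: set[str] = frozenset()) -> SanityReport:
    """Compare every model's extracted mRNA and translated protein against
    reference sets (case-insensitive exact string match).  Transcripts
    absent from the reference sets are SKIPPED; percentages are over the
    compared transcripts.  Names in ``unfixable`` that still mismatch are
    labeled UNFIXED."""
    rep = SanityReport(len(list(models)), 0, 0, 0, 0)
    for m in models:
        ref_rna = mrna.get(m.name)
        ref_prot = proteins.get(m.name)
        if ref_rna is None and ref_prot is None:
            rep.statuses[m.name] = ("SKIPPED", "absent from reference sets")
            continue
        problems = []
        if ref_rna is not None:
            rep.n_mrna_compared += 1
            got = extract_transcript(m, genome)
            if got.upper() == ref_rna.upper():
                rep.mrna_exact_matches += 1
            else:
                problems.append("mRNA mismatch")
        if ref_prot is not None and m.coding:
            rep.n_protein_compared += 1
            got = translate_cds(m, genome)
            if got.upper() == ref_prot.upper().rstrip("*"):
                rep.protein_exact_matches += 1
            else:
                problems.append("protein mismatch")
        if not problems:
            rep.statuses[m.name] = ("MATCH", "")
        elif m.name in unfixable:
            rep.statuses[m.name] = ("UNFIXED", "; ".join(problems))
        else:
            rep.statuses[m.name] = ("MISMATCH", "; ".join(problems))
    return rep


def migrate_annotation(models, cmap: CoordinateMap,
                       merge_threshold: int = 0,
                       direction: str = OLD2NEW):
    """Lift, collapse spurious introns and recompute frames for a set of
    gene models.  Returns (migrated models, unmapped model names)."""
    migrated, unmapped = [], []
    for m in models:
        try:
            lifted = lift_gene_model(m, cmap, direction)
        except UnmappedModelError as exc:
            log.warning("%s", exc)
            unmapped.append(m.name)
            continue
        merged = collapse_spurious_introns(lifted, merge_threshold)
        migrated.append(recompute_frames(merged))
    return migrated, unmapped
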
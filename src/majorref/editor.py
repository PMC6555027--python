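"""Applying a non-overlapping edit set to a FASTA genome.

Substituting SNPs leaves the coordinate frame intact, but every applied
insertion or deletion shifts all downstream coordinates, so the editor
maintains a complete log pairing each replaced span in the source assembly
with its span in the output assembly.  That log is the single source of
truth for the coordinate map and chain file built downstream.  Complex
substitutions (multi-base REF and ALT of different lengths) are applied
natively, not decomposed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)


class RefMismatchError(ValueError):
    """An edit's REF allele does not match the genome at its position."""


class OverlappingEditsError(ValueError):
    pass


class UnknownChromError(KeyError):
    pass


@dataclass(frozen=True)
class AppliedEdit:
    """One replacement with its spans in both assemblies (0-based half-open)."""

    chrom: str
    old_start: int
    old_end: int
    new_start: int
    new_end: int
    ref_seq: str
    alt_seq: str
    af: float = 0.0
    source_class: str = "."

    @property
    def delta(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)


@dataclass
class EditLog:
    """Ordered applied edits per chromosome plus both assembly lengths."""

    edits: dict[str, list[AppliedEdit]] = field(default_factory=dict)
    old_lengths: dict[str, int] = field(default_factory=dict)
    new_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, es in self.edits.items():
            delta = 0
            prev_end = -1
            for e in es:
                assert e.old_end - e.old_start == len(e.ref_seq)
                assert e.new_end - e.new_start == len(e.alt_seq)
                assert e.old_start >= prev_end, "edits overlap or unsorted"
                prev_end = e.old_end
                delta += e.delta
            assert self.new_lengths[chrom] == self.old_lengths[chrom] + delta

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.old_lengths:
                fh.write(f"##contig\t{chrom}\t{self.old_lengths[chrom]}\t"
                         f"{self.new_lengths[chrom]}\n")
            fh.write("#chrom\told_start\told_end\tnew_start\tnew_end\t"
                     "ref\talt\tdelta\taf\tclass\n")
            for chrom, es in self.edits.items():
                for e in es:
                    fh.write(
                        f"{e.chrom}\t{e.old_start}\t{e.old_end}\t"
                        f"{e.new_start}\t{e.new_end}\t{e.ref_seq}\t"
                        f"{e.alt_seq}\t{e.delta}\t{e.af:.6g}\t"
                        f"{e.source_class}\n")

    @classmethod
    def from_tsv(cls, path) -> "EditLog":
        logd = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##contig"):
                    _, chrom, old_len, new_len = line.split("\t")
                    logd.old_lengths[chrom] = int(old_len)
                    logd.new_lengths[chrom] = int(new_len)
                    logd.edits.setdefault(chrom, [])
                    continue
                if line.startswith("#") or not line:
                    continue
                (chrom, os_, oe, ns, ne, ref, alt, _delta, af,
                 cls_) = line.split("\t")
                logd.edits.setdefault(chrom, []).append(AppliedEdit(
                    chrom, int(os_), int(oe), int(ns), int(ne), ref, alt,
                    float(af), cls_))
        logd.validate()
        return logd

    def to_json(self, path) -> None:
        obj = {
            "old_lengths": self.old_lengths,
            "new_lengths": self.new_lengths,
            "edits": {
                chrom: [e.__dict__ for e in es]
                for chrom, es in self.edits.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def apply_edits(genome: dict[str, str], edits,
                uppercase_all: bool = False) -> tuple[dict[str, str], EditLog]:
    """Replace every edit's REF span with its ALT in the genome.

    ``edits`` is a list of :class:`~majorref.selector.MajorAlleleEdit`
    (minimal representation, 1-based pos).  REF must match the genome
    case-insensitively (soft-masking tolerated); replacement text is written
    uppercase, surrounding case preserved unless ``uppercase_all``.
    Returns (new genome, :class:`EditLog`)."""
    by_chrom: dict[str, list] = {}
    for e in edits:
        if e.chrom not in genome:
            raise UnknownChromError(e.chrom)
        by_chrom.setdefault(e.chrom, []).append(e)

    new_genome: dict[str, str] = {}
    elog = EditLog()
    for chrom, seq in genome.items():
        elog.old_lengths[chrom] = len(seq)
        chrom_edits = sorted(by_chrom.get(chrom, ()),
                             key=lambda e: e.interval)
        parts: list[str] = []
        applied: list[AppliedEdit] = []
        cursor = 0  # old coordinate
        new_cursor = 0
        for e in chrom_edits:
            s, t = e.interval
            if s < cursor:
                raise OverlappingEditsError(
                    f"{chrom}: edit at {e.pos} overlaps previous edit")
            if t > len(seq):
                raise RefMismatchError(
                    f"{chrom}:{e.pos}: edit extends past chromosome end")
            slice_ = seq[s:t]
            if slice_.upper() != e.ref.upper():
                raise RefMismatchError(
                    f"{chrom}:{e.pos}: genome has {slice_!r}, edit REF is "
                    f"{e.ref!r}")
            if "N" in slice_.upper():
                log.warning("%s:%s: edit inside assembly N bases applied "
                            "literally", chrom, e.pos)
            parts.append(seq[cursor:s])
            new_cursor += s - cursor
            alt = e.alt.upper()
            parts.append(alt)
            applied.append(AppliedEdit(
                chrom, s, t, new_cursor, new_cursor + len(alt),
                slice_, alt, e.af, e.source_class))
            cursor = t
            new_cursor += len(alt)
        parts.append(seq[cursor:])
        out = "".join(parts)
        if uppercase_all:
            out = out.upper()
        new_genome[chrom] = out
        elog.edits[chrom] = applied
        elog.new_lengths[chrom] = len(out)
    elog.validate()
    return new_genome, elog


@dataclass
class VerificationReport:
    ok: bool
    n_edits: int
    n_segments: int
    errors: list[str] = field(default_factory=list)

    @property
    def first_error(self) -> str | None:
        return self.errors[0] if self.errors else None


def verify_edits(new_genome: dict[str, str], elog: EditLog,
                 old_genome: dict[str, str]) -> VerificationReport:
    """Independently re-check an edit log against both genomes.

    Asserts every logged span (REF in the old genome, ALT in the new) and
    that all inter-edit segments are carried over unchanged."""
    errors: list[str] = []
    n_edits = n_segments = 0
    for chrom, old_len in elog.old_lengths.items():
        old = old_genome.get(chrom, "")
        new = new_genome.get(chrom, "")
        if len(old) != old_len:
            errors.append(f"{chrom}: old length {len(old)} != logged "
                          f"{old_len}")
        if len(new) != elog.new_lengths.get(chrom, -1):
            errors.append(f"{chrom}: new length {len(new)} != logged "
                          f"{elog.new_lengths.get(chrom)}")
        cur_old = cur_new = 0
        for e in elog.edits.get(chrom, ()):
            n_segments += 1
            if old[cur_old:e.old_start].upper() != \
                    new[cur_new:e.new_start].upper():
                errors.append(
                    f"{chrom}: inter-edit segment old[{cur_old}:"
                    f"{e.old_start}] differs from new[{cur_new}:"
                    f"{e.new_start}]")
            n_edits += 1
            if old[e.old_start:e.old_end] != e.ref_seq:
                errors.append(
                    f"{chrom}: edit old[{e.old_start}:{e.old_end}] REF "
                    f"mismatch ({e.ref_seq!r})")
            if new[e.new_start:e.new_end] != e.alt_seq:
                errors.append(
                    f"{chrom}: edit new[{e.new_start}:{e.new_end}] ALT "
                    f"mismatch ({e.alt_seq!r})")
            cur_old, cur_new = e.old_end, e.new_end
        n_segments += 1
        if old[cur_old:].upper() != new[cur_new:].upper():
            errors.append(f"{chrom}: trailing segment differs")
    return VerificationReport(not errors, n_edits, n_segments, errors)
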
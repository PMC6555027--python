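"""Normalization, decomposition and set comparison of variant calls.

Two call sets made against different references can only be compared after
(1) quality filtering, (2) reduction of every record to a minimal,
left-aligned representation, (3) decomposition of complex records into
allelic primitives (simple SNPs and simple INDELs), and (4) lifting onto a
common coordinate frame.  Because the lifted records deliberately keep
their original REF/ALT text, comparison is primarily positional, with two
reconciliation rules: a heterozygous site called against the two different
references appears with REF and ALT swapped (counted as the same variant in
allele mode), and INDELs whose REF intervals overlap within a vicinity
window describe the same event.  The report mirrors the usual two-way
accounting: calls unique to the first set are the false positives it
accrues, calls unique to the second are its false negatives.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

POSITION = "position"
ALLELE = "allele"


class SortRequiredError(ValueError):
    pass


class RefMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class CallRecord:
    """A single-ALT variant call."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    dp: int | None = None

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref) == len(self.alt) else "INDEL"

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open REF span."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


def filter_calls(records, min_qual: float = 10, min_dp: int = 3):
    """Keep records with QUAL > min_qual AND DP > min_dp (both strict);
    a missing DP or QUAL fails the filter."""
    return [
        r for r in records
        if r.qual is not None and r.qual > min_qual
        and r.dp is not None and r.dp > min_dp
    ]


def normalize_variant(genome: dict[str, str], r: CallRecord) -> CallRecord:
    """Minimal, left-aligned representation.

    Shared trailing bases are trimmed (extending left through the genome
    when an allele would empty, which left-shifts INDELs through repeats),
    then shared leading bases are trimmed to a single anchor."""
    chrom = genome[r.chrom]
    pos, ref, alt = r.pos, r.ref.upper(), r.alt.upper()
    if chrom[pos - 1:pos - 1 + len(ref)].upper() != ref:
        raise RefMismatchError(
            f"{r.chrom}:{r.pos}: REF {ref!r} does not match genome")
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1
                                                   or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 1:
            pos -= 1
            base = chrom[pos - 1].upper()
            ref, alt = base + ref, base + alt
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(r, pos=pos, ref=ref, alt=alt)


def _align_unit_cost(ref: str, alt: str):
    """Minimum-cost (unit mismatch/indel) alignment columns via Biopython's
    pairwise aligner; returns the aligned ref/alt strings with '-' gaps."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(ref, alt)[0]
    return str(aln[0]), str(aln[1])


def decompose_primitives(r: CallRecord) -> list[CallRecord]:
    """Break a (normalized) record into allelic primitives.

    Equal-length records yield one SNP per differing base.  Complex
    substitutions are decomposed along a minimum-edit-cost alignment into
    SNP components plus simple INDEL components; INDEL anchors use the true
    reference base preceding the gap.  Simple records pass through."""
    ref, alt = r.ref.upper(), r.alt.upper()
    if len(ref) == len(alt):
        if len(ref) == 1:
            return [r]
        return [
            replace(r, pos=r.pos + i, ref=ref[i], alt=alt[i])
            for i in range(len(ref)) if ref[i] != alt[i]
        ]
    if (len(ref) == 1 or len(alt) == 1) and ref[0] == alt[0]:
        return [r]  # simple anchored indel
    a_ref, a_alt = _align_unit_cost(ref, alt)
    out: list[CallRecord] = []
    ri = 0  # consumed ref bases
    i = 0
    while i < len(a_ref):
        cr, ca = a_ref[i], a_alt[i]
        if cr != "-" and ca != "-":
            if cr != ca:
                out.append(replace(r, pos=r.pos + ri, ref=cr, alt=ca))
            ri += 1
            i += 1
            continue
        # gap run: anchored on the previous reference base, or on the
        # following base when the gap opens the alignment (VCF style)
        j = i
        gap_in = "ref" if cr == "-" else "alt"
        while j < len(a_ref) and (a_ref[j] == "-" if gap_in == "ref"
                                  else a_alt[j] == "-"):
            j += 1
        if gap_in == "ref":  # insertion relative to the reference
            inserted = a_alt[i:j]
            if ri > 0:
                out.append(replace(r, pos=r.pos + ri - 1, ref=ref[ri - 1],
                                   alt=ref[ri - 1] + inserted))
            else:
                out.append(replace(r, pos=r.pos, ref=ref[0],
                                   alt=inserted + ref[0]))
        else:  # deletion
            deleted = a_ref[i:j]
            if ri > 0:
                out.append(replace(r, pos=r.pos + ri - 1,
                                   ref=ref[ri - 1] + deleted,
                                   alt=ref[ri - 1]))
            else:
                nxt = ref[ri + (j - i)]
                out.append(replace(r, pos=r.pos, ref=deleted + nxt,
                                   alt=nxt))
            ri += j - i
        i = j
    return out


# ---------------------------------------------------------------------------
# Set comparison


@dataclass
class ClassCounts:
    total_a: int = 0
    total_b: int = 0
    common: int = 0
    unique_a: int = 0
    unique_b: int = 0

    @property
    def fp_pct(self):
        return compute_fp_fn(self.total_a, self.unique_a,
                             self.total_b, self.unique_b)[0]

    @property
    def fn_pct(self):
        return compute_fp_fn(self.total_a, self.unique_a,
                             self.total_b, self.unique_b)[1]


@dataclass
class ComparisonReport:
    per_class: dict[str, ClassCounts] = field(default_factory=dict)

    def as_dict(self, decimals: int = 2) -> dict:
        out = {}
        for c, k in self.per_class.items():
            fp, fn = compute_fp_fn(k.total_a, k.unique_a, k.total_b,
                                   k.unique_b, decimals)
            out[c] = {
                "total_a": k.total_a, "total_b": k.total_b,
                "common": k.common, "unique_a": k.unique_a,
                "unique_b": k.unique_b,
                "fp_pct": fp if fp is not None else "NA",
                "fn_pct": fn if fn is not None else "NA",
            }
        return out

    def to_tsv(self, path, decimals: int = 2) -> None:
        d = self.as_dict(decimals)
        with open(path, "w") as fh:
            fh.write("class\ttotal_a\ttotal_b\tcommon\tunique_a\tunique_b\t"
                     "fp_pct\tfn_pct\n")
            for c, row in d.items():
                fh.write(
                    f"{c}\t{row['total_a']}\t{row['total_b']}\t"
                    f"{row['common']}\t{row['unique_a']}\t{row['unique_b']}\t"
                    f"{row['fp_pct']}\t{row['fn_pct']}\n")


def compute_fp_fn(total_a, unique_a, total_b, unique_b, decimals: int = 2):
    """The two-way percentages: FP% = 100*unique_a/total_a (calls only in
    the first set), FN% = 100*unique_b/total_b.  Zero totals give None."""
    fp = round(100 * unique_a / total_a, decimals) if total_a else None
    fn = round(100 * unique_b / total_b, decimals) if total_b else None
    return fp, fn


def _check_sorted(records, label):
    seen_chroms = set()
    prev_chrom, prev_pos = None, 0
    for r in records:
        if r.chrom != prev_chrom:
            if r.chrom in seen_chroms:
                raise SortRequiredError(f"set {label} not grouped by "
                                        f"chromosome")
            seen_chroms.add(r.chrom)
            prev_chrom, prev_pos = r.chrom, 0
        if r.pos < prev_pos:
            raise SortRequiredError(f"set {label} not sorted at "
                                    f"{r.chrom}:{r.pos}")
        prev_pos = r.pos


def _alleles_compatible(a: CallRecord, b: CallRecord) -> bool:
    """Same alleles, or REF/ALT interchanged (heterozygous-site swap)."""
    pa = (a.ref.upper(), a.alt.upper())
    pb = (b.ref.upper(), b.alt.upper())
    return pa == pb or pa == pb[::-1]


def _match_snps(snps_a, snps_b, mode):
    by_pos: dict[tuple[str, int], list] = {}
    for idx, b in enumerate(snps_b):
        by_pos.setdefault((b.chrom, b.pos), []).append([b, False])
    common = 0
    for a in snps_a:
        for slot in by_pos.get((a.chrom, a.pos), ()):
            b, used = slot
            if used:
                continue
            if mode == ALLELE and not _alleles_compatible(a, b):
                continue
            slot[1] = True
            common += 1
            break
    return common


def _match_indels(indels_a, indels_b, window):
    """Greedy one-to-one pairing of INDELs whose padded REF intervals
    overlap; each a-record takes the nearest-position unmatched b-record,
    ties to the leftmost."""
    by_chrom: dict[str, list] = {}
    for b in indels_b:
        by_chrom.setdefault(b.chrom, []).append(b)
    state = {}
    for chrom, bs in by_chrom.items():
        bs.sort(key=lambda r: r.pos)
        state[chrom] = (bs, [b.pos for b in bs], [False] * len(bs),
                        _max_ref_len(bs))
    common = 0
    for a in indels_a:
        if a.chrom not in state:
            continue
        bs, pos_list, used, max_ref = state[a.chrom]
        a_s, a_e = a.interval
        a_s -= window
        a_e += window
        # bounded candidate neighborhood around the padded interval
        lo = bisect_left(pos_list, a_s - max_ref - window)
        hi = bisect_right(pos_list, a_e + window + 1)
        best = None
        for j in range(lo, hi):
            if used[j]:
                continue
            b_s, b_e = bs[j].interval
            if b_s - window < a_e and a_s < b_e + window:
                d = abs(bs[j].pos - a.pos)
                if best is None or d < best[0] or \
                        (d == best[0] and bs[j].pos < bs[best[1]].pos):
                    best = (d, j)
        if best is not None:
            used[best[1]] = True
            common += 1
    return common


def _max_ref_len(records) -> int:
    return max((len(r.ref) for r in records), default=1)


def compare_sets(set_a, set_b, mode: str = POSITION,
                 indel_window: int = 0) -> ComparisonReport:
    """Compare two normalized, decomposed, sorted call sets per class.

    Position mode matches SNPs on chrom+pos only; allele mode additionally
    requires equal or swapped REF/ALT.  INDELs match by (padded) REF
    interval overlap in both modes, greedily one-to-one."""
    _check_sorted(set_a, "A")
    _check_sorted(set_b, "B")
    report = ComparisonReport()
    for cls in ("SNP", "INDEL"):
        a = [r for r in set_a if r.vclass == cls]
        b = [r for r in set_b if r.vclass == cls]
        if cls == "SNP":
            common = _match_snps(a, b, mode)
        else:
            common = _match_indels(a, b, indel_window)
        report.per_class[cls] = ClassCounts(
            total_a=len(a), total_b=len(b), common=common,
            unique_a=len(a) - common, unique_b=len(b) - common)
    return report


# ---------------------------------------------------------------------------
# VCF input and the full comparison pipeline


def read_calls(path) -> list[CallRecord]:
    """Read a VCF into CallRecords, splitting multi-ALT rows."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            dp = rec.info.get("DP")
            if dp is None and rec.samples:
                sample = next(iter(rec.samples.values()))
                dp = sample.get("DP")
            for alt in rec.alts or ():
                out.append(CallRecord(
                    rec.chrom, rec.pos, rec.ref, alt,
                    qual=rec.qual, dp=int(dp) if dp is not None else None))
    return out


def _trim_local(r: CallRecord) -> CallRecord:
    """Genome-free minimization: trim shared suffix then prefix, keeping a
    single anchor base (no left-alignment)."""
    pos, ref, alt = r.pos, r.ref.upper(), r.alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(r, pos=pos, ref=ref, alt=alt)


def prepare_calls(records, genome: dict[str, str],
                  min_qual: float = 10, min_dp: int = 3,
                  skip_filter: bool = False,
                  lenient: bool = False) -> list[CallRecord]:
    """Filter, normalize and decompose a call set, returning it sorted.

    With ``lenient``, records whose REF does not match the given genome
    (e.g. calls made against a different reference, REF/ALT deliberately
    not rewritten during liftover) are minimized without left-alignment
    instead of aborting."""
    kept = records if skip_filter else filter_calls(records, min_qual,
                                                    min_dp)
    out: list[CallRecord] = []
    for r in kept:
        try:
            norm = normalize_variant(genome, r)
        except RefMismatchError:
            if not lenient:
                raise
            log.info("%s:%s: REF differs from given genome; minimized "
                     "without left-alignment", r.chrom, r.pos)
            norm = _trim_local(r)
        out.extend(decompose_primitives(norm))
    out.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return out
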
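"""Seeded generators for every input the toolkit consumes.

The generators emulate the statistical structure of a population resource
applied to a linear reference: a small multi-chromosome genome; a
population VCF whose per-allele frequency spectrum mixes minor alleles
(AF < 0.5), major alleles (AF > 0.5) and a near-fixed spike (AF ~ 1,
emulating residual sequencing errors in the assembly); multi-allelic sites;
co-located SNP+INDEL conflicts; gene models carrying planted 2-8 bp
spurious introns that coincide exactly with major deletions (and abutting
exons broken by an assembly deletion that a major insertion repairs); and
paired call sets with planted common/unique variants, REF/ALT-swap pairs
and overlapping INDEL pairs.

Every generator is deterministic under the scenario seed, and each output
comes with a truth manifest sufficient to predict downstream module output
exactly, so assertions never depend on re-deriving intent from samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from . import io as _io
from .annotation import GeneModel, recompute_frames
from .comparator import CallRecord
from .selector import (INDEL, MajorAlleleEdit, PopulationVariant,
                       classify_variant)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
          if a + b + c not in STOPS]


class SpecTooDenseError(ValueError):
    """Requested variants exceed the genome's placement capacity."""


@dataclass
class ScenarioSpec:
    """Knobs for one synthetic scenario; all outputs derive from ``seed``."""

    seed: int = 42
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12000, "chr2": 8000})
    # population VCF composition
    n_snp: int = 120
    n_indel: int = 80
    n_mnp: int = 10
    n_snp_indel: int = 8
    n_sv: int = 4
    frac_above: float = 0.5        # records whose top allele has AF > 0.5
    frac_error_spike: float = 0.08  # records with AF ~ 1 (subset of above)
    frac_multiallelic: float = 0.15
    n_colocated: int = 6           # SNP-inside-deletion conflict pairs
    softmask_frac: float = 0.05
    # gene models
    n_genes: int = 6
    n_minus_genes: int = 2
    n_spurious_introns: int = 3    # 2-8 bp junk insertions -> major deletions
    n_exon_splits: int = 1         # missing bases -> major insertions
    # call sets
    n_common_snp: int = 40
    n_common_indel: int = 15
    n_unique_a_snp: int = 8
    n_unique_b_snp: int = 5
    n_unique_a_indel: int = 5
    n_unique_b_indel: int = 4
    n_swap_pairs: int = 6
    n_overlap_indels: int = 5

    def validate(self) -> None:
        for name, frac in (("frac_above", self.frac_above),
                           ("frac_error_spike", self.frac_error_spike),
                           ("frac_multiallelic", self.frac_multiallelic),
                           ("softmask_frac", self.softmask_frac)):
            assert 0 <= frac <= 1, f"{name} outside [0, 1]"
        assert all(length >= 100 for length in self.chrom_lengths.values())
        assert self.frac_error_spike <= self.frac_above


@dataclass
class Manifest:
    """Ground truth for the population VCF: what selection must produce."""

    expected_edits: list[MajorAlleleEdit] = field(default_factory=list)
    expected_dropped: int = 0
    totals: dict[str, int] = field(default_factory=dict)
    selected: dict[str, int] = field(default_factory=dict)
    multiallelic_selected: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "expected_edits": [asdict(e) for e in self.expected_edits],
            "expected_dropped": self.expected_dropped,
            "totals": self.totals,
            "selected": self.selected,
            "multiallelic_selected": self.multiallelic_selected,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _rand_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_genome(spec: ScenarioSpec, rng=None) -> dict[str, str]:
    """Random uppercase genome with optional soft-masked runs."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    genome = {}
    for chrom, length in spec.chrom_lengths.items():
        seq = _rand_seq(rng, length)
        if spec.softmask_frac > 0:
            n_runs = max(1, int(spec.softmask_frac * length / 50))
            for _ in range(n_runs):
                s = int(rng.integers(0, max(1, length - 50)))
                run = int(rng.integers(10, 50))
                seq = seq[:s] + seq[s:s + run].lower() + seq[s + run:]
        genome[chrom] = seq
    return genome


class _Placer:
    """Collision-free placement of variant footprints on a chromosome set."""

    def __init__(self, rng, chrom_lengths, margin: int = 4):
        self.rng = rng
        self.lengths = dict(chrom_lengths)
        self.names = sorted(self.lengths)
        weights = np.array([self.lengths[c] for c in self.names], float)
        self.probs = weights / weights.sum()
        self.trees = {c: IntervalTree() for c in self.names}
        self.margin = margin

    def reserve(self, chrom, start, end) -> None:
        self.trees[chrom].addi(start - self.margin, end + self.margin)

    def place(self, span: int, chrom=None) -> tuple[str, int]:
        """Return (chrom, 0-based start) of a free span; reserves it."""
        for _ in range(2000):
            c = chrom or str(self.rng.choice(self.names, p=self.probs))
            length = self.lengths[c]
            if length - span - 20 <= 10:
                continue
            s = int(self.rng.integers(10, length - span - 10))
            if not self.trees[c].overlap(s - self.margin,
                                         s + span + self.margin):
                self.reserve(c, s, s + span)
                return c, s
        raise SpecTooDenseError("could not place variant; genome too dense")


# ---------------------------------------------------------------------------
# Population VCF


def _af_pair(rng, above: bool, spike: bool) -> float:
    if spike:
        return float(rng.uniform(0.985, 0.999))
    if above:
        return float(rng.uniform(0.55, 0.95))
    return float(rng.uniform(0.05, 0.45))


def _alt_base(rng, ref_base: str) -> str:
    choices = [b for b in BASES if b != ref_base.upper()]
    return choices[int(rng.integers(0, 3))]


def make_population_vcf(spec: ScenarioSpec, genome: dict[str, str],
                        rng=None, placer: _Placer | None = None,
                        extra_variants=()):
    """Population records of all five classes with INFO AF and a manifest
    of the ground-truth selection outcome at threshold 0.5.

    ``extra_variants`` (e.g. gene-repair edits from the gene generator) are
    merged in; their expected edits must be supplied by the caller."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    placer = placer or _Placer(rng, {c: len(s) for c, s in genome.items()})
    variants: list[PopulationVariant] = []
    manifest = Manifest()
    counter = [0]

    def vid():
        counter[0] += 1
        return f"var{counter[0]:05d}"

    def emit(chrom, pos0, ref, alts, afs, expect_idx=None):
        v = PopulationVariant(
            chrom=chrom, pos=pos0 + 1, vid=vid(), ref=ref,
            alts=tuple(alts), alt_freqs=tuple(round(a, 6) for a in afs),
            vclass=classify_variant(ref, alts))
        variants.append(v)
        if expect_idx is not None:
            alt = alts[expect_idx]
            manifest.expected_edits.append(MajorAlleleEdit(
                chrom, v.pos, ref.upper(), alt.upper(),
                round(afs[expect_idx], 6), v.vclass, v.vid))
        return v

    def allocations(n: int):
        n_above = int(round(spec.frac_above * n))
        n_spike = min(n_above, int(round(spec.frac_error_spike * n)))
        flags = ([("above", True)] * n_spike
                 + [("above", False)] * (n_above - n_spike)
                 + [("below", False)] * (n - n_above))
        rng.shuffle(flags)
        n_multi = int(round(spec.frac_multiallelic * n))
        multi = np.zeros(n, bool)
        multi[:n_multi] = True
        rng.shuffle(multi)
        return flags, multi

    def second_af(rng, af1):
        cap = min(0.3, 1 - af1 - 0.005)
        if cap <= 0.01:
            return None  # near-fixed site: no headroom for a second allele
        return float(rng.uniform(0.01, cap))

    # SNPs
    flags, multi = allocations(spec.n_snp)
    for (kind, spike), is_multi in zip(flags, multi):
        chrom, p = placer.place(1)
        ref = genome[chrom][p].upper()
        alt = _alt_base(rng, ref)
        af = _af_pair(rng, kind == "above", spike)
        alts, afs = [alt], [af]
        af2 = second_af(rng, af) if is_multi else None
        if af2 is not None:
            alt2 = [b for b in BASES if b not in (ref, alt)][
                int(rng.integers(0, 2))]
            alts.append(alt2)
            afs.append(af2)
        emit(chrom, p, ref, alts, afs,
             expect_idx=0 if kind == "above" else None)

    # INDELs (anchored insertions and deletions, 1-8 bp)
    flags, multi = allocations(spec.n_indel)
    for (kind, spike), is_multi in zip(flags, multi):
        size = int(rng.integers(1, 9))
        deletion = bool(rng.integers(0, 2))
        span = size + 1 if deletion else 1
        chrom, p = placer.place(span + 9)
        anchor = genome[chrom][p].upper()
        if deletion:
            ref = (anchor + genome[chrom][p + 1:p + 1 + size]).upper()
            alt = anchor
        else:
            ref = anchor
            alt = anchor + _rand_seq(rng, size)
        af = _af_pair(rng, kind == "above", spike)
        alts, afs = [alt], [af]
        af2 = second_af(rng, af) if is_multi else None
        if af2 is not None:
            alts.append(anchor + _rand_seq(rng, size + 1))
            afs.append(af2)
        emit(chrom, p, ref, alts, afs,
             expect_idx=0 if kind == "above" else None)

    # MNPs (equal length, all bases differing)
    flags, multi = allocations(spec.n_mnp)
    for (kind, spike), is_multi in zip(flags, multi):
        size = int(rng.integers(2, 4))
        chrom, p = placer.place(size)
        ref = genome[chrom][p:p + size].upper()
        alt = "".join(_alt_base(rng, b) for b in ref)
        af = _af_pair(rng, kind == "above", spike)
        alts, afs = [alt], [af]
        af2 = second_af(rng, af) if is_multi else None
        if af2 is not None:
            alt2 = "".join(_alt_base(rng, b) for b in alt)
            if alt2 == ref:
                alt2 = alt2[:-1] + _alt_base(rng, ref[-1])
            alts.append(alt2)
            afs.append(af2)
        emit(chrom, p, ref, alts, afs,
             expect_idx=0 if kind == "above" else None)

    # SNP+INDEL mixed sites (single-base alt plus insertion alt)
    flags, _ = allocations(spec.n_snp_indel)
    for kind, spike in flags:
        chrom, p = placer.place(10)
        ref = genome[chrom][p].upper()
        snp_alt = _alt_base(rng, ref)
        ins_alt = ref + _rand_seq(rng, int(rng.integers(2, 6)))
        af = _af_pair(rng, kind == "above", False)
        low = second_af(rng, af)
        winner_is_snp = bool(rng.integers(0, 2))
        if winner_is_snp:
            alts, afs = [snp_alt, ins_alt], [af, low]
        else:
            alts, afs = [ins_alt, snp_alt], [af, low]
        emit(chrom, p, ref, alts, afs,
             expect_idx=0 if kind == "above" else None)

    # SVs: classified and counted, never selected
    for i in range(spec.n_sv):
        chrom, p = placer.place(2)
        ref = genome[chrom][p].upper()
        af = float(rng.uniform(0.1, 0.95))
        emit(chrom, p, ref, ["<CN0>"], [af], expect_idx=None)

    # co-located SNP + deletion conflicts, both above threshold
    for _ in range(spec.n_colocated):
        size = int(rng.integers(2, 5))
        chrom, p = placer.place(size + 10)
        anchor = genome[chrom][p].upper()
        del_ref = (anchor + genome[chrom][p + 1:p + 1 + size]).upper()
        snp_off = int(rng.integers(1, size + 1))
        snp_ref = genome[chrom][p + snp_off].upper()
        af_del = float(rng.uniform(0.55, 0.95))
        af_snp = float(rng.uniform(0.55, 0.95))
        while abs(af_del - af_snp) < 1e-3:
            af_snp = float(rng.uniform(0.55, 0.95))
        del_wins = af_del > af_snp
        emit(chrom, p, del_ref, [anchor], [af_del],
             expect_idx=0 if del_wins else None)
        emit(chrom, p + snp_off, snp_ref, [_alt_base(rng, snp_ref)],
             [af_snp], expect_idx=None if del_wins else 0)
        manifest.expected_dropped += 1

    variants.extend(extra_variants)
    variants.sort(key=lambda v: (v.chrom, v.pos, v.vid))
    manifest.expected_edits.sort(key=lambda e: (e.chrom, e.pos))
    for v in variants:
        manifest.totals[v.vclass] = manifest.totals.get(v.vclass, 0) + 1
    multi_ids = {(v.chrom, v.vid) for v in variants if v.multiallelic}
    for e in manifest.expected_edits:
        manifest.selected[e.source_class] = \
            manifest.selected.get(e.source_class, 0) + 1
        if (e.chrom, e.source_id) in multi_ids:
            manifest.multiallelic_selected[e.source_class] = \
                manifest.multiallelic_selected.get(e.source_class, 0) + 1
    return variants, manifest


def write_population_vcf(variants, genome, path) -> None:
    rows = [
        (v.chrom, v.pos, v.vid, v.ref, list(v.alts),
         {"AF": ",".join(f"{f:.6g}" for f in v.alt_freqs)})
        for v in variants
    ]
    _io.write_vcf(path, rows,
                  contig_lengths={c: len(s) for c, s in genome.items()})


# ---------------------------------------------------------------------------
# Gene models with planted annotation defects


@dataclass
class GeneFixture:
    """Gene models on the source genome plus companion truth sequences."""

    models: list[GeneModel]
    mrna: dict[str, str]
    proteins: dict[str, str]
    repair_variants: list[PopulationVariant]
    expected_edits: list[MajorAlleleEdit]


def _build_cassette(rng, strand, n_junk, n_gap):
    """Assemble one transcript cassette in sense coordinates.

    Returns (old sense sequence, exon spans, cds span, defects, mrna,
    protein) where defects are ('del', junk_start, junk_end) or
    ('ins', gap_pos, inserted_seq) in sense-old coordinates."""
    u5, u3 = 18, 15
    n_codons = int(rng.integers(40, 70))
    cds = "ATG" + "".join(
        CODONS[i] for i in rng.integers(0, len(CODONS), n_codons)) + "TAA"
    mrna = _rand_seq(rng, u5) + cds + _rand_seq(rng, u3)
    protein = str(Seq(cds).translate()).rstrip("*")
    n_exons = int(rng.integers(2, 5))
    # exon cut points within the mRNA, kept >= 25 bp apart
    interior: list[int] = []
    for _ in range(200):
        if len(interior) == n_exons - 1:
            break
        x = int(rng.integers(12, len(mrna) - 12))
        if all(abs(x - y) >= 25 for y in interior):
            interior.append(x)
    interior.sort()
    bounds = [0] + interior + [len(mrna)]
    exon_mrna = list(zip(bounds[:-1], bounds[1:]))

    # choose defect positions strictly inside the CDS, well separated and
    # clear of exon boundaries (room for an 8 bp defect plus margins)
    cds_lo, cds_hi = u5 + 6, u5 + len(cds) - 15
    candidates = [
        x for x in range(cds_lo, cds_hi)
        if all(ms + 4 <= x <= me - 12 for ms, me in exon_mrna
               if ms <= x < me)
    ]
    rng.shuffle(candidates)
    chosen: list[tuple[int, str]] = []
    for x in candidates:
        if len(chosen) == n_junk + n_gap:
            break
        if all(abs(x - y) >= 15 for y, _ in chosen):
            kind = "junk" if sum(k == "junk" for _, k in chosen) < n_junk \
                else "gap"
            chosen.append((x, kind))
    assert len(chosen) == n_junk + n_gap, "cassette too small for defects"
    defects_by_pos = sorted(chosen)

    pieces_seq: list[str] = []
    exon_spans: list[tuple[int, int]] = []   # old sense coords
    mrna_map: list[tuple[int, int, int]] = []  # (old_start, old_end, mrna_start)
    defects: list[tuple] = []
    pos = 0

    def emit_exon(ms, me):
        nonlocal pos
        if me <= ms:
            return
        pieces_seq.append(mrna[ms:me])
        exon_spans.append((pos, pos + (me - ms)))
        mrna_map.append((pos, pos + (me - ms), ms))
        pos += me - ms

    for i, (ms, me) in enumerate(exon_mrna):
        cur = ms
        for x, kind in defects_by_pos:
            if not (ms < x < me):
                continue
            if kind == "junk":
                emit_exon(cur, x)
                junk = _rand_seq(rng, int(rng.integers(2, 9)))
                defects.append(("del", pos, pos + len(junk)))
                pieces_seq.append(junk)
                pos += len(junk)
                cur = x
            else:  # gap: mRNA bases missing from the old assembly
                gap_len = int(rng.integers(2, 9))
                gap_len = max(2, min(gap_len, me - 4 - x, cds_hi + 8 - x))
                emit_exon(cur, x)
                defects.append(("ins", pos, mrna[x:x + gap_len]))
                cur = x + gap_len
        emit_exon(cur, me)
        if i < len(exon_mrna) - 1:
            intron = _rand_seq(rng, int(rng.integers(40, 81)))
            pieces_seq.append(intron)
            pos += len(intron)

    old_seq = "".join(pieces_seq)

    def mrna_to_old(x, end=False):
        if end:
            for s, e, m0 in mrna_map:
                if m0 <= x - 1 < m0 + (e - s):
                    return s + (x - 1 - m0) + 1
        else:
            for s, e, m0 in mrna_map:
                if m0 <= x < m0 + (e - s):
                    return s + (x - m0)
        raise AssertionError("CDS boundary inside a defect")

    cds_span = (mrna_to_old(u5), mrna_to_old(u5 + len(cds), end=True))
    if strand == "-":
        T = len(old_seq)
        old_seq = str(Seq(old_seq).reverse_complement())
        exon_spans = sorted((T - e, T - s) for s, e in exon_spans)
        cds_span = (T - cds_span[1], T - cds_span[0])
        flipped = []
        for d in defects:
            if d[0] == "del":
                flipped.append(("del", T - d[2], T - d[1]))
            else:
                flipped.append(
                    ("ins", T - d[1], str(Seq(d[2]).reverse_complement())))
        defects = flipped
    return old_seq, exon_spans, cds_span, defects, mrna, protein


def make_gene_models(spec: ScenarioSpec, genome: dict[str, str],
                     rng=None, placer: _Placer | None = None) -> \
        tuple[GeneFixture, dict[str, str]]:
    """Plant gene cassettes into the genome.

    Writes designed transcript sequence into the source genome (including
    2-8 bp spurious insertions and missing-base gaps), returns the
    annotation on source coordinates, the companion mRNA/protein truth
    (derived from the post-edit genome by construction) and the
    major-allele repair records to merge into the population VCF, plus the
    updated genome."""
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    placer = placer or _Placer(rng, {c: len(s) for c, s in genome.items()})
    genome = dict(genome)
    fixture = GeneFixture([], {}, {}, [], [])
    junk_left, gap_left = spec.n_spurious_introns, spec.n_exon_splits
    for g in range(spec.n_genes):
        strand = "-" if g < spec.n_minus_genes else "+"
        n_junk = min(junk_left, 1 if g < spec.n_genes - 1 else junk_left)
        n_gap = 0
        if n_junk == 0 and gap_left > 0:
            n_gap = 1
        junk_left -= n_junk
        gap_left -= n_gap
        name = f"NM_{1000 + g}"
        (old_seq, exon_spans, cds_span, defects, mrna,
         protein) = _build_cassette(rng, strand, n_junk, n_gap)
        chrom, off = placer.place(len(old_seq) + 40)
        seq = genome[chrom]
        genome[chrom] = seq[:off] + old_seq + seq[off + len(old_seq):]
        starts = [off + s for s, _ in exon_spans]
        ends = [off + e for _, e in exon_spans]
        model = GeneModel(
            name=name, chrom=chrom, strand=strand,
            tx_start=starts[0], tx_end=ends[-1],
            cds_start=off + cds_span[0], cds_end=off + cds_span[1],
            exon_starts=starts, exon_ends=ends, name2=f"GENE{g}")
        model = recompute_frames(model)
        model.validate()
        fixture.models.append(model)
        fixture.mrna[name] = mrna
        fixture.proteins[name] = protein
        for j, d in enumerate(defects):
            af = round(float(rng.uniform(0.6, 0.95)), 6)
            vid = f"{name}_fix{j}"
            if d[0] == "del":
                s, e = off + d[1], off + d[2]
                anchor = genome[chrom][s - 1].upper()
                ref = anchor + genome[chrom][s:e].upper()
                alt = anchor
                pos = s  # 1-based anchor position = 0-based s-1 + 1
            else:
                p = off + d[1]
                anchor = genome[chrom][p - 1].upper()
                ref = anchor
                alt = anchor + d[2]
                pos = p
            v = PopulationVariant(chrom, pos, vid, ref, (alt,), (af,),
                                  classify_variant(ref, (alt,)))
            fixture.repair_variants.append(v)
            fixture.expected_edits.append(MajorAlleleEdit(
                chrom, pos, ref, alt, af, INDEL, vid))
    assert junk_left == 0 and gap_left == 0, \
        "more planted defects requested than genes"
    return fixture, genome


# ---------------------------------------------------------------------------
# Paired call sets


@dataclass
class CallsetTruth:
    """Planted per-class common/unique counts for a callset pair."""

    common: dict[str, int] = field(default_factory=dict)
    unique_a: dict[str, int] = field(default_factory=dict)
    unique_b: dict[str, int] = field(default_factory=dict)


def make_callsets(spec: ScenarioSpec, genome: dict[str, str], rng=None):
    """Two call sets with planted common/unique variants per class,
    including REF/ALT-swap pairs and overlapping-INDEL pairs; returns
    (set_a, set_b, CallsetTruth)."""
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    placer = _Placer(rng, {c: len(s) for c, s in genome.items()}, margin=12)
    set_a: list[CallRecord] = []
    set_b: list[CallRecord] = []

    def qualdp():
        return round(float(rng.uniform(15, 60)), 1), int(rng.integers(4, 60))

    def snp_at():
        chrom, p = placer.place(1)
        ref = genome[chrom][p].upper()
        q, d = qualdp()
        return CallRecord(chrom, p + 1, ref, _alt_base(rng, ref), q, d)

    def indel_at(span_extra: int = 0):
        size = int(rng.integers(1, 7))
        deletion = bool(rng.integers(0, 2))
        span = (size + 1 if deletion else 1) + span_extra
        chrom, p = placer.place(span + 8)
        anchor = genome[chrom][p].upper()
        q, d = qualdp()
        if deletion:
            ref = (anchor + genome[chrom][p + 1:p + 1 + size]).upper()
            return CallRecord(chrom, p + 1, ref, anchor, q, d)
        return CallRecord(chrom, p + 1, anchor,
                          anchor + _rand_seq(rng, size), q, d)

    for _ in range(spec.n_common_snp):
        r = snp_at()
        set_a.append(r)
        set_b.append(r)
    for _ in range(spec.n_swap_pairs):
        r = snp_at()
        set_a.append(r)
        q, d = qualdp()
        set_b.append(CallRecord(r.chrom, r.pos, r.alt, r.ref, q, d))
    for _ in range(spec.n_unique_a_snp):
        set_a.append(snp_at())
    for _ in range(spec.n_unique_b_snp):
        set_b.append(snp_at())
    for _ in range(spec.n_common_indel):
        r = indel_at()
        set_a.append(r)
        set_b.append(r)
    for _ in range(spec.n_overlap_indels):
        # two deletions shifted by one base: padded REF intervals overlap
        size = int(rng.integers(2, 6))
        chrom, p = placer.place(size + 10)
        sl = genome[chrom][p:p + size + 2].upper()
        q, d = qualdp()
        set_a.append(CallRecord(chrom, p + 1, sl[:size + 1], sl[0], q, d))
        q, d = qualdp()
        set_b.append(CallRecord(chrom, p + 2, sl[1:], sl[1], q, d))
    for _ in range(spec.n_unique_a_indel):
        set_a.append(indel_at())
    for _ in range(spec.n_unique_b_indel):
        set_b.append(indel_at())

    set_a.sort(key=lambda r: (r.chrom, r.pos))
    set_b.sort(key=lambda r: (r.chrom, r.pos))
    truth = CallsetTruth(
        common={"SNP": spec.n_common_snp + spec.n_swap_pairs,
                "INDEL": spec.n_common_indel + spec.n_overlap_indels},
        unique_a={"SNP": spec.n_unique_a_snp,
                  "INDEL": spec.n_unique_a_indel},
        unique_b={"SNP": spec.n_unique_b_snp,
                  "INDEL": spec.n_unique_b_indel},
    )
    return set_a, set_b, truth


def write_callset(records, genome, path) -> None:
    rows = [
        (r.chrom, r.pos, ".", r.ref, [r.alt], {"DP": r.dp}, f"{r.qual:g}")
        for r in records
    ]
    _io.write_vcf(path, rows,
                  contig_lengths={c: len(s) for c, s in genome.items()})


# ---------------------------------------------------------------------------
# Whole-scenario orchestration


@dataclass
class Scenario:
    spec: ScenarioSpec
    genome: dict[str, str]
    variants: list[PopulationVariant]
    manifest: Manifest
    genes: GeneFixture
    callset_a: list[CallRecord]
    callset_b: list[CallRecord]
    callset_truth: CallsetTruth


def make_scenario(spec: ScenarioSpec | None = None,
                  out_dir=None) -> Scenario:
    """Generate every input of one seeded scenario; optionally write the
    files (FASTA, VCFs, genePred, companion FASTAs, manifest JSON)."""
    spec = spec or ScenarioSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome = make_genome(spec, rng)
    placer = _Placer(rng, {c: len(s) for c, s in genome.items()})
    genes, genome = make_gene_models(spec, genome, rng, placer)
    variants, manifest = make_population_vcf(
        spec, genome, rng, placer, extra_variants=genes.repair_variants)
    manifest.expected_edits.extend(genes.expected_edits)
    manifest.expected_edits.sort(key=lambda e: (e.chrom, e.pos))
    for e in genes.expected_edits:
        manifest.selected[e.source_class] = \
            manifest.selected.get(e.source_class, 0) + 1
    callset_a, callset_b, truth = make_callsets(spec, genome, rng)
    sc = Scenario(spec, genome, variants, manifest, genes, callset_a,
                  callset_b, truth)
    if out_dir is not None:
        write_scenario(sc, out_dir)
    return sc


def write_scenario(sc: Scenario, out_dir) -> dict[str, str]:
    import os

    _io.ensure_dir(out_dir)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "population_vcf": os.path.join(out_dir, "population.vcf"),
        "genepred": os.path.join(out_dir, "genes.gp"),
        "mrna": os.path.join(out_dir, "mrna.fa"),
        "proteins": os.path.join(out_dir, "proteins.fa"),
        "callset_a": os.path.join(out_dir, "callset_a.vcf"),
        "callset_b": os.path.join(out_dir, "callset_b.vcf"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    _io.write_fasta(sc.genome, paths["genome"])
    write_population_vcf(sc.variants, sc.genome, paths["population_vcf"])
    from .annotation import write_genepred

    write_genepred(sc.genes.models, paths["genepred"])
    _io.write_fasta(sc.genes.mrna, paths["mrna"], index=False)
    _io.write_fasta(sc.genes.proteins, paths["proteins"], index=False)
    write_callset(sc.callset_a, sc.genome, paths["callset_a"])
    write_callset(sc.callset_b, sc.genome, paths["callset_b"])
    sc.manifest.to_json(paths["manifest"])
    return paths
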
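"""Coordinate maps and UCSC chain files between an edited assembly and its
source.

The edit log written while building the normalized genome fully determines
the pairwise alignment between the two assemblies: substitutions (delta 0)
lie inside aligned blocks (chains tolerate mismatches), while each
insertion/deletion breaks the alignment, leaving the inserted/deleted
minimal bases aligned to nothing.  This module materializes that alignment
two ways — a direct :class:`CoordinateMap` and a UCSC chain file — and lifts
positions, intervals and VCF records in either direction with explicit
unmapped semantics.  A generic chain-walking lifter, built only from the
serialized chain file, provides an independent route for cross-validation.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

from .editor import EditLog

log = logging.getLogger(__name__)

NEW2OLD = "new2old"
OLD2NEW = "old2new"

# unmapped reasons
INSERTED_IN_SOURCE = "INSERTED_IN_SOURCE"


class OutOfBoundsError(ValueError):
    pass


@dataclass(frozen=True)
class Block:
    """One ungapped aligned block, 0-based half-open on both assemblies."""

    new_start: int
    new_end: int
    old_start: int
    old_end: int

    def __post_init__(self):
        assert self.new_end - self.new_start == self.old_end - self.old_start

    @property
    def size(self) -> int:
        return self.new_end - self.new_start


@dataclass(frozen=True)
class LiftOutcome:
    """Result of lifting one position: a 1-based position or an unmapped
    reason."""

    pos: int | None
    reason: str | None = None

    @property
    def mapped(self) -> bool:
        return self.pos is not None


UNMAPPED = LiftOutcome(None, INSERTED_IN_SOURCE)


@dataclass
class CoordinateMap:
    """Piecewise-monotone mapping between the new and old assembly."""

    blocks: dict[str, list[Block]] = field(default_factory=dict)
    old_lengths: dict[str, int] = field(default_factory=dict)
    new_lengths: dict[str, int] = field(default_factory=dict)

    def chrom_length(self, chrom: str, direction: str) -> int:
        lens = self.new_lengths if direction == NEW2OLD else self.old_lengths
        return lens[chrom]


def build_map(elog: EditLog) -> CoordinateMap:
    """Derive the block structure of the pairwise alignment from an edit log.

    For an edit with REF length r and ALT length a, the first min(r, a)
    bases stay aligned (a substitution within a block); the remaining
    |r - a| bases exist on one side only and break the block."""
    cmap = CoordinateMap(old_lengths=dict(elog.old_lengths),
                         new_lengths=dict(elog.new_lengths))
    for chrom, old_len in elog.old_lengths.items():
        new_len = elog.new_lengths[chrom]
        blocks: list[Block] = []
        b_old = b_new = 0  # start of the open block
        cur_old = cur_new = 0
        for e in elog.edits.get(chrom, ()):
            # carry the open block through the inter-edit segment
            cur_old, cur_new = e.old_start, e.new_start
            k = min(len(e.ref_seq), len(e.alt_seq))
            cur_old += k
            cur_new += k
            if e.delta == 0:
                continue  # substitution: block continues through the edit
            if cur_old > b_old:
                blocks.append(Block(b_new, cur_new, b_old, cur_old))
            b_old, b_new = e.old_end, e.new_end
        assert old_len - b_old == new_len - b_new
        if old_len > b_old:
            blocks.append(Block(b_new, new_len, b_old, old_len))
        cmap.blocks[chrom] = blocks
    return cmap


def _find_block(blocks: list[Block], pos0: int, direction: str) -> int:
    """Index of the block whose source-axis span contains pos0, else -1."""
    if direction == NEW2OLD:
        starts = [b.new_start for b in blocks]
        i = bisect_right(starts, pos0) - 1
        if i >= 0 and blocks[i].new_start <= pos0 < blocks[i].new_end:
            return i
    else:
        starts = [b.old_start for b in blocks]
        i = bisect_right(starts, pos0) - 1
        if i >= 0 and blocks[i].old_start <= pos0 < blocks[i].old_end:
            return i
    return -1


def lift_point(cmap: CoordinateMap, chrom: str, pos0: int,
               direction: str = NEW2OLD, snap: str | None = None):
    """Lift a 0-based coordinate.  Returns (lifted 0-based pos | None,
    snapped flag).  ``snap``: None (unmapped stays unmapped), "right"
    (next aligned base at or after), "left" (previous aligned base)."""
    if chrom not in cmap.blocks:
        raise OutOfBoundsError(f"unknown chromosome {chrom!r}")
    if pos0 < 0 or pos0 >= cmap.chrom_length(chrom, direction):
        raise OutOfBoundsError(f"{chrom}:{pos0} outside assembly")
    blocks = cmap.blocks[chrom]
    i = _find_block(blocks, pos0, direction)
    if i >= 0:
        b = blocks[i]
        if direction == NEW2OLD:
            return b.old_start + (pos0 - b.new_start), False
        return b.new_start + (pos0 - b.old_start), False
    if snap is None:
        return None, False
    if direction == NEW2OLD:
        if snap == "right":
            for b in blocks:
                if b.new_start > pos0:
                    return b.old_start, True
            return None, True
        for b in reversed(blocks):
            if b.new_end <= pos0:
                return b.old_end - 1, True
        return None, True
    if snap == "right":
        for b in blocks:
            if b.old_start > pos0:
                return b.new_start, True
        return None, True
    for b in reversed(blocks):
        if b.old_end <= pos0:
            return b.new_end - 1, True
    return None, True


def lift_position(cmap: CoordinateMap, chrom: str, pos: int,
                  direction: str = NEW2OLD) -> LiftOutcome:
    """Lift a 1-based position through the map; one-sided gaps are
    UNMAPPED with reason INSERTED_IN_SOURCE."""
    lifted, _ = lift_point(cmap, chrom, pos - 1, direction)
    if lifted is None:
        return UNMAPPED
    return LiftOutcome(lifted + 1)


# ---------------------------------------------------------------------------
# Chain files


@dataclass
class ChainAlignment:
    """One UCSC chain: header fields plus (size, dt, dq) body triplets.

    Target = new (normalized) assembly, query = old assembly, matching the
    NewToOld.over.chain convention; both strands '+'."""

    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    chain_id: int
    sizes: list[int] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)  # (dt, dq)

    def validate(self) -> None:
        assert len(self.gaps) == max(len(self.sizes) - 1, 0)
        t_span = sum(self.sizes) + sum(dt for dt, _ in self.gaps)
        q_span = sum(self.sizes) + sum(dq for _, dq in self.gaps)
        assert t_span == self.t_end - self.t_start, "chain t-span identity"
        assert q_span == self.q_end - self.q_start, "chain q-span identity"


def build_chain(source) -> list[ChainAlignment]:
    """Build one chain per chromosome from an :class:`EditLog` (or a
    prebuilt :class:`CoordinateMap`).  Score is the total aligned bases."""
    cmap = source if isinstance(source, CoordinateMap) else build_map(source)
    chains = []
    for cid, chrom in enumerate(sorted(cmap.blocks), start=1):
        blocks = cmap.blocks[chrom]
        if not blocks:
            continue
        sizes = [b.size for b in blocks]
        gaps = [
            (nb.new_start - b.new_end, nb.old_start - b.old_end)
            for b, nb in zip(blocks, blocks[1:])
        ]
        chains.append(ChainAlignment(
            score=sum(sizes),
            t_name=chrom, t_size=cmap.new_lengths[chrom],
            t_start=blocks[0].new_start, t_end=blocks[-1].new_end,
            q_name=chrom, q_size=cmap.old_lengths[chrom],
            q_start=blocks[0].old_start, q_end=blocks[-1].old_end,
            chain_id=cid, sizes=sizes, gaps=gaps,
        ))
        chains[-1].validate()
    return chains


def swap_chain(chain: ChainAlignment) -> ChainAlignment:
    """Exchange target and query (the reverse-direction chain)."""
    return ChainAlignment(
        score=chain.score,
        t_name=chain.q_name, t_size=chain.q_size,
        t_start=chain.q_start, t_end=chain.q_end,
        q_name=chain.t_name, q_size=chain.t_size,
        q_start=chain.t_start, q_end=chain.t_end,
        chain_id=chain.chain_id, sizes=list(chain.sizes),
        gaps=[(dq, dt) for dt, dq in chain.gaps],
    )


def write_chain(chains, path) -> None:
    """Serialize in the UCSC chain dialect (header line, space-separated;
    tab-separated body triplets; final bare size; blank-line terminator)."""
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score} {c.t_name} {c.t_size} + {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} + {c.q_start} {c.q_end} "
                f"{c.chain_id}\n")
            for size, (dt, dq) in zip(c.sizes, c.gaps):
                fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write(f"{c.sizes[-1]}\n\n")


def read_chain(path) -> list[ChainAlignment]:
    chains: list[ChainAlignment] = []
    cur: ChainAlignment | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                cur = None
                continue
            if line.startswith("chain"):
                f = line.split()
                assert f[4] == "+" and f[9] == "+", "only + strands supported"
                cur = ChainAlignment(
                    score=int(f[1]), t_name=f[2], t_size=int(f[3]),
                    t_start=int(f[5]), t_end=int(f[6]), q_name=f[7],
                    q_size=int(f[8]), q_start=int(f[10]), q_end=int(f[11]),
                    chain_id=int(f[12]))
                chains.append(cur)
                continue
            f = line.split()
            cur.sizes.append(int(f[0]))
            if len(f) == 3:
                cur.gaps.append((int(f[1]), int(f[2])))
    for c in chains:
        c.validate()
    return chains


class ChainLifter:
    """Generic chain-walking lifter, independent of :class:`CoordinateMap`.

    Reconstructs aligned intervals purely from chain headers and body
    triplets, the way a generic liftOver consumer would."""

    def __init__(self, chains):
        # per chrom: parallel sorted lists of (t_start, t_end, q_start)
        self._t_index: dict[str, list[tuple[int, int, int]]] = {}
        self._q_index: dict[str, list[tuple[int, int, int]]] = {}
        self._t_sizes: dict[str, int] = {}
        self._q_sizes: dict[str, int] = {}
        for c in chains:
            t, q = c.t_start, c.q_start
            gaps = list(c.gaps) + [(0, 0)]
            for size, (dt, dq) in zip(c.sizes, gaps):
                self._t_index.setdefault(c.t_name, []).append((t, t + size, q))
                self._q_index.setdefault(c.q_name, []).append((q, q + size, t))
                t += size + dt
                q += size + dq
            self._t_sizes[c.t_name] = c.t_size
            self._q_sizes[c.q_name] = c.q_size
        for idx in (self._t_index, self._q_index):
            for chrom in idx:
                idx[chrom].sort()

    def lift(self, chrom: str, pos: int,
             direction: str = NEW2OLD) -> LiftOutcome:
        """Lift a 1-based position via the chain blocks."""
        if direction == NEW2OLD:
            index, sizes = self._t_index, self._t_sizes
        else:
            index, sizes = self._q_index, self._q_sizes
        if chrom not in index:
            raise OutOfBoundsError(f"chromosome {chrom!r} not in chain")
        if pos < 1 or pos > sizes[chrom]:
            raise OutOfBoundsError(f"{chrom}:{pos} outside assembly")
        pos0 = pos - 1
        ivs = index[chrom]
        starts = [iv[0] for iv in ivs]
        i = bisect_right(starts, pos0) - 1
        if i >= 0:
            s, e, other = ivs[i]
            if s <= pos0 < e:
                return LiftOutcome(other + (pos0 - s) + 1)
        return UNMAPPED


# ---------------------------------------------------------------------------
# Record lifting and cross-validation


@dataclass(frozen=True)
class LiftedRecord:
    """A lifted VCF-like record; ``partial`` flags a deletion whose REF span
    extends into a one-sided gap (anchor mapped, tail did not)."""

    record: object
    pos: int
    partial: bool = False


def lift_vcf(cmap: CoordinateMap, records, direction: str = NEW2OLD):
    """Lift record positions; REF/ALT text is intentionally left unchanged.

    ``records`` need chrom/pos/ref attributes.  A record is unmapped when
    its (anchor) position falls in a one-sided gap; a deletion whose anchor
    maps but whose REF span crosses a gap is lifted with a partial flag.
    Returns (lifted sorted by position, unmapped list of (record, reason))."""
    lifted: list[LiftedRecord] = []
    unmapped: list[tuple[object, str]] = []
    for r in records:
        out = lift_position(cmap, r.chrom, r.pos, direction)
        if not out.mapped:
            unmapped.append((r, out.reason))
            continue
        partial = False
        span = len(getattr(r, "ref", "") or "")
        for off in range(1, span):
            probe, _ = lift_point(cmap, r.chrom, r.pos - 1 + off, direction)
            if probe is None:
                partial = True
                log.warning("%s:%s: REF span partially unmapped; lifted "
                            "with warning", r.chrom, r.pos)
                break
        lifted.append(LiftedRecord(r, out.pos, partial))
    lifted.sort(key=lambda lr: (lr.record.chrom, lr.pos))
    return lifted, unmapped


def concordance_check(cmap: CoordinateMap, chains, positions,
                      direction: str = NEW2OLD):
    """Lift every (chrom, 1-based pos) via the direct map and via generic
    chain walking; UNMAPPED outcomes must agree too.  Returns
    (fraction agreeing, list of mismatches); an empty list is vacuously
    concordant (1.0)."""
    lifter = chains if isinstance(chains, ChainLifter) else ChainLifter(chains)
    positions = list(positions)
    if not positions:
        return 1.0, []
    mismatches = []
    agree = 0
    for chrom, pos in positions:
        via_map = lift_position(cmap, chrom, pos, direction)
        via_chain = lifter.lift(chrom, pos, direction)
        if via_map.pos == via_chain.pos:
            agree += 1
        else:
            mismatches.append((chrom, pos, via_map, via_chain))
    return agree / len(positions), mismatches
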
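"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-base replay of edits, O(n^2)
scans, and third-party edit distance.  None of it shares code with the
package paths it validates.
"""

from __future__ import annotations


def replay_alignment(old_seq: str, edits):
    """Construct the per-base correspondence between the old chromosome and
    the edited one by literally replaying minimal edits left to right.

    ``edits`` are (pos1, ref, alt) tuples, 1-based, sorted, non-overlapping.
    Returns (new_seq, old2new, new2old) where the maps hold the partner
    index or None; within an edit the first min(len) bases pair up and the
    remainder is one-sided."""
    old2new: list[int | None] = []
    new2old: list[int | None] = []
    new_chars: list[str] = []
    cursor = 0
    for pos1, ref, alt in sorted(edits, key=lambda e: e[0]):
        s = pos1 - 1
        assert s >= cursor, "edits overlap"
        assert old_seq[s:s + len(ref)].upper() == ref.upper()
        for i in range(cursor, s):
            old2new.append(len(new_chars))
            new2old.append(i)
            new_chars.append(old_seq[i])
        k = min(len(ref), len(alt))
        for i in range(k):
            old2new.append(len(new_chars))
            new2old.append(s + i)
            new_chars.append(alt[i])
        for i in range(k, len(ref)):   # deleted bases: old-only
            old2new.append(None)
        for i in range(k, len(alt)):   # inserted bases: new-only
            new2old.append(None)
            new_chars.append(alt[i])
        cursor = s + len(ref)
    for i in range(cursor, len(old_seq)):
        old2new.append(len(new_chars))
        new2old.append(i)
        new_chars.append(old_seq[i])
    return "".join(new_chars), old2new, new2old


def brute_force_select(variants, threshold=0.5):
    """Reference selection: scan all (record, alt) pairs, keep AF >
    threshold (non-SV, non-symbolic), minimize, then resolve overlaps by
    repeatedly keeping the best remaining candidate (max AF, SNP-shape
    first, lowest position) and discarding everything it overlaps."""
    candidates = []
    for v in variants:
        if v.vclass == "SV":
            continue
        for alt, af in zip(v.alts, v.alt_freqs):
            if af > threshold and not alt.startswith("<") and alt not in \
                    ("*", "."):
                pos, ref, a = v.pos, v.ref.upper(), alt.upper()
                while len(ref) > 1 and len(a) > 1 and ref[-1] == a[-1]:
                    ref, a = ref[:-1], a[:-1]
                while len(ref) > 1 and len(a) > 1 and ref[0] == a[0]:
                    ref, a = ref[1:], a[1:]
                    pos += 1
                if ref != a:
                    candidates.append((v.chrom, pos, ref, a, af))

    def shape(c):
        _, _, ref, alt, _ = c
        if len(ref) == len(alt):
            return 0 if len(ref) == 1 else 1
        return 2

    kept = []
    remaining = list(candidates)
    while remaining:
        best = min(remaining,
                   key=lambda c: (-c[4], shape(c), c[1], len(c[2])))
        kept.append(best)
        bs, be = best[1] - 1, best[1] - 1 + len(best[2])
        remaining = [
            c for c in remaining
            if c is not best and not (
                c[0] == best[0]
                and c[1] - 1 < be and bs < c[1] - 1 + len(c[2]))
        ]
    return sorted(kept, key=lambda c: (c[0], c[1]))


def edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b)["editDistance"]


def primitive_cost(records) -> int:
    """Total unit-cost edits represented by a set of primitives: one per
    SNP base, plus inserted/deleted length per INDEL."""
    cost = 0
    for r in records:
        if len(r.ref) == len(r.alt):
            cost += sum(x != y for x, y in zip(r.ref, r.alt))
        else:
            cost += abs(len(r.ref) - len(r.alt))
            # anchored indels share their anchor; any extra differing
            # aligned bases would be separate SNP records
    return cost
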
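"""Edit-distance infix alignment of AP substrings onto reads.

The whole AP substring is aligned against any substring of the read
(semi-global / infix mode; unit-cost Levenshtein), the natural model for a
short, complete artificial sequence embedded in a long read. Similarity is

    s = 1 - d / L

with d the edit distance and L the AP substring length; infix mode guarantees
d <= L (aligning against a best-case substring never costs more than L), so s
is always in [0, 1].

The true/random double alignment: the best (first) hit on a read stands in
for a genuine AP occurrence; the best hit that avoids the first hit's
positions (second, "masked" alignment) samples what a random alignment looks
like on the same read. The pair drives the dataset-specific cutoff fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

_SEARCH_ALPHABET = frozenset("ACGTN")

# N in a read carries no base information: it must mismatch every AP base
# (cost 1), including a literal N in the pattern, which edlib would otherwise
# treat as equal. Mapping read N to a character outside the pattern alphabet
# enforces that without touching coordinates.
_MASK_N = str.maketrans("N", "#")


@dataclass(frozen=True)
class AlignmentHit:
    """One AP-substring-to-read alignment.

    ``read_start``/``read_end`` are 0-based half-open on the forward read.
    N in the read matches no AP base (cost 1); AP patterns never contain N.
    """

    ap_id: str
    strand: str
    read_start: int
    read_end: int
    edit_distance: int
    ap_sub_length: int
    rank: str = "first"

    @property
    def similarity(self) -> float:
        return similarity(self.edit_distance, self.ap_sub_length)

    def overlaps(self, other: "AlignmentHit") -> bool:
        return self.read_start < other.read_end and other.read_start < self.read_end


def similarity(d: int, L: int) -> float:
    """Similarity of an alignment: 1 minus edit distance over AP length."""
    if L < 1:
        raise ValueError(f"AP substring length must be >= 1, got {L}")
    if d < 0:
        raise ValueError(f"edit distance must be >= 0, got {d}")
    return 1.0 - d / L


def _optimal_interval(ap_sub: str, read_seq: str, d: int,
                      ends_inclusive: list[int]) -> tuple[int, int]:
    """Resolve the tie-broken optimal interval (min start, then min end).

    edlib reports every optimal end position. For each optimal end e the full
    set of optimal starts is enumerated by aligning the reversed pattern
    against the reversed window read[e+1-(m+d) : e+1] in SHW mode (start
    anchored at the reversed window's origin, i.e. at e); any optimal
    alignment spans at most m+d read bases, so the window is sufficient.
    Ends are scanned in ascending order with a lower-bound prune.
    """
    m = len(ap_sub)
    rev_pattern = ap_sub[::-1]
    best: tuple[int, int] | None = None
    for e in sorted(set(ends_inclusive)):
        lb = max(0, e + 1 - (m + d))
        if best is not None and lb > best[0]:
            break  # later ends cannot reach a smaller start
        window = read_seq[lb:e + 1][::-1]
        res = edlib.align(rev_pattern, window, mode="SHW", task="locations")
        if res["editDistance"] != d:  # pragma: no cover - defensive
            continue
        start = e - max(loc[1] for loc in res["locations"])
        cand = (start, e + 1)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best


def best_infix_hit(ap_sub: str, read_seq: str, ap_id: str = "",
                   strand: str = "+") -> AlignmentHit | None:
    """Best semi-global alignment of ``ap_sub`` inside ``read_seq``.

    Returns the hit minimizing the Levenshtein distance of the entire pattern
    against any read substring, with deterministic tie-breaking: smallest
    read_start, then smallest read_end. Returns None when the pattern is
    longer than the read (the read is unsearchable at that L).
    """
    if not ap_sub:
        raise ValueError("empty AP substring")
    if len(ap_sub) > len(read_seq):
        return None
    read_seq = read_seq.translate(_MASK_N)
    res = edlib.align(ap_sub, read_seq, mode="HW", task="locations")
    d = res["editDistance"]
    ends = [loc[1] for loc in res["locations"]]
    start, end = _optimal_interval(ap_sub, read_seq, d, ends)
    return AlignmentHit(
        ap_id=ap_id, strand=strand, read_start=start, read_end=end,
        edit_distance=d, ap_sub_length=len(ap_sub),
    )


def paired_hits(ap_sub: str, read_seq: str, ap_id: str = "",
                strand: str = "+") -> tuple[AlignmentHit | None,
                                            AlignmentHit | None]:
    """True/random alignment pair for one pattern on one read.

    The first hit is the global best. The second is the best alignment whose
    interval avoids the first hit's positions entirely (searching the two
    flanking segments; a contiguous interval that reuses no masked position
    must lie wholly on one side). Coordinates of the second hit stay valid on
    the full read. The second hit is None when neither flanking segment is as
    long as the pattern. Always: second.similarity <= first.similarity.
    """
    first = best_infix_hit(ap_sub, read_seq, ap_id, strand)
    if first is None:
        return None, None
    candidates: list[AlignmentHit] = []
    left = read_seq[: first.read_start]
    hit = best_infix_hit(ap_sub, left, ap_id, strand) if left else None
    if hit is not None:
        candidates.append(hit)
    right = read_seq[first.read_end:]
    hit = best_infix_hit(ap_sub, right, ap_id, strand) if right else None
    if hit is not None:
        offset = first.read_end
        candidates.append(AlignmentHit(
            ap_id=ap_id, strand=strand,
            read_start=hit.read_start + offset, read_end=hit.read_end + offset,
            edit_distance=hit.edit_distance, ap_sub_length=hit.ap_sub_length,
        ))
    if not candidates:
        return first, None
    second = min(candidates,
                 key=lambda h: (h.edit_distance, h.read_start, h.read_end))
    second = AlignmentHit(
        ap_id=ap_id, strand=strand,
        read_start=second.read_start, read_end=second.read_end,
        edit_distance=second.edit_distance, ap_sub_length=second.ap_sub_length,
        rank="second",
    )
    return first, second
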
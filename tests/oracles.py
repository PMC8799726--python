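"""Independent brute-force oracles used to cross-check the fuzzy matchers
and the overlap merger.  Everything here is plain-Python dynamic
programming or exhaustive enumeration — deliberately independent of the
library code paths (and of edlib) it validates."""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (full DP table)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def semiglobal_distance(pattern: str, text: str) -> int:
    """Min edit distance of ``pattern`` against any substring of ``text``.

    Free start and end in the text; insertions/deletions/substitutions all
    cost 1.
    """
    if not pattern:
        return 0
    prev = [0] * (len(text) + 1)  # pattern[:0] matches anywhere for free
    for i, pc in enumerate(pattern, 1):
        cur = [i]
        for j, tc in enumerate(text, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (pc != tc)))
        prev = cur
    return min(prev)


def best_barcode(read: str, barcodes: list[str], k: int) -> int:
    """The demultiplexing rule, by enumeration: unique barcode with minimal
    semi-global distance <= k, else -1 (tie or miss)."""
    dists = [semiglobal_distance(bc, read) for bc in barcodes]
    best = min(dists)
    if best > k or dists.count(best) > 1:
        return -1
    return dists.index(best)


def best_overlap(seq1: str, seq2: str, min_overlap: int):
    """Exhaustive overlap scan of read1 vs revcomp(read2).

    Returns ``(offset, overlap_length, mismatches, ratio)`` of the layout
    with minimal mismatch ratio (ties: longer overlap, then smaller
    offset), or None if no layout reaches min_overlap.
    """
    a = seq1
    b = revcomp(seq2)
    n1, n2 = len(a), len(b)
    best = None
    for d in range(-(n2 - 1), n1):
        lo = max(0, d)
        hi = min(n1, d + n2)
        ov = hi - lo
        if ov < min_overlap:
            continue
        mism = sum(1 for i in range(lo, hi) if a[i] != b[i - d])
        ratio = mism / ov
        key = (ratio, -ov, d)
        if best is None or key < best[0]:
            best = (key, d, ov, mism, ratio)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def quality_trim_cut(quals: list[int], cutoff: int) -> int:
    """Running-sum 3' quality trim position, by direct enumeration of all
    partial sums from the 3' end (5'-most minimum; no cut when >= 0)."""
    n = len(quals)
    sums = [sum(q - cutoff for q in quals[i:]) for i in range(n)]
    if not sums or min(sums) >= 0:
        return n
    return sums.index(min(sums))


def adapter_trim_position(
    read: str, adapter: str, max_error_rate: float, min_overlap: int = 3
):
    """Best 3'-adapter occurrence by exhaustive alignment enumeration.

    Considers every start position and every adapter prefix length
    (full-length matches may end anywhere; partial matches must end at the
    read's 3' end), scoring by edit distance.  Returns the trim position or
    None.  Selection: longest matched adapter prefix, fewest errors,
    leftmost start.
    """
    import math

    n, m = len(read), len(adapter)
    best = None
    for start in range(n):
        for plen in range(min_overlap, m + 1):
            prefix = adapter[:plen]
            allowed = math.floor(max_error_rate * plen)
            if plen == m:
                # full adapter: may end anywhere downstream of start
                cands = [
                    edit_distance(prefix, read[start:end])
                    for end in range(start, n + 1)
                ]
                errors = min(cands)
            else:
                errors = edit_distance(prefix, read[start:])
            if errors <= allowed:
                key = (plen, -errors, -start)
                if best is None or key > best:
                    best = key
    if best is None:
        return None
    return -best[2]
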
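"""Overlap-merging of read pairs into full amplicon sequences.

With 300-bp reads and amplicons of at most 273 bp every proper pair is a
complete read-through: the two reads cover the whole molecule and overlap
along (almost) their full length.  The merger therefore treats containment
layouts as first-class, scanning *every* relative offset of the two reads,
not only the classic staggered ones.

For each candidate offset with overlap >= ``min_overlap`` the mismatch
ratio (mismatches / overlap length) is computed; the offset with the
minimal ratio wins, ties broken by the longer overlap.  If the best ratio
is within ``max_mismatch_ratio`` a consensus is emitted: at each
overlapping position the higher-quality base wins (equal qualities with
conflicting bases fall back to read 1's base).

Match counts for all offsets at once come from a 4-channel cross-
correlation of one-hot base encodings, so the scan runs at C speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Read, ReadPair

__all__ = ["MergeResult", "merge_pair", "merge_batch"]

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MergeResult:
    """Outcome of merging one read pair."""

    merged_sequence: str
    merged_quality: str
    overlap_length: int
    mismatch_ratio: float
    status: str  # "merged" | "unmerged"

    @property
    def merged(self) -> bool:
        return self.status == "merged"


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _qual_array(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33


def _match_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """matches[d + len(b) - 1] = number of equal bases when b is shifted by d.

    Offset d means b[j] aligns with a[d + j].  Non-ACGT codes (255) never
    match anything.
    """
    total = np.zeros(len(a) + len(b) - 1)
    for c in range(4):
        total += np.correlate((a == c).astype(float), (b == c).astype(float), "full")
    return total


def merge_pair(
    read1: Read,
    read2: Read,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
) -> MergeResult:
    """Merge one pair; ``read2`` is given in sequencing orientation and is
    reverse-complemented internally.  Degenerate inputs yield ``unmerged``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not read1.seq or not read2.seq:
        return MergeResult("", "", 0, 1.0, "unmerged")
    a = _encode(read1.seq)
    qa = _qual_array(read1.qual)
    b = _encode(read2.seq)[::-1]
    b = np.where(b == 255, np.uint8(255), (3 - b).astype(np.uint8))  # complement
    qb = _qual_array(read2.qual)[::-1]
    n1, n2 = len(a), len(b)
    if min(n1, n2) < min_overlap and max(n1, n2) < min_overlap:
        return MergeResult("", "", 0, 1.0, "unmerged")

    matches = _match_counts(a, b)
    # candidate offsets d of b relative to a
    ds = np.arange(-(n2 - 1), n1)
    ov = np.minimum(n1, ds + n2) - np.maximum(0, ds)
    valid = ov >= min_overlap
    if not valid.any():
        return MergeResult("", "", 0, 1.0, "unmerged")
    ovv = ov[valid]
    ratio = (ovv - matches[valid]) / ovv
    # min ratio, tie -> longer overlap (overlap term is smaller than any
    # possible ratio difference, which is at least 1/(n1*n2)), further ties
    # resolved to the smallest offset
    best = int(np.argmin(ratio - ovv * (0.5 / (n1 * n2 * max(n1, n2)))))
    best_ratio = float(ratio[best])
    best_ov = int(ovv[best])
    ds = ds[valid]
    if best_ratio > max_mismatch_ratio:
        return MergeResult("", "", best_ov, best_ratio, "unmerged")

    d = int(ds[best])
    # global coordinates: union of a at [0, n1) and b at [d, d + n2)
    g0 = min(0, d)
    span = max(n1, d + n2) - g0
    seq = np.full(span, 255, dtype=np.uint8)
    qual = np.zeros(span, dtype=np.int16)
    a0 = -g0
    b0 = d - g0
    seq[a0 : a0 + n1] = a
    qual[a0 : a0 + n1] = qa
    # overlap region in global coordinates
    o0 = max(a0, b0)
    o1 = min(a0 + n1, b0 + n2)
    # fill b-only parts
    if b0 < a0:
        seq[b0:a0] = b[: a0 - b0]
        qual[b0:a0] = qb[: a0 - b0]
    if b0 + n2 > a0 + n1:
        seq[a0 + n1 : b0 + n2] = b[a0 + n1 - b0 :]
        qual[a0 + n1 : b0 + n2] = qb[a0 + n1 - b0 :]
    # consensus inside the overlap
    if o1 > o0:
        asub = a[o0 - a0 : o1 - a0]
        qasub = qa[o0 - a0 : o1 - a0]
        bsub = b[o0 - b0 : o1 - b0]
        qbsub = qb[o0 - b0 : o1 - b0]
        agree = asub == bsub
        take_b = qbsub > qasub  # read1 wins ties
        cons = np.where(take_b, bsub, asub)
        cons_q = np.where(
            agree,
            np.maximum(qasub, qbsub),
            np.maximum(np.abs(qasub - qbsub), 2),
        )
        seq[o0:o1] = cons
        qual[o0:o1] = cons_q

    merged_seq = _BASES[np.where(seq == 255, 0, seq)]
    # restore any non-ACGT as N
    if (seq == 255).any():
        merged = bytearray(merged_seq.tobytes())
        for i in np.nonzero(seq == 255)[0]:
            merged[i] = ord("N")
        merged_str = merged.decode("ascii")
    else:
        merged_str = merged_seq.tobytes().decode("ascii")
    qual_str = (np.clip(qual, 0, 60) + 33).astype(np.uint8).tobytes().decode("ascii")
    return MergeResult(merged_str, qual_str, best_ov, best_ratio, "merged")


def merge_batch(
    pairs: list[ReadPair],
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
    single_end: bool = False,
) -> tuple[list[Read], list[ReadPair], dict]:
    """Merge a batch of pairs.

    Returns ``(merged_reads, unmerged_pairs, report)``.  In single-end mode
    (or for pairs lacking a mate) the read passes through unchanged — the
    identity merge.  The report carries ``n_input``, ``n_merged``,
    ``n_unmerged`` and an overlap-length histogram.
    """
    merged: list[Read] = []
    unmerged: list[ReadPair] = []
    hist: dict[int, int] = {}
    for pair in pairs:
        if single_end or pair.r2 is None:
            merged.append(pair.r1)
            continue
        res = merge_pair(pair.r1, pair.r2, min_overlap, max_mismatch_ratio)
        if res.merged:
            merged.append(Read(pair.r1.id, res.merged_sequence, res.merged_quality))
            hist[res.overlap_length] = hist.get(res.overlap_length, 0) + 1
        else:
            unmerged.append(pair)
    report = {
        "n_input": len(pairs),
        "n_merged": len(merged) if not single_end else len(pairs),
        "n_unmerged": len(unmerged),
        "overlap_histogram": dict(sorted(hist.items())),
    }
    return merged, unmerged, report
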
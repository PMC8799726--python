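"""Quality/adapter trimming and fuzzy internal-barcode demultiplexing.

The sixteen 8-nt internal barcodes sit in the reverse-primer tail, preceded
by a 4-nt random quatromer, so every read of a sample starts (on the
barcode-carrying mate) with ``[quatromer][barcode][amplicon...]``.  Reads
are assigned by error-tolerant semi-global matching: a barcode matches if
its best edit distance (substitutions + indels) anywhere in the search
window is at most ``floor(max_error_rate * barcode_length)`` — one error for
8-nt barcodes at the default rate of 0.15.  A read is assigned to the unique
barcode at minimal distance; ties and misses go to the unassigned pool, and
the matched barcode (with everything 5' of it) is removed from the read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .core import AmpliconDesign, Read, ReadPair

__all__ = [
    "BarcodeAssignment",
    "DemuxResult",
    "trim_reads",
    "trim_pairs",
    "demultiplex",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class BarcodeAssignment:
    """Outcome of barcode search for one read."""

    read_id: str
    sample_index: int  # UNASSIGNED (-1) when no unique barcode matched
    n_errors: int = -1
    match_offset: int = -1  # start of the barcode match in the read

    @property
    def assigned(self) -> bool:
        return self.sample_index != UNASSIGNED


@dataclass
class DemuxResult:
    """Per-sample read batches plus the unassigned pool and a report."""

    batches: dict[int, list[ReadPair]]
    unassigned: list[ReadPair]
    assignments: list[BarcodeAssignment]

    @property
    def n_input(self) -> int:
        return sum(len(b) for b in self.batches.values()) + len(self.unassigned)

    def report(self) -> pd.DataFrame:
        rows = []
        by_sample: dict[int, list[int]] = {}
        for a in self.assignments:
            if a.assigned:
                by_sample.setdefault(a.sample_index, []).append(a.n_errors)
        for idx in sorted(self.batches):
            errs = by_sample.get(idx, [])
            hist = {
                f"n_errors_{k}": sum(1 for e in errs if e == k) for k in range(3)
            }
            rows.append(
                {"sample_index": idx, "n_assigned": len(self.batches[idx]), **hist}
            )
        df = pd.DataFrame(rows)
        df["n_unassigned_total"] = len(self.unassigned)
        return df


# ---- trimming ----------------------------------------------------------


def _quality_trim_index(quals: str, cutoff: int) -> int:
    """3' quality trim position by the running-sum (BWA/cutadapt) rule.

    Subtract the cutoff from each quality, form partial sums from the 3'
    end, and cut at the position minimising the sum (5'-most minimum);
    no cut when the minimum is non-negative.
    """
    if cutoff <= 0 or not quals:
        return len(quals)
    q = np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
    # s[i] = sum_{j >= i} (q[j] - cutoff)
    s = np.cumsum((q - cutoff)[::-1])[::-1]
    i = int(np.argmin(s))
    return i if s[i] < 0 else len(quals)


def _find_adapter(seq: str, adapter: str, max_error_rate: float, min_overlap: int = 3):
    """Best 3'-adapter occurrence, cutadapt-style.

    The adapter may occur internally (full match, read continues past it) or
    run off the read's 3' end (a prefix of the adapter matching a suffix of
    the read).  Errors are edit operations, allowed up to
    ``floor(max_error_rate * matched_adapter_length)``.  Among qualifying
    matches the longest matched adapter prefix wins, then the fewest errors,
    then the leftmost start.  Returns the trim position or ``None``.
    """
    n, m = len(seq), len(adapter)
    if n == 0 or m == 0:
        return None
    # D[i][j]: min edit distance of adapter[:i] vs seq[start..j) over starts
    # S[i][j]: the start achieving it (leftmost on ties)
    dist = list(range(0, 1))  # placeholder; rows built iteratively
    prev_d = [0] * (n + 1)
    prev_s = list(range(n + 1))
    best = None  # (matched_len, -errors, -start) maximised

    def consider(matched_len: int, errors: int, start: int) -> None:
        nonlocal best
        if matched_len < min_overlap:
            return
        if errors > math.floor(max_error_rate * matched_len):
            return
        key = (matched_len, -errors, -start)
        if best is None or key > best:
            best = key

    for i in range(1, m + 1):
        cur_d = [0] * (n + 1)
        cur_s = [0] * (n + 1)
        cur_d[0] = i
        cur_s[0] = 0
        ai = adapter[i - 1]
        for j in range(1, n + 1):
            sub = prev_d[j - 1] + (ai != seq[j - 1])
            dele = prev_d[j] + 1  # adapter base unmatched
            ins = cur_d[j - 1] + 1  # extra read base inside the match
            d = min(sub, dele, ins)
            # leftmost start on ties, preferring the substitution path
            s_candidates = []
            if sub == d:
                s_candidates.append(prev_s[j - 1])
            if dele == d:
                s_candidates.append(prev_s[j])
            if ins == d:
                s_candidates.append(cur_s[j - 1])
            cur_d[j] = d
            cur_s[j] = min(s_candidates)
        # adapter prefix of length i ending exactly at the read's 3' end
        consider(i, cur_d[n], cur_s[n])
        if i == m:
            # full adapter ending anywhere in the read
            for j in range(1, n + 1):
                consider(m, cur_d[j], cur_s[j])
        prev_d, prev_s = cur_d, cur_s
    if best is None:
        return None
    return -best[2]


def trim_reads(
    reads: list[Read],
    quality_cutoff: int = 0,
    adapters: list[str] | None = None,
    max_error_rate: float = 0.1,
) -> list[Read]:
    """3' quality trimming followed by error-tolerant adapter removal.

    Reads are never lengthened; a read trimmed to zero length is kept as an
    empty record so downstream accounting stays exhaustive.
    """
    if quality_cutoff < 0:
        raise ValueError("quality_cutoff must be >= 0")
    adapters = [a.upper() for a in (adapters or [])]
    out = []
    for r in reads:
        seq, qual = r.seq, r.qual
        if quality_cutoff > 0:
            cut = _quality_trim_index(qual, quality_cutoff)
            seq, qual = seq[:cut], qual[:cut]
        for adapter in adapters:
            pos = _find_adapter(seq, adapter, max_error_rate)
            if pos is not None:
                seq, qual = seq[:pos], qual[:pos]
        out.append(Read(r.id, seq, qual))
    return out


def trim_pairs(
    pairs: list[ReadPair],
    quality_cutoff: int = 0,
    adapters: list[str] | None = None,
    max_error_rate: float = 0.1,
) -> list[ReadPair]:
    """Apply :func:`trim_reads` to both mates of every pair."""
    r1 = trim_reads([p.r1 for p in pairs], quality_cutoff, adapters, max_error_rate)
    mates = [p.r2 for p in pairs]
    paired_idx = [i for i, m in enumerate(mates) if m is not None]
    trimmed2 = trim_reads(
        [mates[i] for i in paired_idx], quality_cutoff, adapters, max_error_rate
    )
    for i, t in zip(paired_idx, trimmed2):
        mates[i] = t
    return [ReadPair(a, b) for a, b in zip(r1, mates)]


# ---- demultiplexing ----------------------------------------------------


def _search_barcodes(
    seq: str,
    barcodes: list[str],
    k: int,
    window_start: int,
    window_end: int,
) -> tuple[int, int, int]:
    """Best-matching barcode in ``seq[window_start:window_end]``.

    Returns ``(barcode_index, n_errors, match_end_in_read)``;
    barcode_index is UNASSIGNED on miss or tie at the best distance.
    """
    region = seq[window_start:window_end]
    if not region:
        return UNASSIGNED, -1, -1
    best_idx = UNASSIGNED
    best_d = k + 1
    best_end = -1
    tie = False
    for i, bc in enumerate(barcodes):
        res = edlib.align(bc, region, mode="HW", task="locations", k=k)
        d = res["editDistance"]
        if d == -1:
            continue
        if d < best_d:
            best_d, best_idx, tie = d, i, False
            best_end = window_start + res["locations"][0][1] + 1
        elif d == best_d:
            tie = True
    if best_idx == UNASSIGNED or tie:
        return UNASSIGNED, -1, -1
    return best_idx, best_d, best_end


def demultiplex(
    reads: list[ReadPair],
    design: AmpliconDesign,
    max_error_rate: float = 0.15,
    barcode_read: str = "r2",
    window: int | None = None,
    trim_barcode: bool = True,
) -> DemuxResult:
    """Partition read pairs by internal barcode.

    ``window`` restricts the barcode search to the read prefix
    ``[0, quatromer_length + barcode_length + window)`` — the expected
    barcode position plus slack; ``None`` searches the whole read.  Both
    modes agree whenever the barcode lies inside the window.  The assigned
    read is trimmed through the end of the barcode match, removing the
    quatromer and barcode.

    Every input read lands in exactly one output batch (including the
    unassigned pool).
    """
    if not design.barcodes:
        raise ValueError("design has no barcodes")
    if not (0.0 <= max_error_rate < 1.0):
        raise ValueError("max_error_rate must be in [0, 1)")
    if barcode_read not in ("r1", "r2"):
        raise ValueError("barcode_read must be 'r1' or 'r2'")
    barcodes = design.barcodes
    blen = design.barcode_length
    qlen = design.quatromer_length
    k = math.floor(max_error_rate * blen)

    bc_lookup = {bc: i for i, bc in enumerate(barcodes)}

    if window is not None:
        win_end = qlen + blen + max(window, k)
    else:
        win_end = None

    batches: dict[int, list[ReadPair]] = {i: [] for i in range(len(barcodes))}
    unassigned: list[ReadPair] = []
    assignments: list[BarcodeAssignment] = []

    use_r2 = barcode_read == "r2"
    for pair in reads:
        target = pair.r2 if (use_r2 and pair.r2 is not None) else pair.r1
        seq = target.seq
        idx = UNASSIGNED
        n_err = -1
        end = -1
        if win_end is not None:
            # anchored fast path: an exact barcode at the expected offset is
            # the assignment unless a competing barcode also occurs exactly
            # inside the window (a distance-0 match is exactly an exact
            # substring, so scanning the window's k-mers finds every
            # potential distance-0 tie)
            hit = bc_lookup.get(seq[qlen : qlen + blen])
            if hit is not None:
                region = seq[:win_end]
                competitors = {
                    bc_lookup[region[j : j + blen]]
                    for j in range(len(region) - blen + 1)
                    if region[j : j + blen] in bc_lookup
                }
                if competitors == {hit}:
                    idx, n_err, end = hit, 0, qlen + blen
        if idx == UNASSIGNED:
            idx, n_err, end = _search_barcodes(
                seq, barcodes, k, 0, len(seq) if win_end is None else win_end
            )
        assignments.append(
            BarcodeAssignment(target.id, idx, n_err, end - blen if end >= 0 else -1)
        )
        if idx == UNASSIGNED:
            unassigned.append(pair)
            continue
        if trim_barcode:
            trimmed = Read(target.id, seq[end:], target.qual[end:])
            if use_r2 and pair.r2 is not None:
                pair = ReadPair(pair.r1, trimmed)
            else:
                pair = ReadPair(trimmed, pair.r2)
        batches[idx].append(pair)
    return DemuxResult(batches=batches, unassigned=unassigned, assignments=assignments)
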
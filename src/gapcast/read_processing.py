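"""Long-read preprocessing algorithms used around hybrid correction.

Four independent tools:

* :func:`qv_trim` -- keep the longest stretch of a corrected read whose
  mean consensus quality strictly exceeds a threshold (default QV 54.5).
* :func:`subsample_longest` -- keep the longest reads up to a target
  coverage (default 25x) before assembly; overlap assemblers degrade on
  excessive coverage.
* :func:`detect_breakpoints` / :func:`split_read` -- find missed-adapter
  chimera junctions from short-read alignments that terminate in both
  orientations around a common point, and split the long read there.
* :func:`recruit_gap_support` / :func:`patch_consensus` -- recruit other
  long reads sharing the short-read anchors flanking a coverage gap and
  patch the gap with their consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import ShortAlignment, reverse_complement


@dataclass
class QualityRead:
    """A read with per-base Phred-scaled quality values."""

    name: str
    sequence: str
    qualities: List[float]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.name!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.name!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrimConfig:
    """Quality-trim settings; the mean-QV comparison is strict ('exceeds')."""

    qv_threshold: float = 54.5

    def __post_init__(self) -> None:
        if self.qv_threshold < 0:
            raise ValueError("qv_threshold must be >= 0")


def qv_trim(read: QualityRead, cfg: TrimConfig = TrimConfig()) -> Tuple[int, int]:
    """Longest interval (0-based half-open) with mean QV > threshold.

    Among equal-length maxima the leftmost wins; (0, 0) when no single base
    exceeds the threshold.  The mean is the arithmetic mean of the Phred
    values themselves (not of error probabilities).

    Equivalent to scanning every window (the brute-force oracle) but runs
    in O(n): with prefix sums P of (QV - threshold), a window [i, j) is
    admissible iff P[j] - P[i] > 0, and only the strictly decreasing
    prefix minima are useful starts / strictly decreasing suffix maxima
    useful ends.
    """
    if len(read) == 0:
        raise ValueError("read is empty")
    q = np.asarray(read.qualities, dtype=float) - cfg.qv_threshold
    prefix = np.concatenate(([0.0], np.cumsum(q)))
    n = len(prefix)

    starts = []  # strictly decreasing prefix minima, ascending index
    best = np.inf
    for i in range(n):
        if prefix[i] < best:
            starts.append(i)
            best = prefix[i]
    ends = []  # indices j whose prefix exceeds everything to their right
    best = -np.inf
    for j in range(n - 1, -1, -1):
        if prefix[j] > best:
            ends.append(j)
            best = prefix[j]
    ends.reverse()  # ascending index, strictly decreasing prefix value

    best_len, best_start = 0, 0
    t = -1  # last valid end index; only advances as prefix[i] decreases
    for i in starts:
        while t + 1 < len(ends) and prefix[ends[t + 1]] > prefix[i]:
            t += 1
        if t >= 0 and prefix[ends[t]] > prefix[i]:
            j = ends[t]
            if j - i > best_len:
                best_len, best_start = j - i, i
    if best_len == 0:
        return (0, 0)
    return (best_start, best_start + best_len)


def qv_trim_bruteforce(read: QualityRead, cfg: TrimConfig = TrimConfig()) -> Tuple[int, int]:
    """O(n^2) reference implementation of :func:`qv_trim` (test oracle)."""
    q = np.asarray(read.qualities, dtype=float) - cfg.qv_threshold
    prefix = np.concatenate(([0.0], np.cumsum(q)))
    n = len(q)
    for length in range(n, 0, -1):
        for start in range(0, n - length + 1):
            if prefix[start + length] - prefix[start] > 0:
                return (start, start + length)
    return (0, 0)


def subsample_longest(
    read_lengths: Sequence[int], genome_size: int, target_cov: float = 25.0
) -> List[int]:
    """Indices of the longest reads reaching ``target_cov`` x genome size.

    Reads are taken longest-first (ties broken by input order) until the
    cumulative length first reaches the target; if the total falls short,
    every read is selected.  Target 0 selects nothing.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if target_cov <= 0:
        return []
    target = target_cov * genome_size
    order = sorted(range(len(read_lengths)), key=lambda i: (-read_lengths[i], i))
    selected: List[int] = []
    cum = 0
    for i in order:
        selected.append(i)
        cum += read_lengths[i]
        if cum >= target:
            break
    return selected


@dataclass
class BreakpointConfig:
    """Chimera-junction detection settings.

    A split needs corroboration: at least ``min_support_per_orientation``
    alignment endpoints in *each* orientation within ``window`` bases of a
    common point.
    """

    window: int = 50
    min_support_per_orientation: int = 2

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_support_per_orientation < 1:
            raise ValueError("min_support_per_orientation must be >= 1")


def detect_breakpoints(
    alignments: Sequence[ShortAlignment], cfg: BreakpointConfig = BreakpointConfig()
) -> List[int]:
    """Chimera junction positions on one long read from its short-read hits.

    A missed SMRTbell adapter joins a sequence to its reverse complement;
    short-read alignments then terminate at the junction in both
    orientations.  Every alignment contributes both of its endpoints,
    tagged with its strand; a position qualifies when both orientations
    have enough endpoints within ``window`` of it; qualifying positions
    closer than ``window`` apart are clustered and reduced to their median.
    """
    events: List[Tuple[int, str]] = []
    for aln in alignments:
        events.append((aln.target_start, aln.strand))
        events.append((aln.target_end, aln.strand))
    if not events:
        return []
    events.sort()
    positions = np.array([p for p, _ in events])
    fwd = np.sort(np.array([p for p, s in events if s == "+"], dtype=int))
    rev = np.sort(np.array([p for p, s in events if s == "-"], dtype=int))

    def support(arr: np.ndarray, p: int) -> int:
        return int(
            np.searchsorted(arr, p + cfg.window, side="right")
            - np.searchsorted(arr, p - cfg.window, side="left")
        )

    qualifying = [
        int(p)
        for p in positions
        if support(fwd, int(p)) >= cfg.min_support_per_orientation
        and support(rev, int(p)) >= cfg.min_support_per_orientation
    ]
    if not qualifying:
        return []
    clusters: List[List[int]] = [[qualifying[0]]]
    for p in qualifying[1:]:
        if p - clusters[-1][-1] <= cfg.window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return [int(median_low(c)) for c in clusters]


def split_read(read: QualityRead, positions: Sequence[int]) -> List[QualityRead]:
    """Partition a read at the given positions (strictly inside, sorted).

    Subread names get ``/1``, ``/2``, ... suffixes; concatenating the
    subreads reproduces the original sequence and qualities exactly.
    """
    for p in positions:
        if not (0 < p < len(read)):
            raise ValueError(f"split position {p} outside read of length {len(read)}")
    if list(positions) != sorted(positions):
        raise ValueError("split positions must be sorted")
    if not positions:
        return [read]
    bounds = [0, *positions, len(read)]
    return [
        QualityRead(
            name=f"{read.name}/{i + 1}",
            sequence=read.sequence[a:b],
            qualities=read.qualities[a:b],
        )
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
    ]


@dataclass
class GapContext:
    """A coverage gap on a long read and its flanking short-read anchors.

    ``flank_left`` / ``flank_right`` are (short_read_name, strand) pairs in
    coordinate order on the gapped read, taken from within ``window`` bases
    of the gap.
    """

    long_read: str
    gap_start: int
    gap_end: int
    flank_left: List[Tuple[str, str]] = field(default_factory=list)
    flank_right: List[Tuple[str, str]] = field(default_factory=list)
    window: int = 500

    def __post_init__(self) -> None:
        if self.gap_start > self.gap_end:
            raise ValueError("gap_start must be <= gap_end")


def build_gap_context(
    long_read: str,
    gap_start: int,
    gap_end: int,
    alignments: Sequence[ShortAlignment],
    window: int = 500,
) -> GapContext:
    """Select the anchor short reads within ``window`` of a coverage gap."""
    left, right = [], []
    for aln in alignments:
        if aln.target_name != long_read:
            continue
        if gap_start - window <= aln.target_end <= gap_start:
            left.append((aln.target_end, aln.query_name, aln.strand))
        if gap_end <= aln.target_start <= gap_end + window:
            right.append((aln.target_start, aln.query_name, aln.strand))
    left.sort()
    right.sort()
    return GapContext(
        long_read=long_read,
        gap_start=gap_start,
        gap_end=gap_end,
        flank_left=[(n, s) for _, n, s in left],
        flank_right=[(n, s) for _, n, s in right],
        window=window,
    )


def recruit_gap_support(
    gap: GapContext,
    alignments: Sequence[ShortAlignment],
    long_reads: Dict[str, str],
) -> List[Tuple[str, str]]:
    """Recruit gap-filling subsequences from other long reads.

    A long read is recruited when it contains alignments of *all* the
    anchor short reads in the same relative order and orientation as on
    the gapped read -- or in fully reversed order with flipped strands, in
    which case its subsequence is reverse-complemented.  The returned
    subsequences run between the innermost anchors (the region covering
    the gap).  Returns (source long read name, subsequence) pairs.
    """
    if not gap.flank_left or not gap.flank_right:
        raise ValueError("gap context needs at least one anchor on each side")
    anchors = [*gap.flank_left, *gap.flank_right]
    anchor_names = [n for n, _ in anchors]
    n_left = len(gap.flank_left)

    by_read: Dict[str, List[ShortAlignment]] = {}
    for aln in alignments:
        by_read.setdefault(aln.target_name, []).append(aln)

    out: List[Tuple[str, str]] = []
    for name, alns in by_read.items():
        if name == gap.long_read or name not in long_reads:
            continue
        hits = {a.query_name: a for a in alns if a.query_name in anchor_names}
        if len(hits) < len(anchor_names):
            continue
        ordered = sorted(hits.values(), key=lambda a: a.target_start)
        order = [a.query_name for a in ordered]
        strands = {a.query_name: a.strand for a in ordered}
        same = order == anchor_names and all(
            strands[n] == s for n, s in anchors
        )
        flip = order == anchor_names[::-1] and all(
            strands[n] == ("-" if s == "+" else "+") for n, s in anchors
        )
        if not (same or flip):
            continue
        seq = long_reads[name]
        if same:
            inner_left = hits[gap.flank_left[-1][0]]
            inner_right = hits[gap.flank_right[0][0]]
            sub = seq[inner_left.target_end : inner_right.target_start]
        else:
            # reversed: the right anchors come first on this read
            inner_right = hits[gap.flank_right[0][0]]
            inner_left = hits[gap.flank_left[-1][0]]
            sub = reverse_complement(
                seq[inner_right.target_end : inner_left.target_start]
            )
        out.append((name, sub))
    return out


def _banded_edit_alignment(center: str, other: str, band: int) -> List[Optional[str]]:
    """Align ``other`` to ``center``; per center column, the aligned base.

    Banded global edit-distance DP with traceback; a center column covered
    by a deletion in ``other`` yields None; insertions in ``other`` are
    dropped (star-alignment simplification).
    """
    n, m = len(center), len(other)
    band = max(band, abs(n - m) + 1)
    INF = 1 << 30
    # dp[i][j] over j in [max(0,i-band), min(m,i+band)]
    prev = {0: 0}
    for j in range(1, min(m, band) + 1):
        prev[j] = j
    back: List[Dict[int, str]] = [{} for _ in range(n + 1)]
    for j in prev:
        back[0][j] = "I" if j else "S"
    for i in range(1, n + 1):
        cur: Dict[int, int] = {}
        lo, hi = max(0, i - band), min(m, i + band)
        for j in range(lo, hi + 1):
            best, op = INF, "?"
            up = prev.get(j, INF) + 1  # deletion in other (gap vs center)
            if up < best:
                best, op = up, "D"
            left = cur.get(j - 1, INF) + 1  # insertion in other
            if left < best:
                best, op = left, "I"
            if j > 0:
                diag = prev.get(j - 1, INF) + (center[i - 1] != other[j - 1])
                if diag <= best:  # prefer matches on ties
                    best, op = diag, "M"
            cur[j] = best
            back[i][j] = op
        prev = cur
    # traceback
    cols: List[Optional[str]] = [None] * n
    i, j = n, m
    while i > 0 or j > 0:
        op = back[i].get(j)
        if op is None:  # fell off the band; treat as deletion
            op = "D" if i > 0 else "I"
        if op == "M":
            cols[i - 1] = other[j - 1]
            i, j = i - 1, j - 1
        elif op == "D":
            cols[i - 1] = None
            i -= 1
        elif op == "I":
            j -= 1
        else:
            break
    return cols


def patch_consensus(candidates: Sequence[str], band: int = 32) -> str:
    """Star consensus of gap-patch candidates.

    The candidate of median length is the centre; every other candidate is
    aligned to it by banded edit distance and each centre column is called
    by plurality (the centre's own base wins ties; a plurality of
    deletions removes the column).  A single candidate is returned as-is.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if len(candidates) == 1:
        return candidates[0]
    order = sorted(range(len(candidates)), key=lambda i: (len(candidates[i]), i))
    center_idx = order[(len(order) - 1) // 2]
    center = candidates[center_idx]
    votes: List[Dict[Optional[str], int]] = [dict() for _ in center]
    for col, base in enumerate(center):
        votes[col][base] = 1
    for i, cand in enumerate(candidates):
        if i == center_idx:
            continue
        for col, base in enumerate(_banded_edit_alignment(center, cand, band)):
            votes[col][base] = votes[col].get(base, 0) + 1
    out = []
    for col, tally in enumerate(votes):
        winner = max(
            tally.items(),
            key=lambda kv: (kv[1], kv[0] == center[col], kv[0] is not None),
        )[0]
        if winner is not None:
            out.append(winner)
    return "".join(out)
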
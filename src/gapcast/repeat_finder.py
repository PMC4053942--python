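"""Maximal repeat detection and genome complexity classification.

The detector finds every maximal exact match (>= ``min_len``) between two
distinct genomic loci, including matches between replicons and in inverted
orientation, using a suffix array + LCP over the concatenation of all
replicons and their reverse complements.  Diverged repeat copies (identity
below 100%) are recovered by co-linear chaining of exact matches, mirroring
what an external aligner such as ``nucmer --maxmatch --nosimplify`` followed
by ``delta-filter -l 500 -i 95`` reports.  Match lists produced by such an
aligner can be substituted via :func:`gapcast.genome_io.read_coords_table`.

Matches are then reduced to intervals along the genome: both loci of every
match are projected, intervals strictly contained in a larger interval are
discarded, the repeat count is the number of remaining intervals and the
longest one is the maximum repeat size.  Overlapping or abutting intervals
are additionally merged into disjoint blocks for the closure simulation,
where an unspanned merged block is what produces an assembly gap.

Complexity classes
------------------
* class I   -- few repeats; the rDNA operon (5-7 kbp) is the largest.
* class II  -- many mid-scale repeats (insertion sequences etc.) but none
  longer than the rDNA benchmark.
* class III -- at least one repeat exceeding 7 kbp (prophage, segmental
  duplication, large tandem array); unresolvable even by long reads unless
  the read length distribution reaches past the repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import GenomeSet, MatchRecord, reverse_complement


@dataclass
class RepeatFilter:
    """Minimum length / identity for a repeat to count."""

    min_len: int = 500
    min_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class ClassThresholds:
    """Boundaries between the three complexity classes.

    Both comparisons are strict: class III needs a repeat strictly longer
    than ``class3_max_repeat``; class II needs strictly more than
    ``class2_copy_count`` repeat intervals.
    """

    class3_max_repeat: int = 7000
    class2_copy_count: int = 100

    def __post_init__(self) -> None:
        if self.class3_max_repeat <= 0 or self.class2_copy_count <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat occurrence on one replicon, 0-based half-open."""

    replicon: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatProfile:
    """Per-genome repeat summary driving classification and closure."""

    intervals: List[RepeatInterval] = field(default_factory=list)
    merged_intervals: List[RepeatInterval] = field(default_factory=list)
    genome_class: str = "I"

    @property
    def repeat_count(self) -> int:
        return len(self.intervals)

    @property
    def max_repeat(self) -> int:
        return max((iv.length for iv in self.intervals), default=0)


# ---------------------------------------------------------------------------
# suffix array machinery
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _suffix_array(arr: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorised)."""
    n = len(arr)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    order = np.argsort(rank, kind="stable")
    k = 1
    while True:
        idx = np.arange(n)
        key2 = np.full(n, -1, dtype=np.int64)
        valid = idx + k < n
        key2[valid] = rank[idx[valid] + k]
        order = np.lexsort((key2, rank))
        r_o, k_o = rank[order], key2[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _lcp_kasai(arr: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array (Kasai); lcp[i] = longest common prefix of sa[i-1], sa[i]."""
    n = len(arr)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    a = arr.tolist()
    ra = rank.tolist()
    sal = sa.tolist()
    h = 0
    for i in range(n):
        r = ra[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and a[i + h] == a[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass
class _Unit:
    """One strand of one replicon inside the concatenated text."""

    rep_index: int
    name: str
    strand: str  # '+' or '-'
    text_start: int
    ext_len: int  # length including circular extension
    true_len: int  # replicon length


def _encode_units(genome: GenomeSet, min_len: int) -> Tuple[np.ndarray, List[_Unit]]:
    """Concatenate fwd and rc copies of every replicon with unique sentinels.

    Each N base and each separator gets its own unique integer code so that
    nothing ever matches across a separator and runs of N can never form a
    repeat (an N mismatches everything, including other Ns).  Circular
    replicons are extended by their first ``min_len - 1`` bases so matches
    crossing the origin are seen; the self-match this copy creates is
    shorter than ``min_len`` and therefore filtered out.
    """
    pieces: List[np.ndarray] = []
    units: List[_Unit] = []
    next_code = 4
    pos = 0

    def encode(seq: str) -> np.ndarray:
        nonlocal next_code
        out = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq):
            code = _BASE_CODE.get(ch)
            if code is None:
                code = next_code
                next_code += 1
            out[i] = code
        return out

    for ri, rep in enumerate(genome):
        ext = rep.sequence
        if rep.circular and min_len > 1:
            ext = ext + rep.sequence[: min_len - 1]
        for strand, seq in (("+", ext), ("-", reverse_complement(ext))):
            enc = encode(seq)
            units.append(_Unit(ri, rep.name, strand, pos, len(enc), rep.length))
            pieces.append(enc)
            pieces.append(np.array([next_code], dtype=np.int64))
            next_code += 1
            pos += len(enc) + 1
    return np.concatenate(pieces), units


def _locate(units: List[_Unit], pos: int) -> _Unit:
    for u in units:
        if u.text_start <= pos < u.text_start + u.ext_len:
            return u
    raise ValueError(f"position {pos} falls on a separator")


def find_exact_maximal_repeats(
    genome: GenomeSet, min_len: int = 500
) -> List[MatchRecord]:
    """Enumerate maximal exact matches >= ``min_len`` between distinct loci.

    Each unordered pair of loci is reported once; self-identity matches on
    the main diagonal (a locus against itself, in either orientation) are
    discarded.  Inverted matches are mapped back to forward coordinates and
    flagged via a decreasing second coordinate pair, as ``show-coords``
    prints them.
    """
    if genome.total_length == 0:
        return []
    arr, units = _encode_units(genome, min_len)
    sa = _suffix_array(arr)
    lcp = _lcp_kasai(arr, sa)
    n = len(arr)
    unit_starts = np.array([u.text_start for u in units])
    unit_of = np.searchsorted(unit_starts, sa, side="right") - 1

    seen: set = set()
    out: List[MatchRecord] = []

    # maximal runs of adjacent suffixes with lcp >= min_len
    q = 1
    while q < n:
        if lcp[q] < min_len:
            q += 1
            continue
        lo = q - 1
        while q < n and lcp[q] >= min_len:
            q += 1
        hi = q - 1  # suffixes sa[lo..hi] pairwise share >= min_len
        group = list(range(lo, hi + 1))
        # left-maximality needs differing preceding characters; groups where
        # every suffix is preceded by the same character (interior offsets
        # of a long repeat) contain no maximal pair and are skipped outright
        prev_char = [int(arr[sa[g] - 1]) if sa[g] > 0 else -1 for g in group]
        if len(set(prev_char)) == 1 and prev_char[0] != -1:
            continue
        for xi in range(len(group)):
            run_min = None
            for yi in range(xi + 1, len(group)):
                x, y = group[xi], group[yi]
                step = lcp[y]
                run_min = step if run_min is None else min(run_min, step)
                if run_min < min_len:
                    break
                if prev_char[xi] == prev_char[yi] and prev_char[xi] != -1:
                    continue
                p1, p2 = int(sa[x]), int(sa[y])
                rec = _make_record(units, int(unit_of[x]), int(unit_of[y]), p1, p2, int(run_min))
                if rec is None:
                    continue
                key = _canonical_key(rec)
                if key in seen:
                    continue
                seen.add(key)
                out.append(rec)
    out.sort(key=lambda r: (r.replicon_a, r.ref_a_start, r.replicon_b, r.ref_b_start))
    return out


def _side_to_forward(u: _Unit, pos_in_unit: int, length: int) -> Tuple[int, str]:
    """Map a match locus on either strand to forward-strand start (mod L)."""
    if u.strand == "+":
        start = pos_in_unit
    else:
        start = u.ext_len - (pos_in_unit + length)
    return start % u.true_len, u.strand


def _make_record(
    units: List[_Unit], ui: int, uj: int, p1: int, p2: int, length: int
) -> Optional[MatchRecord]:
    u1, u2 = units[ui], units[uj]
    length = min(length, u1.true_len, u2.true_len)
    s1, st1 = _side_to_forward(u1, p1 - u1.text_start, length)
    s2, st2 = _side_to_forward(u2, p2 - u2.text_start, length)
    orientation = "forward" if st1 == st2 else "inverted"
    # drop the main diagonal: same locus against itself
    if u1.rep_index == u2.rep_index and s1 == s2:
        return None
    # canonical side order
    a = (u1.name, u1.rep_index, s1)
    b = (u2.name, u2.rep_index, s2)
    if (b[1], b[2]) < (a[1], a[2]):
        a, b = b, a
    name_a, _, start_a = a
    name_b, _, start_b = b
    if orientation == "forward":
        rec = MatchRecord(
            ref_a_start=start_a + 1,
            ref_a_end=start_a + length,
            ref_b_start=start_b + 1,
            ref_b_end=start_b + length,
            identity=100.0,
            replicon_a=name_a,
            replicon_b=name_b,
            orientation="forward",
        )
    else:
        rec = MatchRecord(
            ref_a_start=start_a + 1,
            ref_a_end=start_a + length,
            ref_b_start=start_b + length,
            ref_b_end=start_b + 1,
            identity=100.0,
            replicon_a=name_a,
            replicon_b=name_b,
            orientation="inverted",
        )
    return rec


def _canonical_key(rec: MatchRecord) -> tuple:
    return (
        rec.replicon_a,
        rec.ref_a_start,
        rec.ref_a_end,
        rec.replicon_b,
        rec.ref_b_start,
        rec.ref_b_end,
        rec.orientation,
    )


# ---------------------------------------------------------------------------
# chaining of exact matches into approximate repeats
# ---------------------------------------------------------------------------


def chain_matches(
    matches: Sequence[MatchRecord],
    filt: RepeatFilter = RepeatFilter(),
    max_gap: int = 90,
    genome: Optional[GenomeSet] = None,
) -> List[MatchRecord]:
    """Chain co-linear exact matches into approximate repeat matches.

    Exact matches on the same (replicon_a, replicon_b, orientation) diagonal
    band separated by at most ``max_gap`` on both copies are merged; the
    chain's identity is matched bases divided by the chained span (the
    longer of the two sides).  Chains (or single matches) failing the
    length/identity filter are dropped.  This approximates how an aligner
    with affine tolerance reports diverged repeat copies.

    When ``genome`` is given and the two chained loci have equal length,
    the identity is recomputed exactly by base-wise comparison of the loci
    (the matched/span ratio undercounts whenever an exact segment shorter
    than the seed length hides inside a gap).
    """
    groups: Dict[tuple, List[MatchRecord]] = {}
    for m in matches:
        groups.setdefault((m.replicon_a, m.replicon_b, m.orientation), []).append(m)

    out: List[MatchRecord] = []
    for (rep_a, rep_b, orientation), group in groups.items():
        group = sorted(group, key=lambda m: m.ref_a_start)
        used = [False] * len(group)
        for i, m in enumerate(group):
            if used[i]:
                continue
            chain = [m]
            used[i] = True
            cur = m
            for j in range(i + 1, len(group)):
                if used[j]:
                    continue
                nxt = group[j]
                gap_a = nxt.ref_a_start - cur.ref_a_end - 1
                if orientation == "forward":
                    gap_b = nxt.ref_b_start - cur.ref_b_end - 1
                else:
                    # inverted: b coordinates run backwards as a advances
                    gap_b = cur.ref_b_end - nxt.ref_b_start - 1
                if 0 <= gap_a <= max_gap and 0 <= gap_b <= max_gap:
                    chain.append(nxt)
                    used[j] = True
                    cur = nxt
                elif gap_a > max_gap:
                    break
            matched = sum(c.len_a for c in chain)
            a_start = chain[0].ref_a_start
            a_end = chain[-1].ref_a_end
            if orientation == "forward":
                b_start = chain[0].ref_b_start
                b_end = chain[-1].ref_b_end
            else:
                b_start = chain[0].ref_b_start  # largest b coordinate
                b_end = chain[-1].ref_b_end  # smallest b coordinate
            span = max(a_end - a_start + 1, abs(b_end - b_start) + 1)
            identity = matched / span
            if genome is not None:
                refined = _verify_identity(
                    genome, rep_a, a_start, a_end, rep_b, b_start, b_end, orientation
                )
                if refined is not None:
                    identity = refined
            if span >= filt.min_len and identity >= filt.min_identity:
                out.append(
                    MatchRecord(
                        ref_a_start=a_start,
                        ref_a_end=a_end,
                        ref_b_start=b_start,
                        ref_b_end=b_end,
                        identity=round(identity * 100.0, 4),
                        replicon_a=rep_a,
                        replicon_b=rep_b,
                        orientation=orientation,
                    )
                )
    out.sort(key=lambda r: (r.replicon_a, r.ref_a_start, r.replicon_b, r.ref_b_start))
    return out


def _extract_locus(genome: GenomeSet, rep: str, start1: int, end1: int) -> str:
    """Sequence of a 1-based inclusive locus, wrapping circular replicons."""
    replicon = genome[rep]
    s, e = start1 - 1, end1
    if e <= replicon.length:
        return replicon.sequence[s:e]
    if not replicon.circular:
        return replicon.sequence[s:]
    return (replicon.sequence * 2)[s:e]


def _verify_identity(
    genome: GenomeSet,
    rep_a: str,
    a_start: int,
    a_end: int,
    rep_b: str,
    b_start: int,
    b_end: int,
    orientation: str,
) -> Optional[float]:
    """Exact identity of two equal-length loci by base-wise comparison."""
    seq_a = _extract_locus(genome, rep_a, a_start, a_end)
    lo, hi = sorted((b_start, b_end))
    seq_b = _extract_locus(genome, rep_b, lo, hi)
    if orientation == "inverted":
        seq_b = reverse_complement(seq_b)
    if len(seq_a) != len(seq_b):
        return None  # indel divergence: keep the matched/span estimate
    same = sum(a == b and a != "N" for a, b in zip(seq_a, seq_b))
    return same / len(seq_a)


# ---------------------------------------------------------------------------
# interval reduction and classification
# ---------------------------------------------------------------------------


def _project_intervals(
    matches: Sequence[MatchRecord], lengths: Dict[str, int]
) -> List[RepeatInterval]:
    """Project both loci of every match to 0-based half-open intervals.

    Matches crossing a circular origin (end > replicon length) are split at
    the origin.  Inter-replicon matches contribute an interval on each
    replicon.
    """
    intervals: List[RepeatInterval] = []

    def add(rep: str, start0: int, end0: int) -> None:
        if rep not in lengths:
            raise ValueError(f"match references unknown replicon {rep!r}")
        L = lengths[rep]
        if end0 <= L:
            intervals.append(RepeatInterval(rep, start0, end0))
        else:
            intervals.append(RepeatInterval(rep, start0, L))
            intervals.append(RepeatInterval(rep, 0, end0 - L))

    for m in matches:
        add(m.replicon_a, m.ref_a_start - 1, m.ref_a_end)
        b_lo, b_hi = sorted((m.ref_b_start, m.ref_b_end))
        add(m.replicon_b, b_lo - 1, b_hi)
    return intervals


def _remove_contained(intervals: List[RepeatInterval]) -> List[RepeatInterval]:
    """Drop intervals strictly contained within a strictly larger one.

    Duplicates collapse to a single copy; equal-span overlapping intervals
    are both kept (containment requires strict inclusion in a larger span).
    """
    result: List[RepeatInterval] = []
    by_rep: Dict[str, List[RepeatInterval]] = {}
    for iv in set(intervals):
        by_rep.setdefault(iv.replicon, []).append(iv)
    for rep, ivs in sorted(by_rep.items()):
        ivs.sort(key=lambda iv: (iv.start, -iv.end))
        kept: List[RepeatInterval] = []
        max_end = -1
        for iv in ivs:
            # sorted by start asc, end desc: iv is contained iff some earlier
            # interval reaches at least as far right (strictly larger since
            # equal spans at equal start collapse via the set above)
            if iv.end <= max_end:
                continue
            kept.append(iv)
            max_end = iv.end
        result.extend(kept)
    return result


def merge_intervals(intervals: Sequence[RepeatInterval]) -> List[RepeatInterval]:
    """Union of intervals: overlapping or abutting occurrences merged."""
    by_rep: Dict[str, List[RepeatInterval]] = {}
    for iv in intervals:
        by_rep.setdefault(iv.replicon, []).append(iv)
    merged: List[RepeatInterval] = []
    for rep, ivs in sorted(by_rep.items()):
        ivs.sort(key=lambda iv: iv.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or abut
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(RepeatInterval(rep, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(RepeatInterval(rep, cur_s, cur_e))
    return merged


def classify(
    repeat_count: int, max_repeat: int, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Assign the complexity class from repeat count and max repeat size."""
    if repeat_count < 0 or max_repeat < 0:
        raise ValueError("inputs must be non-negative")
    if max_repeat > thresholds.class3_max_repeat:
        return "III"
    if repeat_count > thresholds.class2_copy_count:
        return "II"
    return "I"


def matches_to_profile(
    matches: Sequence[MatchRecord],
    genome: GenomeSet,
    filt: RepeatFilter = RepeatFilter(),
    thresholds: ClassThresholds = ClassThresholds(),
) -> RepeatProfile:
    """Reduce repeat matches to a per-genome :class:`RepeatProfile`."""
    lengths = {r.name: r.length for r in genome}
    keep = [
        m
        for m in matches
        if m.span >= filt.min_len and m.identity / 100.0 >= filt.min_identity
    ]
    intervals = _remove_contained(_project_intervals(keep, lengths))
    intervals.sort(key=lambda iv: (iv.replicon, iv.start))
    merged = merge_intervals(intervals) if intervals else []
    count = len(intervals)
    max_rep = max((iv.length for iv in intervals), default=0)
    return RepeatProfile(
        intervals=intervals,
        merged_intervals=merged,
        genome_class=classify(count, max_rep, thresholds),
    )


def profile_genome(
    genome: GenomeSet,
    filt: RepeatFilter = RepeatFilter(),
    thresholds: ClassThresholds = ClassThresholds(),
    max_gap: int = 90,
) -> RepeatProfile:
    """End-to-end repeat profiling: detect, chain, reduce, classify."""
    # chaining recovers diverged copies from exact seed matches; exact
    # matches >= min_len survive as chains of one with identity 1.0.  The
    # seed is a fraction of the expected exact-segment length at the
    # identity floor, so most segments between substitutions are seen.
    if filt.min_identity < 1.0:
        seed_len = min(
            filt.min_len, max(16, round(0.8 / (1.0 - filt.min_identity)))
        )
    else:
        seed_len = filt.min_len
    exact = find_exact_maximal_repeats(genome, min_len=seed_len)
    chained = chain_matches(exact, filt=filt, genome=genome)
    return matches_to_profile(chained, genome, filt=filt, thresholds=thresholds)
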
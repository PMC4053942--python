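"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Set, Tuple

import numpy as np
import pytest

from gapcast.genome_io import GenomeSet, MatchRecord, reverse_complement


# ---------------------------------------------------------------------------
# brute-force maximal-repeat oracle (seed-and-extend on explicit strings)
# ---------------------------------------------------------------------------

MatchTuple = Tuple[int, int, int, str]  # (start_a, start_b, length, orientation)


def oracle_mems(seq: str, min_len: int) -> Set[MatchTuple]:
    """All maximal exact matches >= min_len in one linear sequence.

    Independent of the suffix-array path: hash every min_len-mer of the
    sequence and its reverse complement, extend each seed pair outward to
    its mismatch boundaries, and canonicalise.  Self-identity (diagonal)
    matches are excluded.
    """
    n = len(seq)
    rc = reverse_complement(seq)
    strands = {"+": seq, "-": rc}
    seeds: Dict[str, List[Tuple[str, int]]] = {}
    for strand, text in strands.items():
        for i in range(n - min_len + 1):
            seeds.setdefault(text[i : i + min_len], []).append((strand, i))

    found: Set[MatchTuple] = set()
    for occs in seeds.values():
        for (s1, i), (s2, j) in combinations(occs, 2):
            t1, t2 = strands[s1], strands[s2]
            a = 0
            while i - a - 1 >= 0 and j - a - 1 >= 0 and t1[i - a - 1] == t2[j - a - 1]:
                a += 1
            b = min_len
            while i + b < n and j + b < n and t1[i + b] == t2[j + b]:
                b += 1
            length = a + b
            p1, p2 = i - a, j - a
            f1 = p1 if s1 == "+" else n - (p1 + length)
            f2 = p2 if s2 == "+" else n - (p2 + length)
            orientation = "forward" if s1 == s2 else "inverted"
            if f1 == f2:
                continue  # same locus (palindrome diagonal or identity)
            lo, hi = sorted((f1, f2))
            found.add((lo, hi, length, orientation))
    return found


def matches_as_tuples(matches: List[MatchRecord]) -> Set[MatchTuple]:
    out: Set[MatchTuple] = set()
    for m in matches:
        a = m.ref_a_start - 1
        b = min(m.ref_b_start, m.ref_b_end) - 1
        lo, hi = sorted((a, b))
        out.add((lo, hi, m.len_a, m.orientation))
    return out


# ---------------------------------------------------------------------------
# naive de Bruijn unitig oracle (explicit k-mer strings, no hashing)
# ---------------------------------------------------------------------------


def naive_unitig_count(genome: GenomeSet, k: int) -> Tuple[int, int]:
    """(unitig count, distinct canonical k-mer count) via explicit strings."""

    def canonical(s: str) -> Tuple[str, str]:
        r = reverse_complement(s)
        return (s, "+") if s <= r else (r, "-")

    walks: List[List[Tuple[str, str]]] = []
    for rep in genome:
        if rep.length < k:
            continue
        seq = rep.sequence + (rep.sequence[: k - 1] if rep.circular else "")
        n_pos = rep.length if rep.circular else rep.length - k + 1
        walk = [canonical(seq[i : i + k]) for i in range(n_pos)]
        if rep.circular:
            walk.append(walk[0])  # closing edge
        walks.append(walk)

    nodes = {kmer for walk in walks for kmer, _ in walk}
    sides: Dict[Tuple[str, str], Set[Tuple[str, str]]] = {}
    edges: Set[Tuple[Tuple[str, str], Tuple[str, str]]] = set()
    for walk in walks:
        for (u, ou), (v, ov) in zip(walk, walk[1:]):
            a = (u, "t" if ou == "+" else "h")
            b = (v, "h" if ov == "+" else "t")
            edge = tuple(sorted((a, b)))
            if edge in edges:
                continue
            edges.add(edge)
            sides.setdefault(a, set()).add(b)
            sides.setdefault(b, set()).add(a)

    parent = {u: u for u in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_unitigs = len(nodes)
    for a, b in edges:
        if a != b and len(sides[a]) == 1 and len(sides[b]) == 1:
            ra, rb = find(a[0]), find(b[0])
            if ra != rb:
                parent[rb] = ra
                n_unitigs -= 1
    return n_unitigs, len(nodes)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(20130913)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
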
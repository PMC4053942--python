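"""Error-free de Bruijn graph complexity of a reference genome.

For a word size k, the nodes are the distinct canonical k-mers of the
genome (a k-mer and its reverse complement are the same node, giving a
bidirected graph that respects double-stranded DNA) and edges are the
observed k-1 overlaps.  Non-branching paths are maximally collapsed, so
each remaining node is a contig (unitig) and each remaining edge an
adjacency the assembler cannot resolve.  A circular replicon with no
repeat of length >= k-1 collapses to a single, self-adjacent unitig; the
unitig count at increasing k is therefore a direct readout of how long
reads must be to assemble the genome without gaps.

k-mers are identified by a pair of independent 61-bit polynomial rolling
hashes of the forward and reverse-complement word, so memory stays
proportional to genome length and independent of k (large k, e.g. 5,000,
is the interesting regime).  A collision would require two distinct
k-mers agreeing on both 61-bit hashes in both orientations; for genomes
up to hundreds of megabases the probability is < 1e-20.

k-mers containing N are excluded and break the walk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genome_io import GenomeSet

_MOD = (1 << 61) - 1
_B1 = 1000003
_B2 = 999999937
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class Unitig:
    uid: int
    n_kmers: int
    k: int
    self_adjacent: bool = False

    @property
    def length(self) -> int:
        return self.n_kmers + self.k - 1


@dataclass
class UnitigGraph:
    """Compacted de Bruijn graph summary."""

    k: int
    unitigs: List[Unitig] = field(default_factory=list)
    adjacencies: List[Tuple[int, str, int, str]] = field(default_factory=list)
    n_kmers: int = 0

    @property
    def n_unitigs(self) -> int:
        return len(self.unitigs)

    @property
    def self_adjacent_count(self) -> int:
        return sum(u.self_adjacent for u in self.unitigs)


def _prefix_hashes(codes: Sequence[int], base: int) -> List[int]:
    pre = [0] * (len(codes) + 1)
    h = 0
    for i, c in enumerate(codes):
        h = (h * base + c) % _MOD
        pre[i + 1] = h
    return pre


class _Roller:
    """O(1) substring hashing after O(n) preprocessing."""

    def __init__(self, seq: str, k: int):
        codes = [ord(c) for c in seq]
        rc = [ord(_COMP.get(c, "N")) for c in reversed(seq)]
        self.n = len(seq)
        self.k = k
        self.p1 = _prefix_hashes(codes, _B1)
        self.p2 = _prefix_hashes(codes, _B2)
        self.r1 = _prefix_hashes(rc, _B1)
        self.r2 = _prefix_hashes(rc, _B2)
        self.pow1 = pow(_B1, k, _MOD)
        self.pow2 = pow(_B2, k, _MOD)

    def _sub(self, pre, power, i):
        return (pre[i + self.k] - pre[i] * power) % _MOD

    def fwd(self, i: int) -> Tuple[int, int]:
        return (self._sub(self.p1, self.pow1, i), self._sub(self.p2, self.pow2, i))

    def rc(self, i: int) -> Tuple[int, int]:
        j = self.n - i - self.k
        return (self._sub(self.r1, self.pow1, j), self._sub(self.r2, self.pow2, j))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def count_unitigs(
    genome: GenomeSet, k: int, canonical: bool = True
) -> UnitigGraph:
    """Build the compacted de Bruijn graph of the genome at word size k.

    ``canonical=False`` treats the genome as single-stranded (no reverse
    complement identification), for sensitivity analysis.
    """
    if k < 2:
        raise ValueError("k must be >= 2")

    node_id: Dict[tuple, int] = {}
    occurrences: List[List[Tuple[int, str]]] = []  # walks of (node, orient)

    for rep in genome:
        if rep.length < k:
            warnings.warn(f"replicon {rep.name!r} shorter than k={k}; skipped")
            continue
        seq = rep.sequence + (rep.sequence[: k - 1] if rep.circular else "")
        n_pos = rep.length if rep.circular else rep.length - k + 1
        roller = _Roller(seq, k)
        # positions whose k-mer contains a non-ACGT base are invalid
        bad_prefix = [0] * (len(seq) + 1)
        for i, ch in enumerate(seq):
            bad_prefix[i + 1] = bad_prefix[i] + (ch not in "ACGT")
        walk: List[Optional[Tuple[int, str]]] = []
        for i in range(n_pos):
            if bad_prefix[i + k] - bad_prefix[i] > 0:
                walk.append(None)
                continue
            f = roller.fwd(i)
            if canonical:
                r = roller.rc(i)
                if f <= r:
                    key, orient = (f, r), "+"
                else:
                    key, orient = (r, f), "-"
            else:
                key, orient = (f,), "+"
            uid = node_id.setdefault(key, len(node_id))
            walk.append((uid, orient))
        # split the walk at invalid k-mers; close the circle when valid
        segments: List[List[Tuple[int, str]]] = []
        cur: List[Tuple[int, str]] = []
        for step in walk:
            if step is None:
                if cur:
                    segments.append(cur)
                    cur = []
            else:
                cur.append(step)
        if cur:
            segments.append(cur)
        if rep.circular and len(segments) > 1 and walk[0] is not None and walk[-1] is not None:
            # the walk wraps: join last segment to first
            segments[0] = segments.pop() + segments[0]
        elif rep.circular and len(segments) == 1 and all(s is not None for s in walk):
            segments[0] = segments[0] + [segments[0][0]]  # closing edge
        occurrences.extend(segments)

    n_nodes = len(node_id)
    if n_nodes == 0:
        return UnitigGraph(k=k)

    # collect bidirected edges: (node, side) pairs; '+' exits right ('t'),
    # '-' exits left ('h')
    def exit_side(orient: str) -> str:
        return "t" if orient == "+" else "h"

    def entry_side(orient: str) -> str:
        return "h" if orient == "+" else "t"

    adjacency: Dict[Tuple[int, str], set] = {}
    edges: set = set()
    for seg in occurrences:
        for (u, ou), (v, ov) in zip(seg, seg[1:]):
            a = (u, exit_side(ou))
            b = (v, entry_side(ov))
            edge = tuple(sorted((a, b)))
            if edge not in edges:
                edges.add(edge)
                adjacency.setdefault(a, set()).add(b)
                adjacency.setdefault(b, set()).add(a)

    uf = _UnionFind(n_nodes)
    cycle_components: set = set()
    remaining: List[Tuple[Tuple[int, str], Tuple[int, str]]] = []
    for a, b in sorted(edges):
        contractible = (
            len(adjacency[a]) == 1 and len(adjacency[b]) == 1 and a != b
        )
        if contractible:
            if not uf.union(a[0], b[0]):
                cycle_components.add(uf.find(a[0]))
        else:
            remaining.append((a, b))

    comp_sizes: Dict[int, int] = {}
    for node in range(n_nodes):
        root = uf.find(node)
        comp_sizes[root] = comp_sizes.get(root, 0) + 1

    comp_ids = {root: i for i, root in enumerate(sorted(comp_sizes))}
    self_adj = {comp_ids[uf.find(r)] for r in cycle_components}
    adjacencies: List[Tuple[int, str, int, str]] = []
    for a, b in remaining:
        ca, cb = comp_ids[uf.find(a[0])], comp_ids[uf.find(b[0])]
        adjacencies.append((ca, a[1], cb, b[1]))
        if ca == cb:
            self_adj.add(ca)

    unitigs = [
        Unitig(uid=comp_ids[root], n_kmers=size, k=k, self_adjacent=comp_ids[root] in self_adj)
        for root, size in sorted(comp_sizes.items())
    ]
    unitigs.sort(key=lambda u: u.uid)
    return UnitigGraph(k=k, unitigs=unitigs, adjacencies=adjacencies, n_kmers=n_nodes)


def write_gfa(graph: UnitigGraph, path) -> None:
    """Minimal GFA v1 export: segments with lengths, links with end labels.

    Sequences are not stored (nodes are hashes), so segments carry only
    ``LN`` tags; link orientation encodes which end of each unitig the
    adjacency touches ('t' right end = '+', 'h' left end = '-').
    """
    with open(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for u in graph.unitigs:
            fh.write(f"S\tu{u.uid}\t*\tLN:i:{u.length}\n")
        for ca, sa, cb, sb in graph.adjacencies:
            oa = "+" if sa == "t" else "-"
            ob = "+" if sb == "h" else "-"
            fh.write(f"L\tu{ca}\t{oa}\tu{cb}\t{ob}\t{graph.k - 1}M\n")
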
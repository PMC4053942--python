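"""Repeat-spanning closure simulation.

Error-free reads are sampled uniformly from each replicon at a target
coverage, with lengths drawn (with replacement) from a read-length model.
A merged repeat interval is *resolved* when at least one read covers the
whole interval plus a minimum unique anchor (default 40 bp) on both
flanks; this mirrors the minimum overlap an overlap-based assembler needs
to walk through a repeat.  Every unresolved merged interval produces one
assembly gap, and a circular replicon with zero gaps closes into a single
contig.

Because the simulated reads are error-free and their coordinates are
known, spanning is tested coordinate-wise directly; mapping the reads back
with an aligner would give the identical answer.  The flanks adjacent to a
merged interval are unique with respect to all repeats above the length
filter by construction of the merge.

``spanning_probability`` gives the closed-form unresolved probability for
the single-repeat, constant-read-length case and serves as the independent
oracle for the simulator.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeSet, Replicon
from .length_models import ReadLengthModel, model_mean, sample_lengths
from .repeat_finder import RepeatInterval, RepeatProfile

_CHUNK = 1024  # reads are drawn in fixed-size chunks so that a longer
# simulation extends a shorter one with the same seed (common random numbers)


@dataclass
class SimulationConfig:
    """Knobs of the closure simulation.

    ``anchor`` is the minimum unique flank a spanning read must carry on
    each side of a repeat (40 bp: the assembler's minimum overlap).
    """

    coverage: float = 200.0
    anchor: int = 40
    replicates: int = 10
    seed: int = 0
    circular_default: bool = True

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.anchor < 0:
            raise ValueError("anchor must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SimulatedReadSet:
    """Coordinate-only reads on one replicon."""

    replicon: str
    replicon_length: int
    circular: bool
    starts: np.ndarray  # 0-based start positions
    lengths: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def wraps(self) -> np.ndarray:
        return (self.starts + self.lengths) > self.replicon_length

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())


@dataclass
class ReplicateOutcome:
    gaps_per_replicon: Dict[str, int]
    contigs_per_replicon: Dict[str, int]

    @property
    def total_gaps(self) -> int:
        return sum(self.gaps_per_replicon.values())

    @property
    def contigs(self) -> int:
        return sum(self.contigs_per_replicon.values())

    @property
    def closed(self) -> bool:
        return self.total_gaps == 0


@dataclass
class ClosureResult:
    """Gap/contig statistics across simulation replicates."""

    per_replicate: List[ReplicateOutcome] = field(default_factory=list)

    @property
    def mean_gaps(self) -> float:
        return float(np.mean([r.total_gaps for r in self.per_replicate]))

    @property
    def sd_gaps(self) -> float:
        gaps = [r.total_gaps for r in self.per_replicate]
        return float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0

    @property
    def mean_contigs(self) -> float:
        return float(np.mean([r.contigs for r in self.per_replicate]))

    @property
    def closed_fraction(self) -> float:
        return float(np.mean([r.closed for r in self.per_replicate]))


def derive_seed(master: int, *tokens) -> int:
    """Stable sub-seed from a master seed and arbitrary labels (< 2^31)."""
    text = "|".join(str(t) for t in tokens)
    return (int(master) ^ zlib.crc32(text.encode())) & 0x7FFFFFFF


def simulate_reads(
    replicon: Replicon,
    model: ReadLengthModel,
    coverage: float,
    seed: int,
    circular: Optional[bool] = None,
) -> SimulatedReadSet:
    """Sample error-free reads until cumulative length first reaches C x G.

    Starts are uniform on [0, G); reads on circular replicons wrap past the
    origin, reads on linear replicons are truncated at the end.  Read
    lengths longer than the replicon are capped at the replicon length
    (such a read covers the whole circle).  Reproducible under ``seed``,
    and a higher coverage with the same seed yields a superset of the reads
    of a lower coverage (the draw stream is chunked, not resized).
    """
    G = replicon.length
    if G <= 0:
        raise ValueError("replicon length must be > 0")
    circ = replicon.circular if circular is None else circular
    if not circ and model_mean(model) >= G:
        import warnings

        warnings.warn(
            f"mean read length >= linear replicon {replicon.name!r} length; "
            "coverage after end-truncation will fall short of the target"
        )
    target = coverage * G
    starts_parts: List[np.ndarray] = []
    len_parts: List[np.ndarray] = []
    total = 0
    rng = np.random.default_rng(seed)
    while total < target:
        lens = np.minimum(sample_lengths(model, _CHUNK, rng=rng), G)
        starts = rng.integers(0, G, size=_CHUNK)
        if not circ:
            lens = np.minimum(lens, G - starts)
        cum = total + np.cumsum(lens)
        if cum[-1] >= target:
            stop = int(np.searchsorted(cum, target)) + 1
            starts_parts.append(starts[:stop])
            len_parts.append(lens[:stop])
            total = int(cum[stop - 1])
            break
        starts_parts.append(starts)
        len_parts.append(lens)
        total = int(cum[-1])
    return SimulatedReadSet(
        replicon=replicon.name,
        replicon_length=G,
        circular=circ,
        starts=np.concatenate(starts_parts),
        lengths=np.concatenate(len_parts),
    )


def count_unspanned(
    merged: Sequence[RepeatInterval], reads: SimulatedReadSet, anchor: int = 40
) -> int:
    """Number of merged repeat intervals on this replicon with no spanning read.

    An interval [s, e) is spanned when a read covers [s - anchor, e + anchor)
    contiguously, with wrap-around on circular replicons.
    """
    G = reads.replicon_length
    starts = reads.starts
    lengths = reads.lengths
    unspanned = 0
    for iv in merged:
        if iv.replicon != reads.replicon:
            continue
        need_len = (iv.end - iv.start) + 2 * anchor
        if reads.circular:
            if need_len >= G:
                # repeat plus flanks wraps the whole circle: only a read
                # covering everything can span it
                if not np.any(lengths >= G):
                    unspanned += 1
                continue
            need_start = (iv.start - anchor) % G
            offset = (need_start - starts) % G
            spanned = np.any(offset + need_len <= lengths)
        else:
            lo = iv.start - anchor
            hi = iv.end + anchor
            if lo < 0 or hi > G:
                spanned = False  # flank falls off a linear end
            else:
                spanned = np.any((starts <= lo) & (starts + lengths >= hi))
        if not spanned:
            unspanned += 1
    return unspanned


def spanning_probability(
    G: int, R: int, L: int, N: int, anchor: int = 40
) -> float:
    """Closed-form probability that a single repeat remains *unresolved*.

    Circular replicon of size G, one merged repeat interval of length R,
    N reads of constant length L.  A read resolves the repeat iff its start
    falls in one of max(0, L - R - 2*anchor + 1) positions.
    """
    if R + 2 * anchor > G:
        raise ValueError("repeat plus flanks exceeds the genome")
    favourable = max(0, L - R - 2 * anchor + 1)
    p_span = min(1.0, favourable / G)
    return (1.0 - p_span) ** N


def predict_closure(
    genome: GenomeSet,
    profile: RepeatProfile,
    model: ReadLengthModel,
    cfg: SimulationConfig,
) -> ClosureResult:
    """Simulate reads and count unresolved repeats, replicate by replicate.

    Coverage targets each replicon independently (each gets C x its own
    length), so plasmid closure is well defined.  A circular replicon with
    zero gaps yields one contig; with g > 0 gaps it breaks into g contigs.
    A linear replicon yields g + 1 contigs.
    """
    result = ClosureResult()
    for rep_idx in range(cfg.replicates):
        gaps: Dict[str, int] = {}
        contigs: Dict[str, int] = {}
        for rep in genome:
            circ = rep.circular and cfg.circular_default
            seed = derive_seed(cfg.seed, model.name, rep.name, rep_idx)
            reads = simulate_reads(rep, model, cfg.coverage, seed, circular=circ)
            g = count_unspanned(profile.merged_intervals, reads, cfg.anchor)
            gaps[rep.name] = g
            contigs[rep.name] = max(g, 1) if circ else g + 1
        result.per_replicate.append(ReplicateOutcome(gaps, contigs))
    return result


def coverage_sweep(
    genome: GenomeSet,
    profile: RepeatProfile,
    models: Sequence[ReadLengthModel],
    coverages: Sequence[float],
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Closure statistics for every (model, coverage) combination.

    Common random numbers across coverages: per (model, replicon,
    replicate) the read stream is simulated once at the maximum coverage
    and lower coverages take prefixes of it, so closure is non-decreasing
    in coverage by construction.
    """
    if not models or not len(coverages):
        raise ValueError("need at least one model and one coverage")
    coverages = sorted(coverages)
    rows = []
    for model in models:
        per_cov: Dict[float, List[ReplicateOutcome]] = {c: [] for c in coverages}
        for rep_idx in range(cfg.replicates):
            full: Dict[str, SimulatedReadSet] = {}
            for rep in genome:
                seed = derive_seed(cfg.seed, model.name, rep.name, rep_idx)
                circ = rep.circular and cfg.circular_default
                full[rep.name] = simulate_reads(
                    rep, model, max(coverages), seed, circular=circ
                )
            for cov in coverages:
                gaps: Dict[str, int] = {}
                contigs: Dict[str, int] = {}
                for rep in genome:
                    reads = _prefix_reads(full[rep.name], cov)
                    g = count_unspanned(profile.merged_intervals, reads, cfg.anchor)
                    gaps[rep.name] = g
                    circ = rep.circular and cfg.circular_default
                    contigs[rep.name] = max(g, 1) if circ else g + 1
                per_cov[cov].append(ReplicateOutcome(gaps, contigs))
        for cov in coverages:
            res = ClosureResult(per_replicate=per_cov[cov])
            rows.append(
                {
                    "model": model.name,
                    "coverage": cov,
                    "mean_gaps": res.mean_gaps,
                    "sd_gaps": res.sd_gaps,
                    "mean_contigs": res.mean_contigs,
                    "closed_fraction": res.closed_fraction,
                }
            )
    return pd.DataFrame(rows)


def _prefix_reads(reads: SimulatedReadSet, coverage: float) -> SimulatedReadSet:
    """Shortest read prefix whose cumulative length reaches C x G."""
    target = coverage * reads.replicon_length
    cum = np.cumsum(reads.lengths)
    stop = int(np.searchsorted(cum, target)) + 1
    stop = min(stop, len(reads.lengths))
    return SimulatedReadSet(
        replicon=reads.replicon,
        replicon_length=reads.replicon_length,
        circular=reads.circular,
        starts=reads.starts[:stop],
        lengths=reads.lengths[:stop],
    )
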
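"""Synthetic genomes, reads, and chimeras with machine-readable truth.

Every generator is deterministic under its seed, and each emits a `Truth`
record carrying the planted coordinates so downstream detectors can be
scored without any external data.

The genome generator plants repeats into an i.i.d. uniform-composition
background (GC 50%).  Diverged repeat copies are produced by point
substitutions only -- exactly round((1 - identity) * length) of them, at
seeded positions -- which keeps the identity arithmetic exact and the
interval coordinates stable.  Chance exact repeats >= 500 bp in a uniform
background are astronomically unlikely below tens of megabases, so an
unplanted genome is a clean negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import GenomeSet, Replicon, ShortAlignment, reverse_complement
from .length_models import ReadLengthModel, sample_lengths
from .read_processing import QualityRead

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedRepeat:
    """One repeat family to plant: length, copy number, identity, strands.

    ``orientations`` lists one of 'F'/'R' per copy (default all forward).
    ``placements`` optionally pins each copy to (replicon_index, start);
    otherwise copies are spread evenly along the first replicon.
    """

    length: int
    copies: int = 2
    identity: float = 1.0
    orientations: Optional[List[str]] = None
    placements: Optional[List[Tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.length < 1 or self.copies < 2:
            raise ValueError("need length >= 1 and copies >= 2")
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if self.orientations is None:
            self.orientations = ["F"] * self.copies
        if len(self.orientations) != self.copies:
            raise ValueError("need one orientation per copy")


@dataclass
class GenomeSpec:
    """Recipe for a synthetic genome."""

    replicons: List[Tuple[int, bool]] = field(default_factory=lambda: [(100_000, True)])
    planted_repeats: List[PlantedRepeat] = field(default_factory=list)
    seed: int = 0


@dataclass
class Truth:
    """Planted coordinates emitted alongside every synthetic artifact."""

    repeat_copies: List[Dict] = field(default_factory=list)
    read_origins: List[Dict] = field(default_factory=list)
    junctions: List[int] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, identity: float
) -> Tuple[str, int]:
    """Apply exactly round((1 - identity) * len) substitutions."""
    n_sub = int(round((1.0 - identity) * len(seq)))
    if n_sub == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out), n_sub


def make_genome(spec: GenomeSpec) -> Tuple[GenomeSet, Truth]:
    """Generate a genome with the requested planted repeat structure."""
    rng = np.random.default_rng(spec.seed)
    seqs = [list(_random_sequence(rng, length)) for length, _ in spec.replicons]
    truth = Truth()
    occupied: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(len(seqs))}

    for fam_idx, fam in enumerate(spec.planted_repeats):
        prototype = _random_sequence(rng, fam.length)
        placements = fam.placements
        if placements is None:
            L = spec.replicons[0][0]
            gap = L // fam.copies
            if gap < fam.length + 100:
                raise ValueError(
                    f"repeat family {fam_idx}: {fam.copies} copies of "
                    f"{fam.length} bp do not fit in replicon 0"
                )
            placements = [(0, i * gap + 50) for i in range(fam.copies)]
        for copy_idx, ((ri, start), orient) in enumerate(
            zip(placements, fam.orientations)
        ):
            end = start + fam.length
            if end > spec.replicons[ri][0]:
                raise ValueError(
                    f"repeat family {fam_idx} copy {copy_idx} overruns replicon {ri}"
                )
            for s, e in occupied[ri]:
                if start < e and s < end:
                    raise ValueError(
                        f"repeat family {fam_idx} copy {copy_idx} overlaps a "
                        "previously planted copy"
                    )
            copy_seq = prototype
            n_sub = 0
            if copy_idx > 0:  # first copy stays the prototype
                copy_seq, n_sub = _mutate_to_identity(rng, prototype, fam.identity)
            if orient == "R":
                copy_seq = reverse_complement(copy_seq)
            seqs[ri][start:end] = list(copy_seq)
            occupied[ri].append((start, end))
            truth.repeat_copies.append(
                {
                    "family": fam_idx,
                    "copy": copy_idx,
                    "replicon": ri,
                    "start": start,
                    "end": end,
                    "orientation": orient,
                    "substitutions": n_sub,
                }
            )

    replicons = [
        Replicon(f"replicon{i}", "".join(seq), circular=circ)
        for i, (seq, (_, circ)) in enumerate(zip(seqs, spec.replicons))
    ]
    return GenomeSet(replicons), truth


def make_reads(
    genome: GenomeSet,
    model: ReadLengthModel,
    error_rate: float = 0.0,
    qv_mean: float = 60.0,
    qv_sd: float = 0.0,
    coverage: float = 10.0,
    seed: int = 0,
) -> Tuple[List[QualityRead], Truth]:
    """Sample reads with substitution errors and Gaussian QV noise.

    Coverage targets each replicon independently; circular replicons wrap.
    Truth records (replicon, start, length) per read.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reads: List[QualityRead] = []
    truth = Truth()
    for rep in genome:
        target = coverage * rep.length
        total = 0
        while total < target:
            length = int(min(sample_lengths(model, 1, rng=rng)[0], rep.length))
            start = int(rng.integers(0, rep.length))
            if rep.circular:
                seq = (rep.sequence * 2)[start : start + length]
            else:
                length = min(length, rep.length - start)
                seq = rep.sequence[start : start + length]
            if error_rate > 0:
                arr = list(seq)
                errs = np.flatnonzero(rng.random(length) < error_rate)
                for p in errs:
                    choices = [b for b in "ACGT" if b != arr[p]]
                    arr[p] = choices[rng.integers(0, 3)]
                seq = "".join(arr)
            qvs = np.maximum(
                0.0, rng.normal(qv_mean, qv_sd, size=length)
            ).tolist() if qv_sd > 0 else [qv_mean] * length
            name = f"read{len(reads)}"
            reads.append(QualityRead(name, seq, qvs))
            truth.read_origins.append(
                {"name": name, "replicon": rep.name, "start": start, "length": length}
            )
            total += length
    return reads, truth


def make_chimera(
    genome: GenomeSet,
    segment_length: int,
    n_junctions: int = 1,
    seed: int = 0,
    qv: float = 60.0,
) -> Tuple[QualityRead, Truth]:
    """Build a chimeric read: alternating forward / reverse-complement copies
    of one sampled locus, emulating a missed SMRTbell adapter.

    ``n_junctions`` junctions join ``n_junctions + 1`` segments; the truth
    records the junction positions.
    """
    if n_junctions < 1:
        raise ValueError("n_junctions must be >= 1")
    rng = np.random.default_rng(seed)
    rep = genome.replicons[int(rng.integers(0, len(genome)))]
    if segment_length > rep.length:
        raise ValueError("segment longer than replicon")
    start = int(rng.integers(0, rep.length - segment_length + 1))
    locus = rep.sequence[start : start + segment_length]
    segments = [
        locus if i % 2 == 0 else reverse_complement(locus)
        for i in range(n_junctions + 1)
    ]
    seq = "".join(segments)
    truth = Truth(junctions=[segment_length * (i + 1) for i in range(n_junctions)])
    read = QualityRead("chimera", seq, [qv] * len(seq))
    return read, truth


def tile_chimera_alignments(
    chimera: QualityRead,
    truth: Truth,
    read_length: int = 100,
    step: int = 25,
    min_alignment: int = 20,
) -> List[ShortAlignment]:
    """Emulate a local aligner mapping tiling short reads onto a chimera.

    The chimera alternates forward and reverse-complement segments of one
    locus; a genomic short read therefore maps forward inside forward
    segments and reverse inside reverse-complement ones, and an alignment
    is truncated at a junction exactly as a local aligner would truncate
    it.  Tiling windows crossing a junction yield one truncated alignment
    per side (when at least ``min_alignment`` bases remain).
    """
    bounds = [0, *truth.junctions, len(chimera)]
    alignments: List[ShortAlignment] = []
    idx = 0
    for w_start in range(0, len(chimera) - read_length + 1, step):
        w_end = w_start + read_length
        for seg_idx, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            a, b = max(w_start, lo), min(w_end, hi)
            if b - a < min_alignment:
                continue
            strand = "+" if seg_idx % 2 == 0 else "-"
            alignments.append(
                ShortAlignment(
                    query_name=f"sr{idx}",
                    target_name=chimera.name,
                    strand=strand,
                    target_start=a,
                    target_end=b,
                    query_start=0,
                    query_end=b - a,
                )
            )
            idx += 1
    return alignments
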
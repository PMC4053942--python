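"""Survey orchestration, sequencing cost arithmetic, and summaries.

Currency is held in integer cents internally so the worked cost examples
reproduce penny-exact; coverage arithmetic uses exact rationals so cell
counts never suffer float-ceiling artifacts at boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Integral
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .closure_sim import SimulationConfig, coverage_sweep
from .genome_io import GenomeSet, read_fasta
from .length_models import ReadLengthModel
from .repeat_finder import ClassThresholds, RepeatFilter, profile_genome

DEFAULT_YIELD_PER_CELL = 300_000_000  # bases per SMRT cell (RS II)


def _to_fraction(x) -> Fraction:
    if isinstance(x, Integral):
        return Fraction(int(x))
    return Fraction(str(x))


def cells_required(
    coverage, genome_size: int, yield_per_cell: int = DEFAULT_YIELD_PER_CELL
) -> int:
    """Number of SMRT cells needed for the requested coverage (ceiling)."""
    if yield_per_cell <= 0:
        raise ValueError("yield_per_cell must be > 0")
    cov = _to_fraction(coverage)
    if cov < 0:
        raise ValueError("coverage must be >= 0")
    if cov == 0:
        return 0
    total = cov * genome_size
    return int(math.ceil(total / yield_per_cell))


def project_cost(library_prep: float, n_cells: int, cell_cost: float) -> float:
    """Total sequencing cost: library prep + cells, rounded to cents."""
    if library_prep < 0 or n_cells < 0 or cell_cost < 0:
        raise ValueError("cost inputs must be non-negative")
    lib_cents = round(library_prep * 100)
    cell_cents = round(cell_cost * 100)
    return (lib_cents + n_cells * cell_cents) / 100.0


def closed_fraction(
    n_closed: int,
    category_counts: Sequence[int],
    overlap_corrections: Sequence[int] = (),
) -> float:
    """Percentage of closed genomes over the de-duplicated category total."""
    denom = sum(category_counts) - sum(overlap_corrections)
    if denom <= 0:
        raise ValueError("denominator must be > 0")
    return round(100.0 * n_closed / denom, 2)


@dataclass
class SurveyRow:
    name: str
    ok: bool
    repeat_count: int = 0
    max_repeat: int = 0
    genome_class: str = ""
    sweep: Optional[pd.DataFrame] = None
    error: str = ""


@dataclass
class SurveySummary:
    """Per-genome rows plus aggregate class fractions."""

    rows: List[SurveyRow] = field(default_factory=list)

    @property
    def class_fractions(self) -> Dict[str, float]:
        ok = [r for r in self.rows if r.ok]
        if not ok:
            return {}
        return {
            cls: sum(r.genome_class == cls for r in ok) / len(ok)
            for cls in ("I", "II", "III")
        }

    def table(self) -> pd.DataFrame:
        frames = []
        for r in self.rows:
            if not r.ok:
                frames.append(
                    pd.DataFrame(
                        [{"genome": r.name, "error": r.error}]
                    )
                )
                continue
            df = r.sweep.copy()
            df.insert(0, "genome", r.name)
            df.insert(1, "class", r.genome_class)
            df.insert(2, "repeat_count", r.repeat_count)
            df.insert(3, "max_repeat", r.max_repeat)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def survey_genome(
    genome: GenomeSet,
    models: Sequence[ReadLengthModel],
    coverages: Sequence[float],
    cfg: SimulationConfig,
    filt: RepeatFilter = RepeatFilter(),
    thresholds: ClassThresholds = ClassThresholds(),
    name: str = "genome",
) -> SurveyRow:
    profile = profile_genome(genome, filt=filt, thresholds=thresholds)
    sweep = coverage_sweep(genome, profile, models, coverages, cfg)
    return SurveyRow(
        name=name,
        ok=True,
        repeat_count=profile.repeat_count,
        max_repeat=profile.max_repeat,
        genome_class=profile.genome_class,
        sweep=sweep,
    )


def run_survey(
    genome_paths: Sequence[str],
    models: Sequence[ReadLengthModel],
    coverages: Sequence[float],
    cfg: SimulationConfig,
    filt: RepeatFilter = RepeatFilter(),
    thresholds: ClassThresholds = ClassThresholds(),
) -> SurveySummary:
    """Profile and closure-sweep every genome; failures become failed rows.

    Deterministic under the master seed in ``cfg``: per-genome seeds are
    derived from it and the genome name.
    """
    from .closure_sim import derive_seed

    summary = SurveySummary()
    for path in genome_paths:
        name = str(path)
        try:
            genome = read_fasta(path, circular_default=cfg.circular_default)
            sub_cfg = SimulationConfig(
                coverage=cfg.coverage,
                anchor=cfg.anchor,
                replicates=cfg.replicates,
                seed=derive_seed(cfg.seed, "survey", name),
                circular_default=cfg.circular_default,
            )
            row = survey_genome(
                genome, models, coverages, sub_cfg, filt, thresholds, name=name
            )
        except Exception as exc:  # unreadable genome: record and continue
            row = SurveyRow(name=name, ok=False, error=str(exc))
        summary.rows.append(row)
    return summary
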
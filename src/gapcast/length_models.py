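"""Read-length distribution models for single-molecule sequencing.

Corrected single-molecule read lengths are well described by a log-normal
distribution; each sequencing chemistry generation is summarised by the
mean and standard deviation of log length.  The presets below are the
fitted (mu, sigma) pairs for the four PacBio RS chemistry generations,
plus a projected 'ZL' chemistry with double the XL-XL mean length
(implemented as mu + ln 2, sigma unchanged).

Sampling truncates the distribution at ``max_len`` by redrawing (clamping
would pile an atom of probability at the bound).  The truncation bound is
mean + 5 standard deviations *in linear space* by default: for XL-XL this
gives roughly 23.5 kbp, consistent with observed maxima near 25 kbp,
whereas truncating in log space would allow implausible ~158 kbp reads.
Both rules are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ReadLengthModel:
    """Log-normal or empirical read-length distribution.

    For the log-normal kind, ``mu``/``sigma`` are the mean and standard
    deviation of natural-log length in bases.  The empirical kind resamples
    a stored length list uniformly with replacement.
    """

    kind: str = "lognormal"  # "lognormal" | "empirical"
    mu: float = 0.0
    sigma: float = 0.0
    max_len: Optional[int] = None
    lengths: Optional[List[int]] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "empirical"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "lognormal":
            if self.sigma < 0:
                raise ValueError("sigma must be >= 0")
        else:
            if not self.lengths:
                raise ValueError("empirical model needs a non-empty length list")
            if any(l <= 0 for l in self.lengths):
                raise ValueError("empirical lengths must be positive")
        if self.max_len is not None and self.max_len <= 0:
            raise ValueError("max_len must be positive")


def model_mean(model: ReadLengthModel) -> float:
    """Analytic (untruncated) mean read length of the model in bases."""
    if model.kind == "empirical":
        return float(np.mean(model.lengths))
    return math.exp(model.mu + model.sigma**2 / 2.0)


def model_sd(model: ReadLengthModel) -> float:
    """Analytic (untruncated) standard deviation of read length in bases."""
    if model.kind == "empirical":
        return float(np.std(model.lengths, ddof=1)) if len(model.lengths) > 1 else 0.0
    m = model_mean(model)
    return m * math.sqrt(math.expm1(model.sigma**2))


def truncation_bound(mu: float, sigma: float, space: str = "linear") -> int:
    """Default truncation bound mean + 5 sd, in linear or log space."""
    if space == "linear":
        m = math.exp(mu + sigma**2 / 2.0)
        s = m * math.sqrt(math.expm1(sigma**2))
        return max(1, int(round(m + 5.0 * s)))
    if space == "log":
        return max(1, int(round(math.exp(mu + 5.0 * sigma))))
    raise ValueError(f"unknown truncation space {space!r}")


def lognormal_model(
    mu: float, sigma: float, name: str = "", truncation: str = "linear"
) -> ReadLengthModel:
    return ReadLengthModel(
        kind="lognormal",
        mu=mu,
        sigma=sigma,
        max_len=truncation_bound(mu, sigma, truncation),
        name=name,
    )


_PRESET_PARAMS = {
    "C1": (6.69, 0.37),
    "C2": (7.59, 0.67),
    "XL-C2": (7.90, 0.63),
    "XL-XL": (8.02, 0.79),
    "ZL": (8.02 + math.log(2.0), 0.79),
}


def chemistry_preset(name: str, truncation: str = "linear") -> ReadLengthModel:
    """Named chemistry preset (C1, C2, XL-C2, XL-XL, or the projected ZL)."""
    key = name.upper().replace("_", "-")
    if key not in _PRESET_PARAMS:
        raise KeyError(
            f"unknown chemistry {name!r}; choose from {sorted(_PRESET_PARAMS)}"
        )
    mu, sigma = _PRESET_PARAMS[key]
    return lognormal_model(mu, sigma, name=key, truncation=truncation)


def preset_names() -> List[str]:
    return list(_PRESET_PARAMS)


def fit_lognormal(lengths: Sequence[int], truncation: str = "linear") -> ReadLengthModel:
    """Fit a log-normal model: mu/sigma are mean and sample sd of log length."""
    if len(lengths) < 2:
        raise ValueError("need at least 2 lengths to fit")
    arr = np.asarray(lengths, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all lengths must be positive")
    logs = np.log(arr)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1))
    return lognormal_model(mu, sigma, name="fitted", truncation=truncation)


def empirical_model(lengths: Sequence[int], name: str = "empirical") -> ReadLengthModel:
    return ReadLengthModel(
        kind="empirical",
        lengths=list(lengths),
        max_len=max(lengths),
        name=name,
    )


def fraction_above(model: ReadLengthModel, threshold: float) -> float:
    """Model probability that a read is longer than ``threshold`` bases."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if model.kind == "empirical":
        arr = np.asarray(model.lengths, dtype=float)
        return float(np.mean(arr > threshold))
    if model.sigma == 0.0:
        return 1.0 if math.log(threshold) < model.mu else 0.0
    z = (math.log(threshold) - model.mu) / model.sigma
    return float(stats.norm.sf(z))


def sample_lengths(
    model: ReadLengthModel, n: int, seed: Optional[int] = None, rng=None
) -> np.ndarray:
    """Draw ``n`` read lengths; truncation at ``max_len`` is by redraw.

    Lengths are rounded to the nearest base with a floor of 1.  Identical
    (model, n, seed) yields identical output.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if model.kind == "empirical":
        arr = np.asarray(model.lengths, dtype=np.int64)
        return arr[rng.integers(0, len(arr), size=n)]
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.lognormal(model.mu, model.sigma, size=n - filled)
        vals = np.maximum(1, np.rint(draw)).astype(np.int64)
        if model.max_len is not None:
            vals = vals[vals <= model.max_len]
        take = len(vals)
        out[filled : filled + take] = vals
        filled += take
    return out


@dataclass
class SeedQuery:
    """Inputs for the expected-seed-count model.

    ``read_len`` (L) and ``seed_len`` (k) in bases, ``error_rate`` (e) as a
    fraction.  ``read_to_read`` doubles the per-base survival exponent since
    both copies of a shared k-mer must be error-free.
    """

    read_len: int
    error_rate: float
    seed_len: int = 10
    mode: str = "read_to_read"

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (1 <= self.seed_len <= self.read_len):
            raise ValueError("need 1 <= seed_len <= read_len")
        if self.mode not in ("read_to_reference", "read_to_read"):
            raise ValueError(f"unknown mode {self.mode!r}")


def expected_seed_count(q: SeedQuery) -> float:
    """Expected number of error-free k-mer seeds shared with the target.

    This is a simple independent-errors model: each of the L - k + 1 seed
    positions survives with probability (1-e)^k against an error-free
    reference, or (1-e)^(2k) between two error-prone reads.  It captures
    the length-versus-error trade-off qualitatively; it is not an exact
    reproduction of any published seed-count curve.
    """
    windows = q.read_len - q.seed_len + 1
    exponent = q.seed_len if q.mode == "read_to_reference" else 2 * q.seed_len
    return windows * (1.0 - q.error_rate) ** exponent
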
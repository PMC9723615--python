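"""Percentile-rank and Phred calibration of raw classifier scores.

Raw scores are only meaningful relative to the genome-wide reference
population, so they are mapped to percentile ranks (uniform on [0, 1) by
construction) and then Phred-transformed, f(x) = -10 * log10(1 - x), so a
rank of 0.95 — higher than 95% of the genome — becomes 13.01 and a rank of
0.99 becomes 20.  The transform is monotone, so any classification threshold
can be expressed equivalently on the raw, rank or Phred scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass
class CalibrationReference:
    """Sorted raw scores of the reference population."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float).ravel()
        if scores.size < 2:
            raise ConfigError("calibration reference needs at least 2 scores")
        self.scores = np.sort(scores)

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def phred_cap(self) -> float:
        """Phred value of the top-capped rank 1 - 1/(2N)."""
        return phred(1.0 - 1.0 / (2 * self.n))


def percentile_rank(score, reference: CalibrationReference) -> np.ndarray | float:
    """Mid-rank percentile of ``score`` within the reference population.

    rank = (#strictly below + 0.5 * #equal) / N — the mid-rank convention
    keeps in-reference ranks uniform even with ties.  Monotone non-decreasing
    in the score; always in [0, 1).
    """
    s = np.atleast_1d(np.asarray(score, dtype=float))
    below = np.searchsorted(reference.scores, s, side="left")
    upto = np.searchsorted(reference.scores, s, side="right")
    rank = (below + 0.5 * (upto - below)) / reference.n
    rank = np.minimum(rank, 1.0 - 1.0 / (2 * reference.n))
    return rank if np.ndim(score) else float(rank[0])


def phred(x, n_reference: int | None = None):
    """Phred transform -10*log10(1 - x) of a percentile rank.

    ``x`` must be >= 0.  Ranks at or above the cap 1 - 1/(2N) (when
    ``n_reference`` is given; otherwise 1 - 1e-12) are clipped so the
    top-ranked score maps to a finite value.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0):
        raise ConfigError("percentile ranks must be >= 0")
    cap = 1.0 - (1.0 / (2 * n_reference) if n_reference else 1e-12)
    x_arr = np.minimum(x_arr, cap)
    out = -10.0 * np.log10(1.0 - x_arr)
    return out if np.ndim(x) else float(out[0])


def phred_scores(raw_scores, reference: CalibrationReference) -> np.ndarray:
    """Raw scores -> Phred-scaled genome-wide rank scores in one step."""
    return phred(percentile_rank(np.asarray(raw_scores, float), reference), reference.n)


def fraction_for_count(n_tested: int, pool_size: int) -> float:
    """Fraction of the candidate pool an experiment of size ``n_tested`` covers.

    Reported rounded to 3 decimals (the convention used when quoting, e.g.,
    100,000 of 9.2 million as 0.011).
    """
    if pool_size <= 0:
        raise ConfigError("pool_size must be > 0")
    if not 0 < n_tested <= pool_size:
        raise ConfigError("n_tested must lie in (0, pool_size]")
    return round(n_tested / pool_size, 3)


def threshold_for_fraction(reference: CalibrationReference, fraction: float) -> float:
    """Raw-score threshold selecting the top ``fraction`` of the reference.

    The threshold is the order statistic at index ceil((1 - fraction) * N),
    so (absent ties) exactly ``round(fraction * N)`` reference scores are
    >= the threshold; ``fraction=1`` selects everything.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"fraction must lie in (0, 1], got {fraction}")
    idx = int(np.ceil((1.0 - fraction) * reference.n))
    idx = min(idx, reference.n - 1)
    return float(reference.scores[idx])
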
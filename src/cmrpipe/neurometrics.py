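"""Population neurometrics: firing-rate votes, proportion correct, binomial thresholds.

Each cell casts a vote per (condition, SNR) by comparing its mean
first-pip-window firing rate on signal trials against that condition's
noise-alone trials: a >=25% relative increase is a "yes" (1), a >=25%
decrease a "no" (0), anything in between chance (0.5).  The population
proportion correct (mean vote) versus SNR is upsampled by linear
interpolation, and the detection threshold is the lowest SNR at which
performance beats chance by a one-sided exact binomial test at
p < 0.05, Bonferroni-corrected for the number of measured SNRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .sr import first_crossing, upsample

VOTE_CRITERION = 0.25
ALPHA = 0.05


@dataclass
class NeurometricFunction:
    family: str
    snrs_db: np.ndarray
    proportion: np.ndarray    # mean vote per measured SNR
    n_cells: int
    grid_db: np.ndarray
    grid_proportion: np.ndarray
    threshold_db: float | None = None


def cell_vote(rate_signal: float, rate_noise: float,
              criterion: float = VOTE_CRITERION) -> float:
    """Vote of one cell: 1 (yes) for a >=25% rate increase, 0 (no) for a
    >=25% decrease, 0.5 (chance) otherwise."""
    if rate_noise < 0 or rate_signal < 0:
        raise ValueError("rates must be nonnegative")
    if rate_noise == 0.0:
        return 1.0 if rate_signal > 0.0 else 0.5
    if rate_signal >= (1.0 + criterion) * rate_noise:
        return 1.0
    if rate_signal <= (1.0 - criterion) * rate_noise:
        return 0.0
    return 0.5


def population_proportion(votes: np.ndarray, snrs_db: Sequence[float],
                          family: str = "") -> NeurometricFunction:
    """Mean vote across cells per SNR, upsampled to a 0.1 dB grid.

    ``votes`` is (n_cells, n_snrs) with entries in {0, 0.5, 1}.
    """
    votes = np.asarray(votes, dtype=float)
    if votes.ndim != 2 or votes.shape[0] == 0:
        raise ValueError("votes must be a nonempty (n_cells, n_snrs) array")
    prop = votes.mean(axis=0)
    grid, gp = upsample(np.asarray(snrs_db, dtype=float), prop)
    return NeurometricFunction(family=family, snrs_db=np.asarray(snrs_db, float),
                               proportion=prop, n_cells=votes.shape[0],
                               grid_db=grid, grid_proportion=gp)


def binomial_tail_p(successes: int, n: int, p0: float = 0.5) -> float:
    """One-sided exact binomial tail P(X >= successes | n, p0)."""
    return float(stats.binom.sf(successes - 1, n, p0))


def neurometric_threshold(fn: NeurometricFunction, alpha: float = ALPHA,
                          m_tests: int | None = None) -> float | None:
    """Lowest upsampled SNR whose implied success count beats chance at
    p < alpha/m (Bonferroni over the measured SNRs); None if never.

    Fractional votes enter via rounding of proportion x n_cells to the
    nearest integer success count.
    """
    if fn.n_cells <= 0:
        raise ValueError("n_cells must be positive")
    m = m_tests if m_tests is not None else len(fn.snrs_db)
    corrected = alpha / m
    k = np.rint(fn.grid_proportion * fn.n_cells).astype(int)
    pvals = stats.binom.sf(k - 1, fn.n_cells, 0.5)
    sig = np.nonzero(pvals < corrected)[0]
    thr = None if sig.size == 0 else float(fn.grid_db[sig[0]])
    fn.threshold_db = thr
    return thr
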
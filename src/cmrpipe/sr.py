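"""Signal-response (SR) statistics.

The SR statistic isolates signal-evoked activity from the noise response:
per cell i, background condition j and SNR k,

    SR_ijk(t) = (Sig_ijk(t) - N_ij(t)) / sigma_i

where Sig is the signal+noise PSTH, N the noise-alone PSTH (5 ms bins)
and sigma_i the SD of the pooled multiset of all PSTH bin rates of that
cell (all masking conditions and SNRs; FRA trials excluded).  Averaging
SR over the first-pip window [1.175, 1.275] s yields an SR/SNR function
per cell; its first 0.5 SD crossing on a linearly upsampled SNR grid is
the cell's detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import timeline as tl
from .io import PSTH

SR_CRITERION_SD = 0.5
SUBPOP_CRITERION_SD = 0.25
UPSAMPLE_STEP_DB = 0.1


@dataclass
class SRProfile:
    """Per-bin signal response of one (cell, condition, SNR), in SD units."""

    cell_id: object
    family: str
    snr_db: float
    bin_edges: np.ndarray
    sr: np.ndarray            # SD units per 5 ms bin
    sigma: float              # spikes/s


@dataclass
class SRFunction:
    """SR (pip-window mean, SD units) as a function of SNR, plus threshold."""

    cell_id: object
    family: str
    snrs_db: np.ndarray
    values: np.ndarray
    grid_db: np.ndarray
    grid_values: np.ndarray
    threshold_db: float | None


def cell_sigma(psths: Iterable[PSTH]) -> float:
    """SD (population, divide-by-n) of all PSTH bin rates pooled across
    conditions.  Raises on zero variance (cell excluded downstream)."""
    bins = np.concatenate([np.asarray(p.rate, dtype=float) for p in psths])
    if bins.size < 2:
        raise ValueError("need at least 2 PSTH bins to compute sigma")
    sigma = float(np.std(bins))
    if sigma == 0.0:
        raise ValueError("zero variance across PSTH bins; sigma undefined")
    return sigma


def signal_response(sig: PSTH, noise: PSTH, sigma: float,
                    family: str = "", snr_db: float = np.nan) -> SRProfile:
    """SR(t) = (Sig(t) - N(t)) / sigma per 5 ms bin."""
    if sig.rate.shape != noise.rate.shape or not np.allclose(sig.bin_edges, noise.bin_edges):
        raise ValueError("signal and noise PSTHs must share bin edges")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return SRProfile(cell_id=sig.cell_id, family=family, snr_db=snr_db,
                     bin_edges=sig.bin_edges,
                     sr=(sig.rate - noise.rate) / sigma, sigma=sigma)


def _window_bin_slice(bin_edges: np.ndarray, window: tuple[float, float]) -> slice:
    """Slice of bins fully inside [t0, t1)."""
    t0, t1 = window
    lo = int(np.searchsorted(bin_edges, t0 - 1e-9, side="left"))
    hi = int(np.searchsorted(bin_edges, t1 + 1e-9, side="right")) - 1
    if hi <= lo:
        raise ValueError("window covers no complete bin")
    return slice(lo, hi)


def pip_window_mean(profile: SRProfile,
                    window: tuple[float, float] = tl.PIP1_WINDOW) -> float:
    """Mean SR over bins fully inside the first-pip analysis window."""
    return float(profile.sr[_window_bin_slice(profile.bin_edges, window)].mean())


def upsample(snrs_db: Sequence[float], values: Sequence[float],
             step_db: float = UPSAMPLE_STEP_DB) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation upsampling of a function of SNR to a fine grid."""
    snrs_db = np.asarray(snrs_db, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(snrs_db)
    snrs_db, values = snrs_db[order], values[order]
    n_steps = int(round((snrs_db[-1] - snrs_db[0]) / step_db))
    grid = snrs_db[0] + step_db * np.arange(n_steps + 1)
    return grid, np.interp(grid, snrs_db, values)


def first_crossing(grid_db: np.ndarray, grid_values: np.ndarray,
                   criterion: float) -> float | None:
    """Lowest grid SNR with value >= criterion; None if never reached."""
    above = np.nonzero(grid_values >= criterion)[0]
    if above.size == 0:
        return None
    return float(grid_db[above[0]])


def sr_snr_function(profiles: Sequence[SRProfile],
                    criterion: float = SR_CRITERION_SD,
                    window: tuple[float, float] = tl.PIP1_WINDOW) -> SRFunction:
    """SR/SNR function of one cell/condition from its per-SNR SR profiles."""
    if not profiles:
        raise ValueError("no SR profiles supplied")
    snrs = np.array([p.snr_db for p in profiles], dtype=float)
    if np.unique(snrs).size != snrs.size:
        raise ValueError("duplicate SNRs among profiles")
    vals = np.array([pip_window_mean(p, window) for p in profiles])
    grid, gv = upsample(snrs, vals)
    thr = first_crossing(grid, gv, criterion)
    return SRFunction(cell_id=profiles[0].cell_id, family=profiles[0].family,
                      snrs_db=np.sort(snrs), values=vals[np.argsort(snrs)],
                      grid_db=grid, grid_values=gv, threshold_db=thr)


# ---------------------------------------------------------------------------
# bootstrap significance screen
# ---------------------------------------------------------------------------

def bootstrap_significance(rates_a: Sequence[float], rates_b: Sequence[float],
                           n_boot: int = 500,
                           seed: int | np.random.Generator = 0) -> bool:
    """Is condition B's mean rate a significant *increase* over condition A?

    Pools the per-trial rates of both conditions and bootstraps the null
    distribution of the difference of means (|A|- and |B|-sized resamples
    drawn with replacement from the pool, ``n_boot`` times); B is flagged
    significant when the observed mean difference exceeds the 95th
    percentile of that null distribution (one-sided, nominal 5% level).
    """
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    if rates_a.size < 5 or rates_b.size < 5:
        raise ValueError("need at least 5 trials per condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.concatenate([rates_a, rates_b])
    ib = rng.integers(0, pool.size, size=(n_boot, rates_b.size))
    ia = rng.integers(0, pool.size, size=(n_boot, rates_a.size))
    null_diff = pool[ib].mean(axis=1) - pool[ia].mean(axis=1)
    obs = rates_b.mean() - rates_a.mean()
    return bool(obs > np.percentile(null_diff, 95.0))


def select_responsive(flags: Mapping[object, Mapping[tuple[str, float], bool]]
                      ) -> tuple[set, dict[str, set]]:
    """Collapse per-(cell, family, SNR) significance flags into responsive sets.

    ``flags[cell][(family, snr)]`` is the bootstrap outcome of signal+noise
    vs noise-alone.  Returns (overall set, per-family sets).
    """
    overall: set = set()
    per_family: dict[str, set] = {}
    for cell, combos in flags.items():
        for (family, _snr), sig in combos.items():
            if sig:
                overall.add(cell)
                per_family.setdefault(family, set()).add(cell)
    return overall, per_family


# ---------------------------------------------------------------------------
# population aggregation
# ---------------------------------------------------------------------------

def population_mean_sr(profiles_by_cell: Mapping[object, Sequence[SRProfile]],
                       criterion: float = SR_CRITERION_SD) -> SRFunction:
    """Unweighted mean of per-cell SR profiles -> population SR/SNR function.

    Every cell must contribute profiles at the same SNRs.
    """
    if not profiles_by_cell:
        raise ValueError("empty responsive set")
    per_cell_vals = []
    snr_ref = None
    family = ""
    for cell, profiles in profiles_by_cell.items():
        snrs = np.array([p.snr_db for p in profiles], dtype=float)
        order = np.argsort(snrs)
        if snr_ref is None:
            snr_ref = snrs[order]
            family = profiles[0].family
        elif not np.allclose(snrs[order], snr_ref):
            raise ValueError(f"cell {cell} has mismatched SNR set")
        per_cell_vals.append(
            np.array([pip_window_mean(profiles[i]) for i in order]))
    mean_vals = np.mean(per_cell_vals, axis=0)
    grid, gv = upsample(snr_ref, mean_vals)
    return SRFunction(cell_id=None, family=family, snrs_db=snr_ref,
                      values=mean_vals, grid_db=grid, grid_values=gv,
                      threshold_db=first_crossing(grid, gv, criterion))


def subpopulation_sensitivity(values_by_cell: np.ndarray, snrs_db: Sequence[float],
                              n_sel: int = 50, n_rep: int = 500,
                              criterion: float = SUBPOP_CRITERION_SD,
                              seed: int | np.random.Generator = 0) -> float | None:
    """Bootstrap sensitivity of a CF-defined subpopulation.

    ``values_by_cell`` is (n_cells, n_snrs) of per-cell SR/SNR values.  Per
    repeat, ``n_sel`` cells are drawn with replacement and their functions
    averaged; the mean of the ``n_rep`` functions is upsampled and its first
    crossing of ``criterion`` (SD units) returned, or None if never reached.
    """
    values_by_cell = np.asarray(values_by_cell, dtype=float)
    if values_by_cell.ndim != 2 or values_by_cell.shape[0] == 0:
        raise ValueError("empty CF bin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cells = values_by_cell.shape[0]
    picks = rng.integers(0, n_cells, size=(n_rep, n_sel))
    rep_fns = values_by_cell[picks].mean(axis=1)      # (n_rep, n_snrs)
    mean_fn = rep_fns.mean(axis=0)
    grid, gv = upsample(np.asarray(snrs_db, dtype=float), mean_fn)
    return first_crossing(grid, gv, criterion)


def masking_release(threshold_a: float | None, threshold_b: float | None) -> float | None:
    """MR = threshold(A) - threshold(B), dB; positive means B more sensitive.

    Undefined (None) when either threshold is missing.
    """
    if threshold_a is None or threshold_b is None:
        return None
    return float(threshold_a) - float(threshold_b)
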
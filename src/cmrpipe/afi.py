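"""Across-frequency interaction (AFI) on noise-onset responses.

AFI quantifies how widening the masker changes a cell's response to noise
onset.  Mean spike counts in the onset window (0-75 ms of noise onset,
noise-alone trials) are mapped through an exponential (cortical rates are
log-normal across the population, so this linearizes them), normalized by
the cell's maximum across all masker conditions, and differenced:

    AFI = a(broadband) - a(NB),   a(s) = exp(c_s - max_s c_s)

Positive AFI means facilitation of the onset response relative to the
narrowband masker, negative AFI suppression; AFI lies in (-1, 1).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import timeline as tl
from .io import trial_window_counts
from .stimuli import LASER_OFF

N_AFI_BINS = 6


def onset_count(spikes: pd.DataFrame, trials: pd.DataFrame, cell_id,
                masker_kind: str) -> float:
    """Mean per-trial spike count in the noise-onset window (0-75 ms of the
    condition's noise onset), noise-alone trials only."""
    has_precursor = masker_kind != "CM_short"
    window = tl.onset_window(has_precursor)
    counts = trial_window_counts(
        spikes, trials, cell_id,
        {"masker_kind": masker_kind, "snr_db": np.nan, "laser": LASER_OFF},
        window)
    return float(counts.mean())


def normalize_counts(counts: Mapping[str, float]) -> dict[str, float]:
    """Exponentiate then divide by the per-cell maximum, computed in the
    shifted form exp(c - max c) for numerical safety."""
    if not counts:
        raise ValueError("need at least one stimulus count")
    cmax = max(counts.values())
    return {k: float(np.exp(c - cmax)) for k, c in counts.items()}


def afi(counts: Mapping[str, float], broadband: str, narrowband: str = "NB") -> float:
    """AFI = normalized(broadband) - normalized(NB) from raw onset counts."""
    for key in (broadband, narrowband):
        if key not in counts:
            raise KeyError(f"missing onset count for condition {key!r}")
    norm = normalize_counts(counts)
    return norm[broadband] - norm[narrowband]


def afi_mr_relation(afi_values: Sequence[float], mr_values: Sequence[float],
                    n_bins: int = N_AFI_BINS) -> dict:
    """Relationship between AFI and per-cell masking release.

    Bins cells by AFI into ``n_bins`` equal-count bins and reports per-bin
    mean masking release, plus the Pearson correlation across cells.
    Returns r/p as None when the correlation is undefined (constant input).
    """
    a = np.asarray(afi_values, dtype=float)
    m = np.asarray(mr_values, dtype=float)
    if a.size != m.size or a.size < 2:
        raise ValueError("need >=2 cells with both AFI and masking release")

    if np.ptp(a) == 0 or np.ptp(m) == 0:
        r, p = None, None
    else:
        r, p = stats.pearsonr(a, m)
        r, p = float(r), float(p)

    order = np.argsort(a, kind="stable")
    bin_of = np.empty(a.size, dtype=int)
    bin_of[order] = np.minimum((np.arange(a.size) * n_bins) // a.size, n_bins - 1)
    groups = [m[bin_of == b] for b in range(n_bins)]
    bin_mean_afi = [float(a[bin_of == b].mean()) if (bin_of == b).any() else np.nan
                    for b in range(n_bins)]
    bin_mean_mr = [float(g.mean()) if g.size else np.nan for g in groups]
    return {
        "pearson_r": r,
        "pearson_p": p,
        "bin_mean_afi": bin_mean_afi,
        "bin_mean_mr": bin_mean_mr,
        "bin_groups": groups,
        "n_cells": int(a.size),
    }


def afi_by_cf(afi_values: Sequence[float], cfs: Sequence[float],
              grid_freqs: Sequence[float]) -> dict[float, float | None]:
    """Mean AFI per CF grid frequency; empty bins reported as None."""
    a = np.asarray(afi_values, dtype=float)
    c = np.asarray(cfs, dtype=float)
    out: dict[float, float | None] = {}
    for f in grid_freqs:
        sel = np.isclose(c, f, rtol=1e-9)
        out[float(f)] = float(a[sel].mean()) if sel.any() else None
    return out
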
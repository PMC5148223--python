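"""Trial-aligned spike data interchange: CSV reader/writer, PSTHs, window rates.

Interchange format (UTF-8 CSV, header row):

* ``spikes.csv`` -- ``cell_id, trial_id, spike_time_s`` with spike times in
  trial-aligned seconds.
* ``trials.csv`` -- ``trial_id, onset_s, masker_kind, snr_db, laser,
  fra_freq_hz, fra_level_db``; inapplicable fields are left empty (NA).

Condition keys select trials by equality on trial-table columns, e.g.
``{"masker_kind": "CM_long", "snr_db": 5.0, "laser": "off"}``.  A missing
``snr_db`` key is matched with NaN for noise-alone trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import timeline as tl

SPIKE_COLUMNS = ["cell_id", "trial_id", "spike_time_s"]
TRIAL_COLUMNS = ["trial_id", "onset_s", "masker_kind", "snr_db", "laser",
                 "fra_freq_hz", "fra_level_db"]


@dataclass
class PSTH:
    """Per-cell, per-condition binned firing rate (spikes/s)."""

    cell_id: object
    condition: Mapping
    bin_edges: np.ndarray     # len(rate) + 1, seconds
    rate: np.ndarray          # spikes/s per bin
    n_trials: int

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_spikes(self) -> float:
        """Spike count implied by the rate histogram (conservation check)."""
        return float(self.rate.sum() * self.bin_s * self.n_trials)


def validate_tables(spikes: pd.DataFrame, trials: pd.DataFrame) -> None:
    for col in SPIKE_COLUMNS:
        if col not in spikes.columns:
            raise ValueError(f"spikes table missing column {col!r}")
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise ValueError(f"trials table missing column {col!r}")
    if trials["trial_id"].duplicated().any():
        dups = trials.loc[trials["trial_id"].duplicated(), "trial_id"].tolist()
        raise ValueError(f"duplicate trial_ids: {dups[:5]}")
    if len(spikes):
        if not np.issubdtype(np.asarray(spikes["spike_time_s"]).dtype, np.number):
            raise ValueError("non-numeric spike times")
        known = set(trials["trial_id"])
        orphan = set(spikes["trial_id"]) - known
        if orphan:
            raise ValueError(
                f"spikes reference unknown trial_ids: {sorted(orphan)[:10]}"
            )


def read_dataset(spikes_path, trials_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the spikes/trials CSV pair."""
    spikes = pd.read_csv(spikes_path)
    trials = pd.read_csv(trials_path, dtype={"masker_kind": "string", "laser": "string"})
    validate_tables(spikes, trials)
    return spikes, trials


def write_dataset(spikes: pd.DataFrame, trials: pd.DataFrame, out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sp, tp = out_dir / "spikes.csv", out_dir / "trials.csv"
    spikes.to_csv(sp, index=False)
    trials.to_csv(tp, index=False)
    return sp, tp


def _match_trials(trials: pd.DataFrame, condition: Mapping) -> pd.DataFrame:
    mask = np.ones(len(trials), dtype=bool)
    for col, val in condition.items():
        series = trials[col]
        if val is None or (isinstance(val, float) and np.isnan(val)):
            mask &= series.isna().to_numpy()
        else:
            mask &= (series == val).fillna(False).to_numpy()
    return trials[mask]


def compute_psth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    cell_id,
    condition: Mapping,
    bin_s: float = tl.PSTH_BIN_S,
    duration: float = tl.TRIAL_S,
) -> PSTH:
    """Trial-averaged firing-rate histogram with half-open bins [t, t+bin).

    rate[b] = spike count in bin b / (n_trials * bin_s).
    """
    matched = _match_trials(trials, condition)
    n_trials = len(matched)
    if n_trials == 0:
        raise ValueError(f"no trials match condition {dict(condition)}")
    edges = np.arange(0.0, duration + bin_s / 2, bin_s)
    sel = spikes[(spikes["cell_id"] == cell_id)
                 & spikes["trial_id"].isin(matched["trial_id"])]
    t = sel["spike_time_s"].to_numpy(dtype=float)
    idx = np.floor(t / bin_s).astype(int)
    ok = (idx >= 0) & (idx < len(edges) - 1)
    counts = np.bincount(idx[ok], minlength=len(edges) - 1)
    rate = counts / (n_trials * bin_s)
    return PSTH(cell_id=cell_id, condition=dict(condition), bin_edges=edges,
                rate=rate, n_trials=n_trials)


def window_rate(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    cell_id,
    condition: Mapping,
    window: tuple[float, float],
) -> float:
    """Mean firing rate (spikes/s) in a half-open window [t0, t1)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    matched = _match_trials(trials, condition)
    n_trials = len(matched)
    if n_trials == 0:
        raise ValueError(f"no trials match condition {dict(condition)}")
    sel = spikes[(spikes["cell_id"] == cell_id)
                 & spikes["trial_id"].isin(matched["trial_id"])]
    t = sel["spike_time_s"].to_numpy(dtype=float)
    n = int(((t >= t0) & (t < t1)).sum())
    return n / (n_trials * (t1 - t0))


def trial_window_counts(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    cell_id,
    condition: Mapping,
    window: tuple[float, float],
) -> np.ndarray:
    """Per-trial spike counts in a window (one entry per matching trial)."""
    t0, t1 = window
    matched = _match_trials(trials, condition)
    if matched.empty:
        raise ValueError(f"no trials match condition {dict(condition)}")
    sel = spikes[(spikes["cell_id"] == cell_id)
                 & spikes["trial_id"].isin(matched["trial_id"])]
    t = sel["spike_time_s"].to_numpy(dtype=float)
    in_win = sel.loc[(t >= t0) & (t < t1), "trial_id"]
    counts = in_win.value_counts()
    return counts.reindex(matched["trial_id"], fill_value=0).to_numpy(dtype=float)
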
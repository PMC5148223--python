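"""Frequency response areas: smoothing, region extraction, characteristic frequency.

The FRA is a 25 (frequency) x 8 (level) matrix of mean tone-evoked firing
rates.  Raw matrices are smoothed with a 3x3 pyramidal kernel, then
response regions are extracted with a dual criterion: 4-connected
components of cells deviating >=30% from baseline, merged wherever they
are joined through cells passing a weaker 15% criterion of the same
polarity.  Characteristic frequency (CF) is the frequency of the largest
excitatory region's member at the lowest sound level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import timeline as tl
from .stimuli import FRAGrid

#: 3x3 pyramidal smoothing kernel (sums to 1)
PYRAMID_KERNEL = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float) / 16.0

#: 4-connectivity structuring element
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: absolute rate floor (spikes/s) replacing the relative criterion when
#: the baseline rate is zero
ZERO_BASELINE_FLOOR = 1.0


@dataclass
class FRAMatrix:
    """Mean tone-evoked rates on the FRA grid plus the cell's baseline rate."""

    rates: np.ndarray          # (n_freqs, n_levels), spikes/s
    baseline_rate: float
    freqs: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (len(self.freqs), len(self.levels)):
            raise ValueError(
                f"rates shape {self.rates.shape} does not match grid "
                f"({len(self.freqs)}, {len(self.levels)})"
            )


@dataclass
class FRARegion:
    """A 4-connected set of (freq index, level index) grid cells."""

    members: frozenset[tuple[int, int]]
    polarity: str  # excitatory | inhibitory

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CFResult:
    cf: float
    threshold_level: float
    region: FRARegion


def compute_fra(spikes: pd.DataFrame, trials: pd.DataFrame, cell_id,
                grid: FRAGrid) -> FRAMatrix:
    """Build the raw FRA for one cell from FRA trials.

    Each entry is the mean rate in the tone window; the baseline is the mean
    rate in the pre-tone window pooled over all FRA trials.
    """
    fra_trials = trials[trials["fra_freq_hz"].notna()]
    if fra_trials.empty:
        raise ValueError("no FRA trials in the trial table")

    sel = spikes[(spikes["cell_id"] == cell_id)
                 & spikes["trial_id"].isin(fra_trials["trial_id"])]
    merged = sel.merge(fra_trials[["trial_id", "fra_freq_hz", "fra_level_db"]],
                       on="trial_id", how="left")
    t = merged["spike_time_s"].to_numpy(dtype=float)
    t0, t1 = tl.FRA_TONE_ONSET_S, tl.FRA_TONE_ONSET_S + tl.FRA_TONE_DUR_S

    rates = np.zeros((len(grid.freqs), len(grid.levels)))
    missing = []
    for i, f in enumerate(grid.freqs):
        for j, l in enumerate(grid.levels):
            n_tr = int(((fra_trials["fra_freq_hz"] == f)
                        & (fra_trials["fra_level_db"] == l)).sum())
            if n_tr == 0:
                missing.append((f, l))
                continue
            in_cond = (merged["fra_freq_hz"] == f) & (merged["fra_level_db"] == l)
            n_spk = int((in_cond & (t >= t0) & (t < t1)).sum())
            rates[i, j] = n_spk / (n_tr * (t1 - t0))
    if missing:
        raise ValueError(f"missing FRA grid points: {missing[:10]}")

    n_base = int(((t >= 0.0) & (t < t0)).sum())
    baseline = n_base / (len(fra_trials) * t0)
    return FRAMatrix(rates=rates, baseline_rate=baseline,
                     freqs=tuple(grid.freqs), levels=tuple(grid.levels))


def smooth_pyramidal(m: FRAMatrix) -> FRAMatrix:
    """3x3 pyramidal smoothing; at edges the kernel is renormalized over
    in-bounds cells so a constant matrix is left unchanged."""
    num = ndimage.convolve(m.rates, PYRAMID_KERNEL, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(m.rates), PYRAMID_KERNEL,
                           mode="constant", cval=0.0)
    return FRAMatrix(rates=num / den, baseline_rate=m.baseline_rate,
                     freqs=m.freqs, levels=m.levels)


def _criterion_masks(m: FRAMatrix, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """(excitatory, inhibitory) boolean masks at a relative criterion."""
    b = m.baseline_rate
    if b > 0:
        exc = m.rates >= b * (1.0 + frac)
        inh = m.rates <= b * (1.0 - frac)
    else:
        # silent baseline: relative criteria are degenerate; use a rate floor
        exc = m.rates >= ZERO_BASELINE_FLOOR * (frac / 0.30)
        inh = np.zeros_like(m.rates, dtype=bool)
    return exc, inh


def _components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    labels, n = ndimage.label(mask, structure=FOUR_CONN)
    out = []
    for k in range(1, n + 1):
        ii, jj = np.nonzero(labels == k)
        out.append(frozenset(zip(ii.tolist(), jj.tolist())))
    return out


def find_regions(m: FRAMatrix, strong: float = 0.30, weak: float = 0.15) -> list[FRARegion]:
    """Extract response regions with the dual 30%/15% criterion.

    Strong (30%) components of the same polarity that are connected through
    cells passing the weak (15%) criterion are merged into single regions.
    """
    regions: list[FRARegion] = []
    strong_exc, strong_inh = _criterion_masks(m, strong)
    weak_exc, weak_inh = _criterion_masks(m, weak)
    for polarity, s_mask, w_mask in (("excitatory", strong_exc, weak_exc),
                                     ("inhibitory", strong_inh, weak_inh)):
        strong_comps = _components(s_mask)
        if not strong_comps:
            continue
        weak_labels, _ = ndimage.label(w_mask, structure=FOUR_CONN)
        # group strong components by the weak component that contains them
        groups: dict[int, set] = {}
        for comp in strong_comps:
            i, j = next(iter(comp))
            key = int(weak_labels[i, j])  # strong cells always pass weak
            groups.setdefault(key, set()).update(comp)
        for members in groups.values():
            regions.append(FRARegion(members=frozenset(members), polarity=polarity))
    return regions


def characteristic_frequency(regions: list[FRARegion], m: FRAMatrix) -> CFResult | None:
    """CF from the largest excitatory region: frequency of the member at the
    lowest level; ties at the lowest level go to the highest smoothed rate.

    Returns None when the cell has no excitatory region (excluded from
    CF-based analyses).
    """
    exc = [r for r in regions if r.polarity == "excitatory"]
    if not exc:
        return None
    largest = max(exc, key=lambda r: (len(r), -min(j for _, j in r.members)))
    min_j = min(j for _, j in largest.members)
    tips = [(i, j) for i, j in largest.members if j == min_j]
    i_best, j_best = max(tips, key=lambda ij: m.rates[ij])
    return CFResult(cf=m.freqs[i_best], threshold_level=m.levels[j_best],
                    region=largest)
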
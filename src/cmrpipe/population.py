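"""Synthetic neuronal populations with planted condition effects.

Each model neuron is an inhomogeneous Poisson unit whose rate is built
from: a log-normally distributed baseline, Gaussian-in-log-frequency
tuning around a characteristic frequency, an exponentially decaying
onset transient at noise onset, a sustained noise-driven component, and
a logistic signal response in the first-pip window whose midpoint is the
cell's *planted* detection threshold for that masker condition.  Planted
per-condition thresholds encode the effects the analysis must recover
(comodulation release, priming, and inactivation shifts), and a signed
coupling links per-cell onset suppression under comodulated noise to
threshold improvement.  The laser multiplies the rate during the laser
window (suppressive for PV- cells, excitatory for PV+ cells).

The signal response is multiplicative (a relative rate increase on top of
the cell's noise response), so that the +-25% vote statistic behaves
identically across masker conditions and planted threshold *differences*
survive the analysis unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import timeline as tl
from .stimuli import (FAMILIES, LASER_OFF, LASER_ON, SIGNAL_FREQ_HZ,
                      StimulusSchedule, TrialCondition, envelope_value,
                      family_key)

DEFAULT_THRESHOLDS_DB = {
    "NB": 8.0,
    "IM": 6.5,
    "CM_long": 1.0,
    "CM_short": 6.5,
    "CM_long_laser": 6.5,
    "CM_short_laser": 6.5,
}


@dataclass
class PopulationConfig:
    """Generative parameters of a simulated population."""

    n_cells: int = 500
    cf_range_hz: tuple[float, float] = (15000.0, 22000.0)
    # log-normal baseline: mu/sigma of log(rate in spikes/s)
    baseline_log_mu: float = float(np.log(3.0))
    baseline_log_sigma: float = 0.4
    tuning_bw_oct: float = 0.2
    tuning_bw_jitter: float = 0.03
    sustained_gain: float = 60.0
    sustained_gain_jitter: float = 0.1
    #: adaptation of the sustained response during the precursor (fraction
    #: of the masker-portion sustained gain)
    precursor_gain: float = 0.5
    onset_gain: float = 40.0
    #: SD of the per-cell log onset-gain perturbation under broadband noise
    onset_delta_sd: float = 0.4
    #: dB of threshold change per unit (negative) onset-delta for CM noise;
    #: negative coupling means onset suppression -> threshold improvement
    afi_coupling: float = -3.0
    #: same coupling for the IM condition (paper-like default: none)
    afi_coupling_im: float = 0.0
    thresholds_db: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS_DB))
    threshold_jitter_sd: float = 1.0
    threshold_slope_db: float = 1.25
    signal_gain: float = 1.5          # relative rate increase at full response
    signal_gain_jitter: float = 0.3
    onset_tau_s: float = 0.025
    respond_all_pips: bool = False
    envelope_locking: bool = False
    pv_pos_frac: float = 0.1
    laser_gain_pv_neg: float = 0.15
    laser_gain_pv_pos: float = 3.0
    fra_gain: float = 25.0
    fra_tip_level_db: float = 30.0
    fra_slope_db_per_oct: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 < self.cf_range_hz[0] <= self.cf_range_hz[1]):
            raise ValueError(f"invalid cf_range_hz {self.cf_range_hz}")


@dataclass
class NeuronParams:
    """Ground-truth generative parameters of one simulated neuron."""

    cell_id: int
    cf: float
    tuning_bw: float
    baseline_rate: float
    sustained_gain: float
    precursor_gain: float         # sustained-gain fraction during the precursor
    onset_gain: dict              # per masker kind, spikes/s per unit weight
    onset_tau_s: float
    signal_gain: float            # relative (multiplicative) response gain
    threshold_db: dict            # per condition family
    threshold_slope: float
    afi_delta: float              # planted log onset perturbation (CM)
    pv_type: str                  # "PV+" | "PV-"
    laser_gain: float
    fra_gain: float
    fra_tip_level_db: float
    fra_slope_db_per_oct: float
    respond_all_pips: bool = False
    envelope_locking: bool = False


def sample_population(config: PopulationConfig) -> list[NeuronParams]:
    """Draw a seeded population: log-uniform CFs, log-normal baselines,
    per-cell planted thresholds = population effect sizes + jitter, and
    onset perturbations coupled to CM thresholds via ``afi_coupling``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    lo, hi = config.cf_range_hz
    cfs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    baselines = np.exp(rng.normal(config.baseline_log_mu,
                                  config.baseline_log_sigma, size=n))
    bws = np.maximum(config.tuning_bw_oct
                     + rng.normal(0.0, config.tuning_bw_jitter, size=n), 0.05)
    sus = np.maximum(config.sustained_gain
                     * np.exp(rng.normal(0.0, config.sustained_gain_jitter, size=n)), 0.0)
    sgain = np.maximum(config.signal_gain
                       + rng.normal(0.0, config.signal_gain_jitter, size=n), 0.0)
    delta_cm = rng.normal(0.0, config.onset_delta_sd, size=n)
    delta_im = rng.normal(0.0, config.onset_delta_sd, size=n)
    pv_pos = rng.random(n) < config.pv_pos_frac

    cells = []
    for i in range(n):
        onset_gain = {
            "NB": config.onset_gain,
            "IM": config.onset_gain * float(np.exp(delta_im[i])),
            "CM_long": config.onset_gain * float(np.exp(delta_cm[i])),
            "CM_short": config.onset_gain * float(np.exp(delta_cm[i])),
        }
        thr = {}
        for fam in FAMILIES:
            base = config.thresholds_db[fam]
            if fam in ("CM_long", "CM_long_laser"):
                base = base - config.afi_coupling * delta_cm[i]
            elif fam == "IM":
                base = base - config.afi_coupling_im * delta_im[i]
            thr[fam] = float(base + rng.normal(0.0, config.threshold_jitter_sd))
        cells.append(NeuronParams(
            cell_id=i, cf=float(cfs[i]), tuning_bw=float(bws[i]),
            baseline_rate=float(baselines[i]), sustained_gain=float(sus[i]),
            precursor_gain=config.precursor_gain,
            onset_gain=onset_gain, onset_tau_s=config.onset_tau_s,
            signal_gain=float(sgain[i]), threshold_db=thr,
            threshold_slope=config.threshold_slope_db,
            afi_delta=float(delta_cm[i]),
            pv_type="PV+" if pv_pos[i] else "PV-",
            laser_gain=(config.laser_gain_pv_pos if pv_pos[i]
                        else config.laser_gain_pv_neg),
            fra_gain=config.fra_gain,
            fra_tip_level_db=config.fra_tip_level_db,
            fra_slope_db_per_oct=config.fra_slope_db_per_oct,
            respond_all_pips=config.respond_all_pips,
            envelope_locking=config.envelope_locking,
        ))
    return cells


def truth_frame(population: Sequence[NeuronParams]) -> pd.DataFrame:
    """Flatten ground-truth parameters to a table (for text export)."""
    rows = []
    for p in population:
        row = {
            "cell_id": p.cell_id, "cf_hz": p.cf, "tuning_bw_oct": p.tuning_bw,
            "baseline_rate": p.baseline_rate, "sustained_gain": p.sustained_gain,
            "precursor_gain": p.precursor_gain,
            "signal_gain": p.signal_gain, "threshold_slope_db": p.threshold_slope,
            "afi_delta": p.afi_delta, "pv_type": p.pv_type,
            "laser_gain": p.laser_gain,
        }
        for kind, g in p.onset_gain.items():
            row[f"onset_gain_{kind}"] = g
        for fam, t in p.threshold_db.items():
            row[f"threshold_{fam}_db"] = t
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------

def _tuning_weight(cf: np.ndarray, bw: np.ndarray, freq) -> np.ndarray:
    d = np.log2(np.asarray(freq, dtype=float) / cf)
    return np.exp(-0.5 * (d / bw) ** 2)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


class _ParamArrays:
    """Column-wise view of a population for vectorized rate evaluation."""

    def __init__(self, population: Sequence[NeuronParams]):
        self.n = len(population)
        g = lambda attr: np.array([getattr(p, attr) for p in population], float)
        self.cf = g("cf")
        self.bw = g("tuning_bw")
        self.baseline = g("baseline_rate")
        self.sustained = g("sustained_gain")
        self.precursor_gain = g("precursor_gain")
        self.sgain = g("signal_gain")
        self.slope = g("threshold_slope")
        self.laser_gain = g("laser_gain")
        self.tau = g("onset_tau_s")
        self.fra_gain = g("fra_gain")
        self.fra_tip = g("fra_tip_level_db")
        self.fra_slope = g("fra_slope_db_per_oct")
        self.onset_gain = {k: np.array([p.onset_gain[k] for p in population])
                           for k in population[0].onset_gain}
        self.thr = {f: np.array([p.threshold_db[f] for p in population])
                    for f in population[0].threshold_db}
        self.respond_all_pips = population[0].respond_all_pips
        self.envelope_locking = population[0].envelope_locking
        self.w_sig = _tuning_weight(self.cf, self.bw, SIGNAL_FREQ_HZ)


def _pip_windows(respond_all: bool) -> list[tuple[float, float]]:
    if respond_all:
        return [(on, on + 0.1) for on in tl.PIP_ONSETS_S]
    return [tl.PIP1_WINDOW]


def _rate_matrix(pa: _ParamArrays, condition: TrialCondition,
                 t: np.ndarray) -> np.ndarray:
    """Instantaneous rate (spikes/s) for every cell at times ``t`` (trial-aligned)."""
    rate = np.broadcast_to(pa.baseline[:, None], (pa.n, t.size)).copy()

    if condition.masker is not None:
        masker = condition.masker
        kind = masker.kind
        band_freqs = np.array([b.center_freq for b in masker.bands])
        w = _tuning_weight(pa.cf[:, None], pa.bw[:, None], band_freqs[None, :])

        # precursor adaptation: the sustained response during the precursor
        # is scaled down by precursor_gain relative to the masker portion
        t_stim = t - tl.BASELINE_S
        in_pre = np.zeros(t.size, dtype=bool)
        if masker.has_precursor:
            p_on = tl.noise_onset_s(True)
            in_pre = (t >= p_on) & (t < p_on + masker.precursor_s)
        if pa.envelope_locking:
            envs = np.stack([envelope_value(masker, b, t_stim)
                             for b in range(len(masker.bands))])
        else:
            # unlocked sustained response: time-averaged envelope (0.5 within
            # active segments, 0 in the gap and silence)
            seg = np.zeros(t.size)
            m_on = tl.MASKER_ONSET_S
            seg[(t >= m_on) & (t < m_on + masker.masker_s)] = 0.5
            seg[in_pre] = 0.5
            envs = np.broadcast_to(seg, (len(masker.bands), t.size))
        sus = pa.sustained[:, None] * (w @ envs)
        sus[:, in_pre] *= pa.precursor_gain[:, None]
        rate = rate + sus

        t_on = tl.noise_onset_s(masker.has_precursor)
        dt_on = t - t_on
        transient = np.where(dt_on >= 0, np.exp(-np.maximum(dt_on, 0) / pa.tau[:, None]), 0.0)
        rate = rate + (pa.onset_gain[kind] * w.sum(axis=1))[:, None] * transient

        if condition.signal is not None:
            fam = family_key(kind, condition.laser)
            lvl = _logistic((condition.signal.snr_db - pa.thr[fam]) / pa.slope)
            mult = 1.0 + pa.sgain * lvl * pa.w_sig
            for w0, w1 in _pip_windows(pa.respond_all_pips):
                in_win = (t >= w0) & (t < w1)
                rate[:, in_win] *= mult[:, None]

        if condition.laser == LASER_ON:
            in_las = (t >= tl.LASER_WINDOW[0]) & (t < tl.LASER_WINDOW[1])
            rate[:, in_las] *= pa.laser_gain[:, None]
    else:
        freq, level = condition.fra_tone
        t_thr = pa.fra_tip + pa.fra_slope * np.abs(np.log2(freq / pa.cf))
        amp = pa.fra_gain * _logistic((level - t_thr) / 4.0)
        on = (t >= tl.FRA_TONE_ONSET_S) & (t < tl.FRA_TONE_ONSET_S + tl.FRA_TONE_DUR_S)
        rate[:, on] += amp[:, None]

    return np.maximum(rate, 0.0)


def rate_function(neuron: NeuronParams, condition: TrialCondition, t) -> np.ndarray | float:
    """Instantaneous firing rate of one neuron at trial-aligned time ``t``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = _rate_matrix(_ParamArrays([neuron]), condition, t_arr)[0]
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    trials: pd.DataFrame
    spikes: pd.DataFrame
    truth: list[NeuronParams]


def _condition_signature(tc: TrialCondition, trial_id: int, locking: bool):
    if tc.fra_tone is not None:
        return ("FRA", tc.fra_tone[0], tc.fra_tone[1])
    snr = tc.signal.snr_db if tc.signal is not None else None
    if locking and tc.masker.kind == "IM":
        # incoherent envelopes are re-drawn per presentation; rates are
        # trial-specific when the sustained response locks to the envelope
        return ("IM_trial", trial_id)
    return (tc.masker.kind, snr, tc.laser)


def generate_trials(population: Sequence[NeuronParams],
                    schedule: StimulusSchedule,
                    seed: int = 0,
                    dt: float = 0.001) -> SimulatedDataset:
    """Sample spike trains for every cell and trial of a schedule.

    Spikes are drawn from an inhomogeneous Poisson process at ``dt``
    resolution: per (cell, trial) the total count is Poisson with mean
    equal to the integrated rate, and spike times are drawn from the
    normalized rate profile by inverse-CDF sampling.
    """
    rng = np.random.default_rng(seed)
    pa = _ParamArrays(population)
    cell_ids = np.array([p.cell_id for p in population])

    groups: dict = {}
    for tid, tc in enumerate(schedule.trials):
        groups.setdefault(_condition_signature(tc, tid, pa.envelope_locking),
                          []).append(tid)

    all_cells, all_trials, all_times = [], [], []
    for sig_key, tids in groups.items():
        tc = schedule.trials[tids[0]]
        n_bins = int(round(tc.duration / dt))
        t_grid = (np.arange(n_bins) + 0.5) * dt
        rate = _rate_matrix(pa, tc, t_grid)            # (n_cells, n_bins)
        lam = rate.sum(axis=1) * dt
        counts = rng.poisson(lam[None, :], size=(len(tids), pa.n))

        total = rate.sum(axis=1)
        safe = np.where(total > 0, total, 1.0)
        cdf = np.cumsum(rate, axis=1) / safe[:, None]
        combined = (cdf + np.arange(pa.n)[:, None]).ravel()

        flat = counts.ravel()
        n_spikes = int(flat.sum())
        if n_spikes == 0:
            continue
        pair_cell = np.tile(np.arange(pa.n), len(tids))
        pair_trial = np.repeat(np.asarray(tids), pa.n)
        spike_cell = np.repeat(pair_cell, flat)
        spike_trial = np.repeat(pair_trial, flat)
        u = rng.random(n_spikes)
        idx = np.searchsorted(combined, spike_cell + u, side="left")
        bin_idx = idx - spike_cell * n_bins
        times = (bin_idx + rng.random(n_spikes)) * dt

        all_cells.append(cell_ids[spike_cell])
        all_trials.append(spike_trial)
        all_times.append(times)

    if all_cells:
        spikes = pd.DataFrame({
            "cell_id": np.concatenate(all_cells),
            "trial_id": np.concatenate(all_trials),
            "spike_time_s": np.concatenate(all_times),
        })
    else:
        spikes = pd.DataFrame({"cell_id": [], "trial_id": [], "spike_time_s": []})

    return SimulatedDataset(trials=schedule.to_frame(), spikes=spikes,
                            truth=list(population))
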
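"""Stimulus battery: maskers, signals, FRA grid and the block schedule.

The battery consists of sinusoidally amplitude-modulated (SAM, 10 Hz)
tone maskers in three bandwidth configurations -- a narrowband masker
(NB, a single 20 kHz band), and two seven-band broadband maskers whose
six flanking bands are modulated either incoherently (IM, random
envelope phases) or coherently (CM) with the on-frequency band.  Long
maskers carry a 400 ms precursor and a 100 ms gap before the 500 ms
masker portion; the short CM masker omits the precursor.  The signal is
a train of three 50 ms 20 kHz pips placed in envelope troughs 3-5 of the
masker portion, at SNRs of -10..20 dB in 5 dB steps re the 65 dB SPL
masker.

Envelope convention: the raised-cosine modulator starts at its *minimum*
at each segment onset, so envelope troughs fall at multiples of 100 ms
from segment onset and the first tone pip occupies the trial-aligned
window [1.175, 1.275] s used by all downstream analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import timeline as tl

MASKER_KINDS = ("NB", "IM", "CM_long", "CM_short")
SNR_GRID_DB = (-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0)
SIGNAL_FREQ_HZ = 20000.0
MASKER_LEVEL_DBSPL = 65.0

#: condition-family labels used for analysis keys (masker kind x laser)
FAMILIES = ("NB", "IM", "CM_long", "CM_short", "CM_long_laser", "CM_short_laser")

LASER_OFF = "off"
LASER_ON = "precursor_150ms"


def family_key(masker_kind: str, laser: str) -> str:
    """Map a (masker kind, laser state) pair to its condition-family label."""
    if laser == LASER_ON:
        return f"{masker_kind}_laser"
    return masker_kind


@dataclass(frozen=True)
class BandSpec:
    """One SAM pure-tone component of a masker."""

    center_freq: float                  # Hz
    modulator_rate: float = tl.MODULATOR_HZ
    modulator_phase: float = 0.0        # degrees, [0, 360)
    level_role: str = "on_frequency"    # on_frequency | low_flanker | high_flanker

    def __post_init__(self):
        if self.center_freq <= 0:
            raise ValueError(f"center_freq must be positive, got {self.center_freq}")
        if not (0.0 <= self.modulator_phase < 360.0):
            raise ValueError(f"modulator_phase must lie in [0, 360), got {self.modulator_phase}")


@dataclass(frozen=True)
class MaskerSpec:
    """A complete masker: band set plus temporal segmentation."""

    kind: str
    bands: tuple[BandSpec, ...]
    precursor_s: float
    gap_s: float
    masker_s: float = tl.MASKER_DUR_S
    level_dbspl: float = MASKER_LEVEL_DBSPL

    def __post_init__(self):
        if self.kind not in MASKER_KINDS:
            raise ValueError(f"unknown masker kind {self.kind!r}")
        n = len(self.bands)
        if self.kind == "NB" and n != 1:
            raise ValueError("NB masker must have exactly 1 band")
        if self.kind != "NB" and n != 7:
            raise ValueError(f"{self.kind} masker must have 7 bands, got {n}")

    @property
    def has_precursor(self) -> bool:
        return self.precursor_s > 0

    @property
    def masker_onset_stim(self) -> float:
        """Masker-portion onset in stimulus time (stim time 0 = trial 0.5 s)."""
        return tl.MASKER_ONSET_S - tl.BASELINE_S


@dataclass(frozen=True)
class SignalSpec:
    """Tone-pip train embedded in the masker portion."""

    snr_db: float
    carrier_freq: float = SIGNAL_FREQ_HZ
    n_pips: int = 3
    pip_s: float = tl.PIP_DUR_S
    pip_onsets: tuple[float, ...] = tl.PIP_ONSETS_S   # trial-aligned seconds


@dataclass(frozen=True)
class TrialCondition:
    """Everything that defines one stimulus presentation."""

    masker: Optional[MaskerSpec] = None
    signal: Optional[SignalSpec] = None
    fra_tone: Optional[tuple[float, float]] = None    # (freq Hz, level dB SPL)
    laser: str = LASER_OFF
    trial_onset: float = 0.0                          # session clock, seconds

    def __post_init__(self):
        if (self.masker is None) == (self.fra_tone is None):
            raise ValueError("a trial bears exactly one of masker or fra_tone")
        if self.signal is not None and self.masker is None:
            raise ValueError("signal requires a masker")

    @property
    def family(self) -> Optional[str]:
        if self.masker is None:
            return None
        return family_key(self.masker.kind, self.laser)

    @property
    def duration(self) -> float:
        return tl.TRIAL_S if self.masker is not None else tl.FRA_TRIAL_S


@dataclass(frozen=True)
class FRAGrid:
    """Pure-tone grid for frequency-response-area mapping."""

    freqs: tuple[float, ...]
    levels: tuple[float, ...]


@dataclass
class StimulusSchedule:
    trials: list[TrialCondition] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the trials-table interchange format (one row per trial)."""
        rows = []
        for tid, tc in enumerate(self.trials):
            rows.append(
                {
                    "trial_id": tid,
                    "onset_s": tc.trial_onset,
                    "masker_kind": tc.masker.kind if tc.masker else pd.NA,
                    "snr_db": tc.signal.snr_db if tc.signal else np.nan,
                    "laser": tc.laser,
                    "fra_freq_hz": tc.fra_tone[0] if tc.fra_tone else np.nan,
                    "fra_level_db": tc.fra_tone[1] if tc.fra_tone else np.nan,
                }
            )
        df = pd.DataFrame(rows)
        df["masker_kind"] = df["masker_kind"].astype("string")
        return df


# ---------------------------------------------------------------------------
# masker construction
# ---------------------------------------------------------------------------

# flanking-band centres sit +-5/8 octave from the 20 kHz signal frequency,
# each composed of three components at 1/8 octave spacing on the same grid
_LOW_FLANKER_OCT = (-0.75, -0.625, -0.5)
_HIGH_FLANKER_OCT = (0.5, 0.625, 0.75)


def _flanker_freqs() -> list[tuple[float, str]]:
    out = [(SIGNAL_FREQ_HZ * 2.0**o, "low_flanker") for o in _LOW_FLANKER_OCT]
    out += [(SIGNAL_FREQ_HZ * 2.0**o, "high_flanker") for o in _HIGH_FLANKER_OCT]
    return out


def build_masker(kind: str, seed: int | np.random.Generator = 0) -> MaskerSpec:
    """Construct a masker of the given kind.

    IM flanking-band envelope phases are drawn independently (uniform on
    [0, 180) degrees) on every call; pass a seed (or Generator) for
    reproducibility.  CM and NB maskers are deterministic.
    """
    if kind not in MASKER_KINDS:
        raise ValueError(f"unknown masker kind {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    on_band = BandSpec(SIGNAL_FREQ_HZ, modulator_phase=0.0, level_role="on_frequency")
    if kind == "NB":
        bands: tuple[BandSpec, ...] = (on_band,)
    else:
        flankers = []
        for f, role in _flanker_freqs():
            if kind == "IM":
                phase = float(rng.uniform(0.0, 180.0))
            else:
                phase = 0.0  # comodulated: identical to the on-frequency band
            flankers.append(BandSpec(f, modulator_phase=phase, level_role=role))
        bands = (on_band, *flankers)

    if kind == "CM_short":
        precursor_s, gap_s = 0.0, 0.0
    else:
        precursor_s, gap_s = tl.PRECURSOR_DUR_S, tl.GAP_DUR_S
    return MaskerSpec(kind=kind, bands=bands, precursor_s=precursor_s, gap_s=gap_s)


def envelope_value(masker: MaskerSpec, band_index: int, t) -> np.ndarray | float:
    """SAM envelope of one band at stimulus time ``t`` (0 = trial 0.5 s).

    Raised cosine 0.5*(1 - cos(2*pi*f_mod*t' + phase)) where t' runs from
    the onset of the active segment (precursor or masker portion); zero in
    the gap and outside the stimulus.
    """
    if not (0 <= band_index < len(masker.bands)):
        raise IndexError(f"band_index {band_index} out of range")
    band = masker.bands[band_index]
    t = np.asarray(t, dtype=float)
    phase = math.radians(band.modulator_phase)

    m_on = masker.masker_onset_stim
    out = np.zeros_like(t)

    if masker.has_precursor:
        p_on = m_on - masker.gap_s - masker.precursor_s
        in_pre = (t >= p_on) & (t < p_on + masker.precursor_s)
        tp = t[in_pre] - p_on
        out[in_pre] = 0.5 * (1.0 - np.cos(2 * np.pi * band.modulator_rate * tp + phase))

    in_mask = (t >= m_on) & (t < m_on + masker.masker_s)
    tm = t[in_mask] - m_on
    out[in_mask] = 0.5 * (1.0 - np.cos(2 * np.pi * band.modulator_rate * tm + phase))
    return out if out.ndim else float(out)


def build_signal(snr_db: float | None, masker: MaskerSpec) -> SignalSpec | None:
    """Signal pips for a given SNR; ``None`` means the noise-alone condition.

    The three 50 ms half-sine pips are centred on the 3rd, 4th and 5th
    envelope troughs of the masker portion (onset minimum counts as
    trough 1), i.e. trial-aligned onsets 1.175, 1.275, 1.375 s.
    """
    if masker.masker_s <= 0:
        raise ValueError("masker has no masker portion")
    if snr_db is None:
        return None
    if float(snr_db) not in SNR_GRID_DB:
        raise ValueError(f"snr_db {snr_db} outside the configured grid {SNR_GRID_DB}")
    centers = [tl.MASKER_ONSET_S + k * tl.MOD_PERIOD_S for k in (2, 3, 4)]
    onsets = tuple(c - tl.PIP_DUR_S / 2 for c in centers)
    return SignalSpec(snr_db=float(snr_db), pip_onsets=onsets)


def build_fra_grid() -> FRAGrid:
    """25 frequencies at 1/8-octave spacing centred on 20 kHz; 8 levels 10-80 dB."""
    freqs = tuple(SIGNAL_FREQ_HZ * 2.0 ** (k / 8.0) for k in range(-12, 13))
    levels = tuple(float(l) for l in range(10, 81, 10))
    return FRAGrid(freqs=freqs, levels=levels)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    masker_kinds: tuple[str, ...] = MASKER_KINDS
    snr_grid_db: tuple[float, ...] = SNR_GRID_DB
    #: masker kinds that also appear with the laser on
    laser_kinds: tuple[str, ...] = ("CM_long", "CM_short")
    n_cycles: int = 6
    masking_blocks_per_cycle: int = 5
    include_fra: bool = True
    isi_masking_s: float = 2.0
    isi_fra_s: float = 1.0


def _masking_combos(config: ScheduleConfig) -> list[tuple[str, float | None, str]]:
    combos = []
    for kind in config.masker_kinds:
        lasers = [LASER_OFF]
        if kind in config.laser_kinds:
            lasers.append(LASER_ON)
        for laser in lasers:
            for snr in (None, *config.snr_grid_db):
                combos.append((kind, snr, laser))
    return combos


def build_schedule(config: ScheduleConfig | None = None, seed: int = 0) -> StimulusSchedule:
    """Block-interleaved schedule: per cycle, five masking blocks then one
    FRA block; every block holds one repeat of each combination in a seeded
    random order.  Defaults yield 30 repeats per masker/signal combination
    and 6 repeats per FRA frequency/level combination.
    """
    config = config or ScheduleConfig()
    combos = _masking_combos(config)
    if not combos:
        raise ValueError("empty condition set")
    grid = build_fra_grid()
    fra_combos = [(f, l) for f in grid.freqs for l in grid.levels]

    root = np.random.default_rng(seed)
    trials: list[TrialCondition] = []
    clock = 0.0

    for _ in range(config.n_cycles):
        for _ in range(config.masking_blocks_per_cycle):
            order = root.permutation(len(combos))
            for idx in order:
                kind, snr, laser = combos[idx]
                masker = build_masker(kind, root)  # IM phases re-drawn per trial
                signal = build_signal(snr, masker)
                trials.append(
                    TrialCondition(masker=masker, signal=signal, laser=laser, trial_onset=clock)
                )
                clock += tl.TRIAL_S + config.isi_masking_s
        if config.include_fra:
            order = root.permutation(len(fra_combos))
            for idx in order:
                trials.append(TrialCondition(fra_tone=fra_combos[idx], trial_onset=clock))
                clock += tl.FRA_TRIAL_S + config.isi_fra_s
    return StimulusSchedule(trials=trials, seed=seed)


# ---------------------------------------------------------------------------
# waveform rendering (optional audio export)
# ---------------------------------------------------------------------------

def render_waveform(condition: TrialCondition, sample_rate: float) -> np.ndarray:
    """Render a trial's stimulus to mono samples (sum of SAM tone components).

    Levels are relative amplitudes with the 65 dB SPL masker band as the
    0 dB reference.  Intended for inspection/export, not calibration.
    """
    if condition.fra_tone is not None:
        f, level = condition.fra_tone
        top = f
    else:
        top = max(b.center_freq for b in condition.masker.bands)
        if condition.signal is not None:
            top = max(top, condition.signal.carrier_freq)
    if sample_rate < 4 * top:
        raise ValueError(f"sample_rate {sample_rate} < 4x highest component {top}")

    n = int(round(condition.duration * sample_rate))
    t = np.arange(n) / sample_rate   # trial-aligned
    out = np.zeros(n)

    if condition.fra_tone is not None:
        f, level = condition.fra_tone
        amp = 10 ** ((level - MASKER_LEVEL_DBSPL) / 20.0)
        on = (t >= tl.FRA_TONE_ONSET_S) & (t < tl.FRA_TONE_ONSET_S + tl.FRA_TONE_DUR_S)
        out[on] = amp * np.sin(2 * np.pi * f * t[on])
        return out

    masker = condition.masker
    t_stim = t - tl.BASELINE_S
    for i, band in enumerate(masker.bands):
        env = envelope_value(masker, i, t_stim)
        out += env * np.sin(2 * np.pi * band.center_freq * t)

    if condition.signal is not None:
        sig = condition.signal
        amp = 10 ** (sig.snr_db / 20.0)
        for onset in sig.pip_onsets:
            in_pip = (t >= onset) & (t < onset + sig.pip_s)
            tp = t[in_pip] - onset
            pip_env = np.sin(np.pi * tp / sig.pip_s)  # half-sine fills the trough
            out[in_pip] += amp * pip_env * np.sin(2 * np.pi * sig.carrier_freq * t[in_pip])
    return out
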
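"""Trial timeline constants shared across the pipeline.

All analysis operates in *trial-aligned* ("session") time: a trial starts
with a silent baseline, the stimulus occupies one second, and a short
post-stimulus tail follows.  The masker portion is anchored at a fixed
session time for every masker kind, so that analysis windows (first tone
pip, noise onset, laser window) line up across conditions.

Masking trial layout (seconds, trial-aligned):

    0.0            baseline starts (silence)
    0.5            stimulus time zero; noise onset for precursor-bearing
                   maskers; laser onset when the laser is used
    0.5 - 0.9      precursor (400 ms, long maskers only)
    0.9 - 1.0      gap (100 ms, long maskers only)
    1.0 - 1.5      masker portion (500 ms, all kinds)
    1.175/1.275/1.375  signal pip onsets (pips centred on envelope troughs
                   3, 4 and 5 of the masker portion)
    2.0            trial end

FRA trial layout:

    0.0 - 0.25     baseline
    0.25 - 0.75    pure tone (500 ms)
    1.0            trial end
"""

from __future__ import annotations

# -- masking trials ---------------------------------------------------------
BASELINE_S = 0.5        # silent pre-stimulus baseline
STIM_S = 1.0            # stimulus span (precursor + gap + masker)
POST_S = 0.5
TRIAL_S = BASELINE_S + STIM_S + POST_S   # 2.0 s

MASKER_ONSET_S = 1.0    # masker portion onset, trial-aligned
MASKER_DUR_S = 0.5
PRECURSOR_DUR_S = 0.4
GAP_DUR_S = 0.1

MODULATOR_HZ = 10.0
MOD_PERIOD_S = 1.0 / MODULATOR_HZ

# three 50 ms pips centred on troughs 3, 4, 5 of the masker portion
# (trough 1 = envelope minimum at masker onset)
PIP_DUR_S = 0.05
PIP_ONSETS_S = (1.175, 1.275, 1.375)
PIP1_WINDOW = (1.175, 1.275)    # first-pip analysis window

LASER_ONSET_S = 0.5     # laser covers the first 150 ms of stimulus time
LASER_DUR_S = 0.15
LASER_WINDOW = (0.5, 0.65)

ONSET_WINDOW_S = 0.075  # noise-onset analysis window length (0-75 ms)

PSTH_BIN_S = 0.005      # 5 ms bins everywhere

# -- FRA trials -------------------------------------------------------------
FRA_TONE_ONSET_S = 0.25
FRA_TONE_DUR_S = 0.5
FRA_TRIAL_S = 1.0


def noise_onset_s(has_precursor: bool) -> float:
    """Trial-aligned onset of the first acoustic energy of a masker."""
    if has_precursor:
        return MASKER_ONSET_S - GAP_DUR_S - PRECURSOR_DUR_S
    return MASKER_ONSET_S


def onset_window(has_precursor: bool) -> tuple[float, float]:
    """Noise-onset window [t0, t0 + 75 ms), trial-aligned."""
    t0 = noise_onset_s(has_precursor)
    return (t0, t0 + ONSET_WINDOW_S)
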
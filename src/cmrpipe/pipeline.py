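"""End-to-end orchestration: simulate -> analyze -> report.

`analyze_dataset` is the vectorized driver that runs the whole statistics
chain (PSTHs, sigma, SR functions, bootstrap responsiveness screen,
neurometric thresholds, masking release, AFI) over a full spikes/trials
dataset.  It computes exactly what the per-cell operations in
:mod:`cmrpipe.sr`, :mod:`cmrpipe.neurometrics` and :mod:`cmrpipe.afi`
define, but batched over (cell, condition) for speed; equivalence is
covered by the oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import timeline as tl
from .neurometrics import NeurometricFunction, neurometric_threshold, population_proportion
from .population import (NeuronParams, PopulationConfig, generate_trials,
                         sample_population, truth_frame, SimulatedDataset)
from .sr import (SR_CRITERION_SD, first_crossing, masking_release, upsample)
from .stimuli import (LASER_OFF, LASER_ON, SIGNAL_FREQ_HZ, ScheduleConfig,
                      build_schedule, family_key)

#: tuned-cell band: |log2(cf / 20 kHz)| <= 0.42 octaves (~15.0-26.8 kHz grid
#: interval reproducing the 15-23 kHz selection on the 1/8-octave CF grid)
TUNED_BAND_OCT = 0.42


def tuned_mask(cfs: np.ndarray, band_oct: float = TUNED_BAND_OCT) -> np.ndarray:
    cfs = np.asarray(cfs, dtype=float)
    out = np.zeros(cfs.shape, dtype=bool)
    ok = np.isfinite(cfs) & (cfs > 0)
    out[ok] = np.abs(np.log2(cfs[ok] / SIGNAL_FREQ_HZ)) <= band_oct
    return out


@dataclass
class AnalysisResult:
    """Everything the report stage needs, in array form."""

    cell_ids: np.ndarray                  # (n_cells,) after sigma screen
    families: list[str]
    snrs_db: np.ndarray
    sigma: np.ndarray                     # (n_cells,)
    sr_values: np.ndarray                 # (n_cells, n_fam, n_snr), SD units
    cell_thresholds: np.ndarray           # (n_cells, n_fam), 0.5 SD SR crossing, NaN if none
    cell_rate_thresholds: np.ndarray      # (n_cells, n_fam), >=25% rate-change crossing
    votes: np.ndarray                     # (n_cells, n_fam, n_snr)
    responsive_any: np.ndarray            # (n_cells,) bool
    responsive_fam: np.ndarray            # (n_cells, n_fam) bool
    tuned: np.ndarray                     # (n_cells,) bool
    onset_counts: dict                    # kind -> (n_cells,) mean onset count
    neurometric: dict                     # selection label -> {family: NeurometricFunction}
    population_sr: dict                   # selection label -> {family: (grid, values, threshold)}
    cfs: np.ndarray


def _pip_bins(n_bins: int, bin_s: float) -> slice:
    lo = int(round(tl.PIP1_WINDOW[0] / bin_s))
    hi = int(round(tl.PIP1_WINDOW[1] / bin_s))
    return slice(lo, min(hi, n_bins))


def analyze_dataset(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    cfs_by_cell: Mapping | None = None,
    screen: bool = True,
    n_boot: int = 500,
    seed: int = 0,
    bin_s: float = tl.PSTH_BIN_S,
) -> AnalysisResult:
    """Run the complete masking analysis over a dataset.

    ``cfs_by_cell`` maps cell_id -> characteristic frequency (from the FRA
    stage or from simulation ground truth); cells without a CF are treated
    as untuned.  ``screen=False`` skips the bootstrap responsiveness screen
    (all cells responsive), which is useful for small fixtures.
    """
    rng = np.random.default_rng(seed)
    mask_trials = trials[trials["masker_kind"].notna()].copy()
    if mask_trials.empty:
        raise ValueError("no masking trials in dataset")

    fam_of_trial = [family_key(k, l) for k, l in
                    zip(mask_trials["masker_kind"], mask_trials["laser"])]
    mask_trials["family"] = fam_of_trial
    families = sorted(set(fam_of_trial))
    snrs = np.array(sorted(mask_trials["snr_db"].dropna().unique()), dtype=float)
    n_fam, n_snr = len(families), len(snrs)
    n_cond = n_fam * (n_snr + 1)          # slot 0 of each family = noise-alone

    fam_idx = {f: i for i, f in enumerate(families)}
    snr_idx = {s: k + 1 for k, s in enumerate(snrs)}
    cond_of_trial = np.array(
        [fam_idx[f] * (n_snr + 1)
         + (0 if np.isnan(s) else snr_idx[float(s)])
         for f, s in zip(mask_trials["family"], mask_trials["snr_db"])],
        dtype=np.int64)
    trial_ids = mask_trials["trial_id"].to_numpy()
    n_trials_per_cond = np.bincount(cond_of_trial, minlength=n_cond)
    if (n_trials_per_cond == 0).any():
        raise ValueError("every family/SNR combination needs at least one trial")

    # trial-within-condition index, for per-trial window count matrices
    order = np.argsort(cond_of_trial, kind="stable")
    within = np.empty(len(cond_of_trial), dtype=np.int64)
    within[order] = np.arange(len(cond_of_trial)) - np.repeat(
        np.concatenate([[0], np.cumsum(n_trials_per_cond)[:-1]]), n_trials_per_cond)
    max_tr = int(n_trials_per_cond.max())

    cell_ids = np.unique(np.asarray(spikes["cell_id"]))
    n_cells = len(cell_ids)

    # numpy joins (id -> index) instead of pandas maps, for speed at scale
    tid_perm = np.argsort(trial_ids, kind="stable")
    tid_sorted = trial_ids[tid_perm]
    spk_tid = spikes["trial_id"].to_numpy()
    pos = np.clip(np.searchsorted(tid_sorted, spk_tid), 0, len(tid_sorted) - 1)
    is_mask_spk = tid_sorted[pos] == spk_tid
    trial_row = tid_perm[pos[is_mask_spk]]

    sc = np.searchsorted(cell_ids, np.asarray(spikes["cell_id"])[is_mask_spk])
    scond = cond_of_trial[trial_row]
    swithin = within[trial_row]
    st = spikes["spike_time_s"].to_numpy(dtype=float)[is_mask_spk]

    # PSTH tensor (n_cells, n_cond, n_bins)
    n_bins = int(round(tl.TRIAL_S / bin_s))
    sbin = np.floor(st / bin_s).astype(np.int64)
    ok = (sbin >= 0) & (sbin < n_bins)
    flatidx = (sc[ok] * n_cond + scond[ok]) * n_bins + sbin[ok]
    counts = np.bincount(flatidx, minlength=n_cells * n_cond * n_bins)
    psth = counts.reshape(n_cells, n_cond, n_bins).astype(float)
    psth /= (n_trials_per_cond[None, :, None] * bin_s)

    # sigma over all masking PSTH bins; drop zero-variance cells
    sigma = psth.reshape(n_cells, -1).std(axis=1)
    keep = sigma > 0
    cell_ids, sigma, psth = cell_ids[keep], sigma[keep], psth[keep]
    kept_idx = {c: i for i, c in enumerate(cell_ids)}
    n_cells = len(cell_ids)
    if n_cells == 0:
        raise ValueError("no cells with nonzero rate variance")

    # SR values: pip-window mean of (Sig - N)/sigma
    psth4 = psth.reshape(n_cells, n_fam, n_snr + 1, n_bins)
    pips = _pip_bins(n_bins, bin_s)
    sig_pip = psth4[:, :, 1:, pips].mean(axis=3)
    noise_pip = psth4[:, :, 0, pips].mean(axis=2)
    sr_values = (sig_pip - noise_pip[:, :, None]) / sigma[:, None, None]

    # per-cell thresholds (0.5 SD first crossing of the upsampled function)
    cell_thresholds = np.full((n_cells, n_fam), np.nan)
    for i in range(n_cells):
        for j in range(n_fam):
            grid, gv = upsample(snrs, sr_values[i, j])
            thr = first_crossing(grid, gv, SR_CRITERION_SD)
            if thr is not None:
                cell_thresholds[i, j] = thr

    # per-trial spike counts in the pip window, per (cell, cond)
    keep_spk = ok & keep[sc]
    remap = np.full(keep.size, -1, dtype=np.int64)
    remap[np.nonzero(keep)[0]] = np.arange(n_cells)
    w0, w1 = tl.PIP1_WINDOW
    in_pip = keep_spk & (st >= w0) & (st < w1)
    tflat = ((remap[sc[in_pip]] * n_cond + scond[in_pip]) * max_tr
             + swithin[in_pip])
    trial_counts = np.bincount(
        tflat, minlength=n_cells * n_cond * max_tr
    ).reshape(n_cells, n_cond, max_tr).astype(float)
    # entries beyond a condition's trial count stay zero and are masked below

    win_len = w1 - w0
    mean_counts = trial_counts.sum(axis=2) / n_trials_per_cond[None, :]
    mean_rates = mean_counts / win_len                     # (n_cells, n_cond)
    rates4 = mean_rates.reshape(n_cells, n_fam, n_snr + 1)

    # votes: +-25% relative change vs the family's own noise-alone rate
    rs = rates4[:, :, 1:]
    rn = rates4[:, :, 0][:, :, None]
    votes = np.full(rs.shape, 0.5)
    votes[rs >= 1.25 * rn] = 1.0
    votes[rs <= 0.75 * rn] = 0.0
    votes[(rn == 0) & (rs > 0)] = 1.0
    votes[(rn == 0) & (rs == 0)] = 0.5

    # per-cell condition thresholds from mean firing-rate changes: first
    # upsampled SNR where the rate change reaches +25% (the vote criterion)
    cell_rate_thresholds = np.full((n_cells, n_fam), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rn > 0, rs / np.where(rn > 0, rn, 1.0), np.inf)
    for i in range(n_cells):
        for j in range(n_fam):
            vals = ratio[i, j]
            if not np.all(np.isfinite(vals)):
                continue
            grid, gv = upsample(snrs, vals)
            thr = first_crossing(grid, gv, 1.25)
            if thr is not None:
                cell_rate_thresholds[i, j] = thr

    # bootstrap responsiveness screen (signal+noise vs noise-alone, pooled).
    # Resampling weights are shared across cells (each cell's marginal null
    # is unchanged; draws are data-independent), which turns the per-cell
    # bootstrap into one matrix product per combination.
    responsive_fam = np.zeros((n_cells, n_fam), dtype=bool)
    if screen:
        for j in range(n_fam):
            c0 = j * (n_snr + 1)
            n0 = int(n_trials_per_cond[c0])
            pool_noise = trial_counts[:, c0, :n0]
            for k in range(n_snr):
                ck = c0 + 1 + k
                n1 = int(n_trials_per_cond[ck])
                sig_counts = trial_counts[:, ck, :n1]
                pooled = np.concatenate([pool_noise, sig_counts], axis=1)
                n_pool = n0 + n1
                ib = rng.integers(0, n_pool, size=(n_boot, n1))
                ia = rng.integers(0, n_pool, size=(n_boot, n0))
                w = np.zeros((n_boot, n_pool))
                np.add.at(w, (np.repeat(np.arange(n_boot), n1), ib.ravel()), 1.0 / n1)
                np.add.at(w, (np.repeat(np.arange(n_boot), n0), ia.ravel()), -1.0 / n0)
                null_diff = pooled @ w.T                  # (n_cells, n_boot)
                q95 = np.percentile(null_diff, 95.0, axis=1)
                obs = sig_counts.mean(axis=1) - pool_noise.mean(axis=1)
                responsive_fam[:, j] |= obs > q95
    else:
        responsive_fam[:] = True
    responsive_any = responsive_fam.any(axis=1)

    # CF / tuned-cell selection
    cfs = np.full(n_cells, np.nan)
    if cfs_by_cell is not None:
        for c, f in cfs_by_cell.items():
            if c in kept_idx and f is not None:
                cfs[kept_idx[c]] = f
    tuned = tuned_mask(cfs)

    # onset counts for AFI (noise-alone, laser-off families only)
    onset_counts: dict[str, np.ndarray] = {}
    kinds_present = [f for f in families if not f.endswith("_laser")]
    for kind in kinds_present:
        t0, t1 = tl.onset_window(kind != "CM_short")
        c0 = fam_idx[kind] * (n_snr + 1)
        in_on = keep_spk & (scond == c0) & (st >= t0) & (st < t1)
        cnt = np.bincount(remap[sc[in_on]], minlength=n_cells).astype(float)
        onset_counts[kind] = cnt / n_trials_per_cond[c0]

    # neurometric functions per selection set
    selections = {
        "all_responsive": responsive_any,
        "tuned_responsive": responsive_any & tuned,
    }
    if "CM_long" in fam_idx:
        cm_resp = responsive_fam[:, fam_idx["CM_long"]]
        selections["tuned_cm_responsive"] = cm_resp & tuned

    neurometric: dict[str, dict] = {}
    population_sr: dict[str, dict] = {}
    for label, sel_mask in selections.items():
        if not sel_mask.any():
            continue
        neurometric[label] = {}
        population_sr[label] = {}
        for j, fam in enumerate(families):
            fn = population_proportion(votes[sel_mask, j, :], snrs, family=fam)
            neurometric_threshold(fn, m_tests=n_snr)
            neurometric[label][fam] = fn
            mean_sr = sr_values[sel_mask, j, :].mean(axis=0)
            grid, gv = upsample(snrs, mean_sr)
            population_sr[label][fam] = {
                "snrs_db": snrs.tolist(),
                "values": mean_sr.tolist(),
                "threshold_db": first_crossing(grid, gv, SR_CRITERION_SD),
            }

    return AnalysisResult(
        cell_ids=cell_ids, families=families, snrs_db=snrs, sigma=sigma,
        sr_values=sr_values, cell_thresholds=cell_thresholds,
        cell_rate_thresholds=cell_rate_thresholds, votes=votes,
        responsive_any=responsive_any, responsive_fam=responsive_fam,
        tuned=tuned, onset_counts=onset_counts, neurometric=neurometric,
        population_sr=population_sr, cfs=cfs)


# ---------------------------------------------------------------------------
# AFI from an AnalysisResult
# ---------------------------------------------------------------------------

def afi_from_result(res: AnalysisResult) -> pd.DataFrame:
    """Per-cell AFI values and masking release.

    Masking release uses the per-cell firing-rate-change thresholds (the
    +25% criterion crossing), matching how the votes are derived; cells
    lacking a threshold in either condition get NaN.
    """
    from .afi import normalize_counts

    kinds = list(res.onset_counts)
    rows = []
    fam_idx = {f: i for i, f in enumerate(res.families)}
    for i, cell in enumerate(res.cell_ids):
        counts = {k: float(res.onset_counts[k][i]) for k in kinds}
        norm = normalize_counts(counts)
        thr_nb = (res.cell_rate_thresholds[i, fam_idx["NB"]]
                  if "NB" in fam_idx else np.nan)
        row = {"cell_id": cell, "cf_hz": res.cfs[i]}
        for broad, col in (("CM_long", "afi_cm"), ("IM", "afi_im")):
            if broad in norm and "NB" in norm:
                row[col] = norm[broad] - norm["NB"]
            else:
                row[col] = np.nan
        for broad, col in (("CM_long", "mr_cm"), ("IM", "mr_im")):
            if broad in fam_idx:
                thr_b = res.cell_rate_thresholds[i, fam_idx[broad]]
                row[col] = masking_release(
                    None if np.isnan(thr_nb) else thr_nb,
                    None if np.isnan(thr_b) else thr_b)
            else:
                row[col] = None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    screen: bool = True
    n_boot: int = 500

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        sched = ScheduleConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in d.get("schedule", {}).items()})
        pop = PopulationConfig(**{k: tuple(v) if isinstance(v, list) and k.endswith("_hz")
                                  else v for k, v in d.get("population", {}).items()})
        return cls(schedule=sched, population=pop,
                   screen=d.get("screen", True), n_boot=d.get("n_boot", 500))


def simulate_experiment(config: ExperimentConfig, seed: int) -> SimulatedDataset:
    """Build the schedule, sample a population and generate spikes.

    A single master seed fans out to independent per-stage streams.
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_pop, s_spk = ss.spawn(3)
    schedule = build_schedule(config.schedule, seed=int(s_sched.generate_state(1)[0]))
    pop_cfg = config.population
    pop_cfg.seed = int(s_pop.generate_state(1)[0])
    population = sample_population(pop_cfg)
    return generate_trials(population, schedule,
                           seed=int(s_spk.generate_state(1)[0]))


def run_experiment(config: ExperimentConfig, seed: int,
                   out_dir: str | Path | None = None) -> dict:
    """Full pipeline on simulated data; returns (and optionally writes) the report."""
    ss = np.random.SeedSequence(seed)
    _, _, _, s_an = ss.spawn(4)
    ds = simulate_experiment(config, seed)
    cf_map = {p.cell_id: p.cf for p in ds.truth}
    res = analyze_dataset(ds.spikes, ds.trials, cfs_by_cell=cf_map,
                          screen=config.screen, n_boot=config.n_boot,
                          seed=int(s_an.generate_state(1)[0]))
    afi_df = afi_from_result(res)
    battery = run_test_battery(res, afi_df)

    thresholds = {
        label: {fam: fn.threshold_db for fam, fn in fns.items()}
        for label, fns in res.neurometric.items()
    }
    contrasts = {}
    label = ("tuned_responsive" if "tuned_responsive" in thresholds
             else "all_responsive")
    thr = thresholds.get(label, {})
    thr_cm = thresholds.get("tuned_cm_responsive", thr)
    pairs = [("NB", "IM", thr), ("NB", "CM_long", thr),
             ("CM_short", "CM_long", thr_cm),
             ("CM_long_laser", "CM_long", thr_cm),
             ("CM_short_laser", "CM_short", thr_cm)]
    for a, b, table in pairs:
        if a in table and b in table:
            contrasts[f"{a}_vs_{b}_db"] = masking_release(table[a], table[b])

    report = {
        "seed": seed,
        "n_cells": int(len(res.cell_ids)),
        "n_responsive": int(res.responsive_any.sum()),
        "n_tuned": int(res.tuned.sum()),
        "families": res.families,
        "snrs_db": res.snrs_db.tolist(),
        "neurometric_thresholds_db": thresholds,
        "masking_release_db": contrasts,
        "population_sr": res.population_sr,
        "mean_afi": {
            "cm": _nanmean_or_none(afi_df.get("afi_cm")),
            "im": _nanmean_or_none(afi_df.get("afi_im")),
        },
        "test_battery": battery,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_jsonable))
        afi_df.to_csv(out_dir / "afi.csv", index=False)
        pd.DataFrame({
            "cell_id": res.cell_ids, "cf_hz": res.cfs, "sigma": res.sigma,
            **{f"threshold_{f}_db": res.cell_thresholds[:, j]
               for j, f in enumerate(res.families)},
        }).to_csv(out_dir / "cell_thresholds.csv", index=False)
    return report


def _nanmean_or_none(series) -> float | None:
    if series is None:
        return None
    vals = series.dropna()
    return float(vals.mean()) if len(vals) else None


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# standard-test battery
# ---------------------------------------------------------------------------

def run_test_battery(res: AnalysisResult, afi_df: pd.DataFrame) -> dict:
    """Apply the named off-the-shelf tests to the standard comparisons.

    All tests come from scipy; nothing here is bespoke.  Returns
    statistic/p-value pairs keyed by comparison.
    """
    out: dict[str, dict] = {}
    fam_idx = {f: j for j, f in enumerate(res.families)}
    sel = res.responsive_any & res.tuned
    if not sel.any():
        sel = res.responsive_any

    trio = [f for f in ("NB", "IM", "CM_long") if f in fam_idx]
    if len(trio) == 3 and sel.sum() >= 3:
        samples = [res.sr_values[sel, fam_idx[f], :].mean(axis=1) for f in trio]
        stat, p = stats.friedmanchisquare(*samples)
        out["friedman_sr_nb_im_cm"] = {"statistic": float(stat), "dof": 2, "p": float(p)}
        for a, b in (("NB", "IM"), ("CM_long", "NB"), ("CM_long", "IM")):
            xa = res.sr_values[sel, fam_idx[a], :].mean(axis=1)
            xb = res.sr_values[sel, fam_idx[b], :].mean(axis=1)
            if np.allclose(xa, xb):
                out[f"wilcoxon_sr_{a}_vs_{b}"] = {"statistic": None, "p": 1.0}
            else:
                w = stats.wilcoxon(xa, xb)
                out[f"wilcoxon_sr_{a}_vs_{b}"] = {
                    "statistic": float(w.statistic), "p": float(w.pvalue)}

    if {"NB", "CM_long"} <= set(res.onset_counts) and sel.sum() >= 5:
        diff = res.onset_counts["CM_long"][sel] - res.onset_counts["NB"][sel]
        nz = diff[diff != 0]
        if nz.size:
            bt = stats.binomtest(int((nz > 0).sum()), nz.size, 0.5)
            out["sign_onset_cm_vs_nb"] = {"n": int(nz.size), "p": float(bt.pvalue)}

    if {"afi_cm", "afi_im"} <= set(afi_df.columns):
        a_cm = afi_df["afi_cm"].dropna().to_numpy()
        a_im = afi_df["afi_im"].dropna().to_numpy()
        if a_cm.size >= 5 and a_im.size >= 5:
            ks = stats.ks_2samp(a_cm, a_im)
            out["ks_afi_cm_vs_im"] = {"statistic": float(ks.statistic),
                                      "p": float(ks.pvalue)}
    for col_a, col_m, name in (("afi_cm", "mr_cm", "pearson_afi_mr_cm"),
                               ("afi_im", "mr_im", "pearson_afi_mr_im")):
        if {col_a, col_m} <= set(afi_df.columns):
            sub = afi_df[[col_a, col_m]].dropna()
            if len(sub) >= 3 and sub[col_a].nunique() > 1 and sub[col_m].nunique() > 1:
                r, p = stats.pearsonr(sub[col_a], sub[col_m])
                out[name] = {"r": float(r), "p": float(p), "n": int(len(sub))}
    return out
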
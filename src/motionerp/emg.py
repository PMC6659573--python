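"""EMG onset detection and trial-level behavioral measures.

Onset detection follows the threshold tradition for surface EMG: the signal
is rectified, 50 Hz low-pass filtered, smoothed with a 25 ms moving
average, and the onset is the first post-stimulus time at which this
envelope exceeds the baseline mean by three baseline standard deviations
and stays above threshold for a minimum hold time.

Two deliberate refinements over the bare threshold rule (both documented in
the methods note):

* The detection path is strictly causal (one-pass filter, trailing moving
  average).  Symmetric (zero-phase/centered) smoothing spreads the burst
  backward in time, so a near-baseline threshold is crossed systematically
  *before* the true onset -- and the earlier the higher the burst SNR.  A
  causal path makes the raw crossing time a small, positive, bounded delay
  instead.
* The raw crossing is then bias-corrected with the processing chain's own
  step response: for an envelope step of measured height, the crossing
  delay of the causal chain is a deterministic, computable constant, so the
  detector subtracts it.  On an ideal step the corrected onset is exact to
  about a sample; on stochastic bursts the residual error is zero-mean with
  a few-ms spread.

The visuomotor reaction time (VMRT) is button press minus stimulus onset;
motor time is VMRT minus EMG onset, identically, for every trial on which
both are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateBaselineError, MotionErpError, QualityError

EXCLUSION_REASONS = (
    "no_onset", "onset_lt_100", "vmrt_range", "vmrt_outlier",
    "motor_outlier", "eeg_artifact", "blink",
)


@dataclass(frozen=True)
class OnsetParams:
    """EMG onset detector parameters.

    lowpass_hz : envelope low-pass cutoff (Hz).
    smooth_window_ms : moving-average window (ms), trailing alignment.
    k_sd : threshold in baseline standard deviations above the baseline mean.
    baseline_window : (start, stop) ms of the pre-stimulus baseline.
    min_hold_ms : minimum time the envelope must stay above threshold;
        replaces a manual visual check with an objective persistence rule.
    """

    lowpass_hz: float = 50.0
    smooth_window_ms: float = 25.0
    k_sd: float = 3.0
    baseline_window: tuple = (-500.0, 0.0)
    min_hold_ms: float = 10.0

    def __post_init__(self):
        for name in ("lowpass_hz", "smooth_window_ms", "k_sd", "min_hold_ms"):
            if getattr(self, name) <= 0:
                raise MotionErpError(f"{name} must be positive")


@dataclass
class TrialRecord:
    """Per-trial behavioral measurements and inclusion bookkeeping."""

    trial_id: int
    condition: str
    stimulus_sample: int
    emg_onset_ms: float | None = None
    button_press_ms: float | None = None
    vmrt_ms: float | None = None
    motor_time_ms: float | None = None
    exclusion_reasons: list = field(default_factory=list)

    @property
    def include(self) -> bool:
        return not self.exclusion_reasons

    def exclude(self, reason: str):
        if reason not in EXCLUSION_REASONS:
            raise MotionErpError(f"unknown exclusion reason {reason!r}")
        if reason not in self.exclusion_reasons:
            self.exclusion_reasons.append(reason)


def trials_to_frame(trials) -> pd.DataFrame:
    """One row per trial, all flags explicit (TSV-friendly)."""
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition,
                "stimulus_sample": t.stimulus_sample,
                "emg_onset_ms": t.emg_onset_ms,
                "button_press_ms": t.button_press_ms,
                "vmrt_ms": t.vmrt_ms,
                "motor_time_ms": t.motor_time_ms,
                "include": t.include,
                "exclusion_reasons": ";".join(t.exclusion_reasons),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Onset detection
# --------------------------------------------------------------------------

def _envelope(x: np.ndarray, srate: float, params: OnsetParams) -> tuple[np.ndarray, np.ndarray]:
    """Causal rectify -> low-pass -> trailing moving average.

    Returns ``(filtered, smoothed)``: the rectified low-passed signal and
    its trailing moving average.  The smoothed trace is the detection
    signal; the threshold statistics come from the filtered (pre-average)
    baseline, whose variance is not yet collapsed by the smoother --
    thresholding the heavily smoothed envelope at 3 of its *own* baseline
    SDs would sit so close to the baseline mean that noise excursions cross
    it constantly.
    """
    sos = signal.butter(4, params.lowpass_hz, btype="low", fs=srate, output="sos")
    filt = signal.sosfilt(sos, np.abs(x))
    w = max(1, int(round(params.smooth_window_ms * srate / 1000.0)))
    kernel = np.ones(w) / w
    # trailing window: output[i] = mean(filt[i-w+1 .. i])
    return filt, signal.lfilter(kernel, [1.0], filt)


@lru_cache(maxsize=8)
def _step_response(srate: float, params: OnsetParams) -> np.ndarray:
    n = int(srate)  # 1 s of step response is ample
    return _envelope(np.ones(n), srate, params)[1]


def _step_crossing_delay(ratio: float, srate: float, params: OnsetParams) -> float:
    """Delay (ms) at which the causal chain's unit-step response reaches
    ``ratio``; the deterministic crossing bias for an ideal envelope step."""
    resp = np.clip(_step_response(srate, params), 0.0, None)
    idx = np.nonzero(resp >= ratio)[0]
    if idx.size == 0:
        return 0.0
    i = idx[0]
    if i == 0:
        return 0.0
    # linear interpolation between samples for sub-ms resolution
    f = (ratio - resp[i - 1]) / max(resp[i] - resp[i - 1], 1e-300)
    return (i - 1 + f) * 1000.0 / srate


def detect_emg_onset(
    emg_epoch: np.ndarray,
    srate: float,
    params: OnsetParams | None = None,
    window=(-500.0, 1000.0),
) -> float | None:
    """Detect the EMG onset in a single stimulus-locked epoch.

    Parameters
    ----------
    emg_epoch : 1-D array covering ``window`` (ms relative to stimulus).
    srate : sampling rate (Hz).

    Returns
    -------
    Onset in ms post-stimulus, or None when the envelope never exceeds the
    threshold for the minimum hold time.  Raises
    :class:`DegenerateBaselineError` when the baseline has zero variance.
    """
    params = params or OnsetParams()
    emg_epoch = np.asarray(emg_epoch, dtype=float)
    n = emg_epoch.size
    t0 = int(round(-window[0] * srate / 1000.0))  # index of stimulus onset
    filt, env = _envelope(emg_epoch, srate, params)

    b0 = t0 + int(round(params.baseline_window[0] * srate / 1000.0))
    b1 = t0 + int(round(params.baseline_window[1] * srate / 1000.0))
    # skip the causal filter's settling transient at the epoch start
    settle = int(round(2 * params.smooth_window_ms * srate / 1000.0))
    base = filt[max(b0, settle):b1]
    if base.size < 10:
        raise MotionErpError("baseline window too short for onset detection")
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    if sd == 0.0:
        raise DegenerateBaselineError(
            "flat EMG baseline: the 3-SD threshold is undefined"
        )
    thr = mu + params.k_sd * sd

    hold = max(1, int(round(params.min_hold_ms * srate / 1000.0)))
    above = env[t0:] >= thr
    if not above.any():
        return None
    # first run of >= hold consecutive supra-threshold samples
    runs = np.diff(np.r_[0, above.astype(int), 0])
    starts, ends = np.nonzero(runs == 1)[0], np.nonzero(runs == -1)[0]
    cross = None
    for s, e in zip(starts, ends):
        if e - s >= hold:
            cross = s
            break
    if cross is None:
        return None
    t_cross = cross * 1000.0 / srate

    # model-based bias correction: estimate the burst plateau shortly after
    # the crossing and subtract the chain's step-response crossing delay
    i_c = t0 + cross
    plateau = env[i_c + int(0.010 * srate): i_c + int(0.060 * srate)]
    if plateau.size and plateau.mean() > thr:
        ratio = (thr - mu) / (plateau.mean() - mu)
        t_cross -= _step_crossing_delay(ratio, srate, params)
    return max(t_cross, 0.0)


# --------------------------------------------------------------------------
# Trial-level measures and filters
# --------------------------------------------------------------------------

def compute_vmrt(trials, recording_events, srate: float = 1000.0):
    """Fill VMRT (button press minus stimulus, ms) and motor time.

    The first button press after the stimulus and before the next stimulus
    counts; trials without a press get no VMRT and are excluded downstream.
    """
    stims = recording_events.stimuli()
    presses = [e.sample for e in recording_events.responses()]
    stim_samples = [e.sample for e in stims]
    out = []
    for t in trials:
        t = replace(t, exclusion_reasons=list(t.exclusion_reasons))
        i = stim_samples.index(t.stimulus_sample)
        nxt = stim_samples[i + 1] if i + 1 < len(stim_samples) else np.inf
        cand = [p for p in presses if t.stimulus_sample < p < nxt]
        if cand:
            t.button_press_ms = (cand[0] - t.stimulus_sample) * 1000.0 / srate
            t.vmrt_ms = t.button_press_ms
            if t.emg_onset_ms is not None:
                t.motor_time_ms = t.vmrt_ms - t.emg_onset_ms
        out.append(t)
    return out


def apply_onset_exclusion(trials, min_onset_ms: float = 100.0):
    """Flag trials with no EMG onset, or an onset earlier than 100 ms after
    the stimulus (too fast to be stimulus-driven)."""
    out = []
    for t in trials:
        t = replace(t, exclusion_reasons=list(t.exclusion_reasons))
        if t.emg_onset_ms is None:
            t.exclude("no_onset")
        elif t.emg_onset_ms < min_onset_ms:
            t.exclude("onset_lt_100")
        out.append(t)
    return out


def apply_behavioral_filters(
    trials,
    vmrt_range=(100.0, 500.0),
    z_thresh: float = 3.0,
    min_trials: int = 5,
):
    """Range-filter VMRT, then flag |z| > 3 outliers of VMRT and motor time.

    The range filter runs first; the mean/SD for the z-scores are then
    computed per condition on the surviving trials only, in a single pass
    (no iteration).  Trials keep their measured values when excluded.  A
    zero SD (all values equal) yields no outlier flags.
    """
    out = [replace(t, exclusion_reasons=list(t.exclusion_reasons)) for t in trials]
    for t in out:
        if t.vmrt_ms is None:
            if "no_onset" not in t.exclusion_reasons:
                t.exclude("vmrt_range")
        elif not (vmrt_range[0] <= t.vmrt_ms <= vmrt_range[1]):
            t.exclude("vmrt_range")

    for cond in sorted({t.condition for t in out}):
        surv = [t for t in out if t.condition == cond and t.include]
        if len(surv) < min_trials:
            raise QualityError(
                f"insufficient trials ({len(surv)}) in condition {cond!r} "
                f"after range filtering"
            )
        for attr, reason in (("vmrt_ms", "vmrt_outlier"),
                             ("motor_time_ms", "motor_outlier")):
            vals = np.array([getattr(t, attr) for t in surv
                             if getattr(t, attr) is not None])
            if vals.size < min_trials:
                continue
            mu, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0:
                continue
            for t in surv:
                v = getattr(t, attr)
                if v is not None and abs(v - mu) > z_thresh * sd:
                    t.exclude(reason)
    return out


def condition_summary(trials) -> pd.DataFrame:
    """Mean and SD of EMG onset, VMRT, and motor time per condition over
    included trials (the behavioral rows of the subject summary table)."""
    df = trials_to_frame(trials)
    inc = df[df["include"]]
    rows = []
    for cond, g in inc.groupby("condition"):
        rows.append(
            {
                "condition": cond,
                "n_trials": len(g),
                "emg_onset_mean": g["emg_onset_ms"].mean(),
                "emg_onset_sd": g["emg_onset_ms"].std(),
                "vmrt_mean": g["vmrt_ms"].mean(),
                "vmrt_sd": g["vmrt_ms"].std(),
                "motor_time_mean": g["motor_time_ms"].mean(),
                "motor_time_sd": g["motor_time_ms"].std(),
            }
        )
    return pd.DataFrame(rows)
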
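"""Stimulus-locked EEG preprocessing: filtering, epoching, baseline
correction, artifact flagging, and bad-channel management.

Trial exclusions are additive metadata: a flagged trial keeps its data and
its flags (with reason codes) and is only dropped at averaging time, so the
full bookkeeping -- n_trials = included + sum(excluded by reason) -- can be
audited after any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from . import csd as _csd
from .errors import MotionErpError, QualityError
from .io import Recording
from .montage import Montage

#: Exclusion reason codes, in pipeline precedence order.
REASONS = (
    "eeg_artifact", "blink", "no_onset", "onset_lt_100",
    "vmrt_range", "vmrt_outlier", "motor_outlier", "edge",
)


@dataclass
class EpochSet:
    """Trials x channels x time array locked to stimulus or EMG onset.

    ``window`` is the (start, stop) of the epoch in ms relative to the lock
    event; times are a half-open range sampled at 1 ms, so a (-500, 1000)
    window has 1500 samples at times -500 .. 999 ms.  ``flags`` maps trial
    index -> set of reason codes; flagged trials stay in ``data``.
    """

    data: np.ndarray                       # (n_trials, n_channels, n_times)
    srate: float
    window: tuple                          # (start_ms, stop_ms), half-open
    channel_labels: tuple
    channel_kinds: tuple
    lock: str = "stimulus"                 # "stimulus" | "response"
    baseline_window: tuple | None = None
    trial_ids: np.ndarray | None = None
    conditions: np.ndarray | None = None   # per-trial condition labels
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        n_expected = self._ms_to_samp(self.window[1]) - self._ms_to_samp(self.window[0])
        if self.data.ndim != 3 or self.data.shape[2] != n_expected:
            raise MotionErpError(
                f"epoch data has {self.data.shape[-1]} samples, window "
                f"{self.window} implies {n_expected}"
            )
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        if self.conditions is None:
            self.conditions = np.array([""] * self.data.shape[0], dtype=object)
        self.channel_labels = tuple(self.channel_labels)
        self.channel_kinds = tuple(self.channel_kinds)

    def _ms_to_samp(self, ms: float) -> int:
        return int(round(ms * self.srate / 1000.0))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.srate
        return self.window[0] + step * np.arange(self.data.shape[2])

    def sample_range(self, interval_ms) -> slice:
        """Half-open sample slice for an ms interval relative to the lock."""
        lo = self._ms_to_samp(interval_ms[0]) - self._ms_to_samp(self.window[0])
        hi = self._ms_to_samp(interval_ms[1]) - self._ms_to_samp(self.window[0])
        if lo < 0 or hi > self.data.shape[2]:
            raise MotionErpError(
                f"interval {interval_ms} outside epoch window {self.window}"
            )
        return slice(lo, hi)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MotionErpError(f"channel {label!r} not in epochs") from None

    def add_flag(self, trial: int, reason: str):
        if reason not in REASONS:
            raise MotionErpError(f"unknown rejection reason {reason!r}")
        self.flags.setdefault(int(trial), set()).add(reason)

    def flagged(self, reasons=None) -> np.ndarray:
        """Boolean mask of trials carrying any (or any of ``reasons``) flag."""
        mask = np.zeros(self.n_trials, dtype=bool)
        for t, rs in self.flags.items():
            if reasons is None or rs & set(reasons):
                mask[t] = True
        return mask

    @property
    def included(self) -> np.ndarray:
        return ~self.flagged()

    def first_reason(self, trial: int) -> str | None:
        """First triggering reason in the documented precedence order."""
        rs = self.flags.get(int(trial), set())
        for r in REASONS:
            if r in rs:
                return r
        return None

    def copy_with(self, **kw) -> "EpochSet":
        if "flags" not in kw:
            kw["flags"] = {t: set(r) for t, r in self.flags.items()}
        return replace(self, **kw)

    def subset(self, mask) -> "EpochSet":
        """Trials selected by boolean mask or index array, flags remapped."""
        idx = np.nonzero(mask)[0] if np.asarray(mask).dtype == bool else np.asarray(mask)
        flags = {new: set(self.flags[old]) for new, old in enumerate(idx)
                 if int(old) in self.flags}
        return replace(
            self,
            data=self.data[idx],
            trial_ids=self.trial_ids[idx],
            conditions=self.conditions[idx],
            flags=flags,
        )


@dataclass
class RejectionReport:
    """Per-trial reasons and per-channel artifact statistics."""

    trial_reasons: dict                      # trial -> set of reasons
    channel_fraction: dict                   # EEG label -> fraction of trials
    excluded_channels: list = field(default_factory=list)

    def __post_init__(self):
        for frac in self.channel_fraction.values():
            if not (0.0 <= frac <= 1.0):
                raise MotionErpError("channel artifact fraction outside [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": list(self.channel_fraction),
                "artifact_fraction": list(self.channel_fraction.values()),
                "interpolated": [
                    lb in self.excluded_channels for lb in self.channel_fraction
                ],
            }
        )


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def bandpass_eeg(recording: Recording, low: float = 0.3, high: float = 35.0) -> Recording:
    """Zero-phase band-pass of the EEG/EOG channels (EMG is left untouched;
    it has its own detection path).

    A 4th-order Butterworth band-pass applied forward-backward
    (``sosfiltfilt``): monotone passband, no phase distortion, so component
    peak latencies are preserved.
    """
    nyq = recording.srate / 2.0
    if high >= nyq:
        raise MotionErpError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise MotionErpError("need 0 < low < high")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=recording.srate,
                        output="sos")
    out = recording.data.copy()
    idx = recording.picks("eeg") + recording.picks("eog")
    out[idx] = signal.sosfiltfilt(sos, recording.data[idx], axis=1)
    return recording.copy_with(data=out)


def segment(
    recording: Recording,
    window=(-500.0, 1000.0),
    condition: str | None = None,
    channels: list | None = None,
) -> EpochSet:
    """Cut one epoch per stimulus event.

    Events whose window under- or over-runs the recording produce a trial of
    edge-padded data flagged ``"edge"`` rather than an exception, keeping
    trial ids aligned with the event stream.
    """
    sr = recording.srate
    lo = int(round(window[0] * sr / 1000.0))
    hi = int(round(window[1] * sr / 1000.0))
    stims = recording.events.stimuli(condition)
    if channels is None:
        ch_idx = list(range(len(recording.channel_labels)))
    else:
        ch_idx = [recording.channel_index(c) for c in channels]
    n_t = hi - lo
    data = np.zeros((len(stims), len(ch_idx), n_t), dtype=recording.data.dtype)
    flags: dict[int, set] = {}
    conds = np.array([e.condition or "" for e in stims], dtype=object)
    for i, ev in enumerate(stims):
        a, b = ev.sample + lo, ev.sample + hi
        if a < 0 or b > recording.n_samples:
            flags[i] = {"edge"}
            aa, bb = max(a, 0), min(b, recording.n_samples)
            data[i, :, aa - a : aa - a + (bb - aa)] = recording.data[ch_idx, aa:bb]
        else:
            data[i] = recording.data[ch_idx, a:b]
    return EpochSet(
        data=data,
        srate=sr,
        window=tuple(window),
        channel_labels=[recording.channel_labels[i] for i in ch_idx],
        channel_kinds=[recording.channel_kinds[i] for i in ch_idx],
        trial_ids=np.arange(len(stims)),
        conditions=conds,
        flags=flags,
    )


def baseline_subtract(epochs: EpochSet, window=(-500.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (idempotent)."""
    sl = epochs.sample_range(window)
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    out = epochs.copy_with(data=epochs.data - base)
    out.baseline_window = tuple(window)
    return out


def flag_blink_trials(
    epochs: EpochSet,
    eog_channel: str = "EOG",
    interval=(-500.0, 200.0),
    threshold: float | None = None,
) -> EpochSet:
    """Flag trials whose EOG deviates beyond ``threshold`` inside ``interval``.

    Blinks inside the pre-stimulus/early interval impair the task-relevant
    visual processing, so those trials are excluded from averages.  When
    ``threshold`` is None it defaults to 4x the robust SD (1.4826 * MAD) of
    the EOG baseline across all trials, measured around the baseline median.
    """
    ieog = epochs.channel_index(eog_channel)
    eog = epochs.data[:, ieog, :]
    if threshold is None:
        bsl = epochs.sample_range((epochs.window[0], 0.0))
        base = eog[:, bsl]
        med = np.median(base)
        rsd = 1.4826 * np.median(np.abs(base - med))
        if rsd == 0:
            return epochs.copy_with()
        threshold = 4.0 * rsd
        center = med
    else:
        center = 0.0
    sl = epochs.sample_range(interval)
    out = epochs.copy_with()
    dev = np.abs(eog[:, sl] - center)
    for t in np.nonzero(dev.max(axis=1) > threshold)[0]:
        out.add_flag(t, "blink")
    return out


def reject_artifacts(
    epochs: EpochSet,
    interval=(-500.0, 500.0),
    step_thresh: float = 50.0,
    amp_thresh: float = 150.0,
) -> tuple[EpochSet, RejectionReport]:
    """Flag trials with voltage steps > ``step_thresh`` uV between adjacent
    samples (per ms at 1000 Hz) or absolute amplitude beyond ``amp_thresh``
    uV on any EEG channel inside ``interval``; report per-channel artifact
    fractions.
    """
    sl = epochs.sample_range(interval)
    eeg_idx = [i for i, k in enumerate(epochs.channel_kinds) if k == "eeg"]
    seg = epochs.data[:, eeg_idx, sl]
    amp_bad = np.abs(seg).max(axis=2) > amp_thresh              # (trials, eeg)
    step_bad = np.abs(np.diff(seg, axis=2)).max(axis=2) > step_thresh
    ch_bad = amp_bad | step_bad
    out = epochs.copy_with()
    for t in np.nonzero(ch_bad.any(axis=1))[0]:
        out.add_flag(t, "eeg_artifact")
    frac = ch_bad.mean(axis=0)
    report = RejectionReport(
        trial_reasons={t: set(r) for t, r in out.flags.items()},
        channel_fraction={
            epochs.channel_labels[i]: float(frac[j]) for j, i in enumerate(eeg_idx)
        },
    )
    return out, report


def manage_bad_channels(
    epochs: EpochSet,
    report: RejectionReport,
    montage: Montage,
    frac_thresh: float = 0.25,
    reject_kwargs: dict | None = None,
) -> tuple[EpochSet, RejectionReport]:
    """Interpolate channels that are artifactual in more than ``frac_thresh``
    of trials, then recompute artifact flags without the offending channels'
    original data.

    Raises :class:`QualityError` when more than 20% of EEG channels exceed
    the threshold -- interpolating that many channels would no longer be a
    repair but a fabrication.
    """
    bad = [lb for lb, f in report.channel_fraction.items() if f > frac_thresh]
    n_eeg = len(report.channel_fraction)
    if not bad:
        return epochs.copy_with(), report
    if len(bad) > 0.2 * n_eeg:
        raise QualityError(
            f"{len(bad)} of {n_eeg} channels (> 20%) exceed the artifact "
            f"fraction threshold"
        )
    eeg_labels = [lb for lb in epochs.channel_labels
                  if epochs.channel_kinds[epochs.channel_index(lb)] == "eeg"]
    sub = montage.subset(eeg_labels)
    eeg_idx = [epochs.channel_index(lb) for lb in eeg_labels]
    fixed = epochs.data.copy()
    fixed_eeg = _csd.interpolate_channels(
        np.moveaxis(epochs.data[:, eeg_idx, :], 1, 0).reshape(len(eeg_idx), -1),
        bad, sub, channel_axis=0,
    )
    fixed[:, eeg_idx, :] = np.moveaxis(
        fixed_eeg.reshape(len(eeg_idx), epochs.n_trials, -1), 0, 1
    )
    clean = epochs.copy_with(data=fixed)
    # drop stale artifact flags, re-derive them from the repaired data
    for t in list(clean.flags):
        clean.flags[t].discard("eeg_artifact")
        if not clean.flags[t]:
            del clean.flags[t]
    kw = reject_kwargs or {}
    reflagged, new_report = reject_artifacts(clean, **kw)
    for lb in bad:
        new_report.channel_fraction[lb] = 0.0
    new_report.excluded_channels = bad
    return reflagged, new_report


def average_epochs(epochs: EpochSet, include: np.ndarray | None = None):
    """Arithmetic mean over included (unflagged) trials.

    Returns ``(average, n_included)`` where average is channels x time.
    """
    mask = epochs.included if include is None else np.asarray(include, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise QualityError("no trials left to average")
    return epochs.data[mask].mean(axis=0), n
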
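"""Synthetic visuomotor-reaction recordings with exact ground truth.

The generator emulates the study protocol: 80 trials per motion-velocity
condition ("slow", "fast"), inter-stimulus intervals uniform on 2-6 s, a
200 ms motion stimulus, 63 EEG channels + EOG + EMG at 1000 Hz.  Each trial
embeds raised-cosine ERP bumps (N1/N2 over the parieto-occipital MT pool,
an early positivity and later negativity over the frontocentral BA6 pool)
at per-trial latencies drawn around the condition means, an EMG burst
starting at the drawn onset, and a button-press marker at onset + motor
time, exactly.  Blink and high-amplitude artifacts can be injected on top.

Every random draw flows from explicit seeds through numpy's splittable
``SeedSequence`` scheme, so identical specs + seeds give bit-identical
output, and every drawn value is recorded in a :class:`GroundTruth` table.

Amplitudes are sensor-level microvolts and are free parameters of the
emulation (the study reports amplitudes only after the current source
density transform); defaults mirror the reported post-CSD amplitude ratios
at magnitudes typical for motion-onset responses on posterior electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .errors import ConfigError, MotionErpError
from .io import Event, EventList, Recording
from .montage import Montage, load_montage

#: Component templates: raised-cosine full widths (ms).  Smooth, single
#: peaked, and with an analytically known maximum at the drawn latency.
COMPONENT_WIDTHS = {"N1": 80.0, "N2": 120.0, "BA6pos": 80.0, "BA6neg": 120.0}

#: Spatial pattern centers (bilateral for MT components) and angular spread.
COMPONENT_CENTERS = {
    "N1": ("PO7", "PO8"),
    "N2": ("PO7", "PO8"),
    "BA6pos": ("FCz",),
    "BA6neg": ("FCz",),
}
_SPATIAL_SIGMA_DEG = 28.0


@dataclass(frozen=True)
class ComponentParams:
    """Latency/amplitude distribution of one ERP component in one condition."""

    latency_mean: float     # ms post-stimulus
    latency_sd: float       # trial-to-trial SD, ms
    amplitude_mean: float   # sensor uV (sign carries polarity)
    amplitude_sd: float     # trial-to-trial SD, uV

    def __post_init__(self):
        if self.latency_sd < 0 or self.amplitude_sd < 0:
            raise ConfigError("SDs must be >= 0")


@dataclass(frozen=True)
class ConditionSpec:
    """One motion-velocity condition of the reaction protocol.

    Latency/behavioral means default to the group means reported for the
    protocol (slow and fast variants via :func:`default_conditions`);
    ``emg_delay`` and ``motor_time`` are (mean, trial SD) pairs in ms.
    """

    name: str
    n_trials: int = 80
    isi_range: tuple = (2.0, 6.0)          # seconds, uniform
    stim_duration: float = 200.0           # ms
    component_params: dict = field(default_factory=dict)
    emg_delay: tuple = (206.4, 15.0)       # ms from stimulus to EMG onset
    motor_time: tuple = (51.9, 5.0)        # ms from EMG onset to button press

    def __post_init__(self):
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if not self.isi_range[0] < self.isi_range[1]:
            raise ConfigError("isi_range must be (low, high) with low < high")
        if self.emg_delay[0] <= 0 or self.motor_time[0] <= 0:
            raise ConfigError("emg_delay and motor_time means must be > 0")
        if self.emg_delay[1] < 0 or self.motor_time[1] < 0:
            raise ConfigError("emg_delay and motor_time SDs must be >= 0")
        for name in self.component_params:
            if name not in COMPONENT_WIDTHS:
                raise ConfigError(f"unknown component {name!r}")


@dataclass(frozen=True)
class NoiseProfile:
    """Background noise and artifact structure of one subject.

    broadband_sd : total background EEG RMS per channel (uV) in-band; a
        50/50 power mixture of white and 1/f^alpha noise.
    pink_exponent : alpha of the 1/f^alpha part.
    blink_rate : blinks per minute on the EOG (propagating to frontal EEG).
    artifact_fraction : fraction of trials receiving an injected
        high-amplitude artifact (> 150 uV excursion or > 50 uV step).
    emg_noise_sd : EMG baseline noise SD (mV-scale units).
    emg_burst_gain : burst-to-baseline amplitude ratio of the EMG model.
    """

    broadband_sd: float = 8.0
    pink_exponent: float = 1.0
    blink_rate: float = 1.0
    artifact_fraction: float = 0.05
    emg_noise_sd: float = 0.02
    emg_burst_gain: float = 8.0

    def __post_init__(self):
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ConfigError("artifact_fraction must be in [0,1]")
        if self.blink_rate < 0:
            raise ConfigError("blink_rate must be >= 0")
        if self.broadband_sd < 0 or self.emg_noise_sd <= 0:
            raise ConfigError("noise SDs invalid")


@dataclass(frozen=True)
class SubjectSpec:
    """Subject identity, subject-level shifts, noise profile, and seed."""

    subject_id: str
    latency_offsets: dict = field(default_factory=dict)   # component -> ms
    amplitude_scales: dict = field(default_factory=dict)  # component -> factor
    emg_offset: float = 0.0                               # ms
    motor_offset: float = 0.0                             # ms
    noise_profile: NoiseProfile = field(default_factory=NoiseProfile)
    mt_anterior: bool = False        # place MT energy on the anterior pool
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """A cohort with a linear latent coupling between N2/N2-r latencies and
    EMG onset:  EMG = mean_EMG + b*(N2 - mean_N2) + c*(N2r - mean_N2r) + a + eps.

    ``between_subject_sds`` maps parameter names (``"N2"``, ``"N2r"``,
    ``"N1"``, ``"BA6pos"``, ``"BA6neg"``, ``"motor_time"``) to SDs of the
    subject-level draws.  N2 and N2-r are drawn independently at the
    subject level; the EMG onset follows the coupling model.
    """

    n_subjects: int = 37
    coupling: tuple = (0.0, 0.7, -0.9, 3.2)   # (a, b, c, residual SD)
    between_subject_sds: dict = field(default_factory=dict)
    n2r_means: dict = field(default_factory=lambda: {"slow": -0.1, "fast": 17.2})
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.coupling[3] < 0:
            raise ConfigError("coupling residual SD must be >= 0")


#: Between-subject SDs of the subject-level parameter draws (ms), following
#: the reported group dispersion per condition.
DEFAULT_BETWEEN_SDS = {
    "N1": 3.3, "N2": 6.0, "N2r": 7.4, "BA6pos": 4.4, "BA6neg": 7.2,
    "motor_time": 3.2,
    # multiplicative between-subject spread of component amplitudes
    "amplitude_scale": 0.15,
}


def default_conditions() -> list:
    """The two study conditions with group-mean defaults.

    Latency and behavioral means per condition follow the reported group
    means; amplitudes are sensor-level choices mirroring the reported
    post-CSD amplitude ratios.  Trial-to-trial latency SDs (8 ms for the
    ERP components, 15/5 ms for EMG onset / motor time) are emulation
    choices typical for strong sensory components.
    """
    slow = ConditionSpec(
        name="slow",
        component_params={
            "N1": ComponentParams(107.3, 8.0, -8.0, 1.6),
            "N2": ComponentParams(193.4, 8.0, -15.0, 3.0),
            "BA6pos": ComponentParams(88.9, 8.0, 6.0, 1.2),
            "BA6neg": ComponentParams(161.8, 8.0, -10.0, 2.0),
        },
        emg_delay=(206.4, 15.0),
        motor_time=(51.9, 5.0),
    )
    fast = ConditionSpec(
        name="fast",
        component_params={
            "N1": ComponentParams(103.4, 8.0, -14.0, 2.8),
            "N2": ComponentParams(187.1, 8.0, -18.0, 3.6),
            "BA6pos": ComponentParams(87.7, 8.0, 7.0, 1.4),
            "BA6neg": ComponentParams(164.5, 8.0, -13.0, 2.6),
        },
        emg_delay=(181.2, 15.0),
        motor_time=(51.3, 5.0),
    )
    return [slow, fast]


@dataclass
class GroundTruth:
    """Exact per-trial and per-subject generated values.

    ``trials`` has one row per trial with the drawn component latencies and
    amplitudes, the true EMG onset and button-press time (ms post-stimulus;
    press = onset + motor time exactly), and artifact bookkeeping columns.
    ``subject`` summarizes per-condition true means.
    """

    subject_id: str
    trials: pd.DataFrame
    subject: pd.DataFrame

    def condition_means(self, condition: str) -> dict:
        row = self.subject[self.subject["condition"] == condition]
        if row.empty:
            raise MotionErpError(f"no condition {condition!r} in ground truth")
        return row.iloc[0].to_dict()


# --------------------------------------------------------------------------
# Signal primitives
# --------------------------------------------------------------------------

def raised_cosine(times_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak raised-cosine bump of full width ``width_ms``."""
    phase = (times_ms - center_ms) / (width_ms / 2.0)
    out = np.where(np.abs(phase) < 1.0, 0.5 * (1.0 + np.cos(np.pi * phase)), 0.0)
    return out


def spatial_pattern(montage: Montage, centers, sigma_deg: float = _SPATIAL_SIGMA_DEG) -> np.ndarray:
    """Gaussian angular falloff around one or more center electrodes,
    normalized to unit maximum."""
    sig = np.deg2rad(sigma_deg)
    w = np.zeros(len(montage))
    for c in centers:
        cosang = np.clip(montage.positions @ montage.position(c), -1.0, 1.0)
        ang = np.arccos(cosang)
        w += np.exp(-0.5 * (ang / sig) ** 2)
    return w / w.max()


def _colored_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                   sd: float, alpha: float, srate: float) -> np.ndarray:
    """White + 1/f^alpha mixture with total RMS ``sd`` per channel."""
    if sd == 0:
        return np.zeros((n_ch, n_samp), dtype=np.float32)
    # A sum of independent white and 1/f^alpha Gaussian processes is itself
    # Gaussian with the summed PSD, so one spectrally shaped draw suffices.
    # The two parts have equal power at 10 Hz; per-channel RMS is then
    # normalized to sd.  The FFT length is padded to an FFT-friendly size
    # (awkward prime factors make the transform an order of magnitude
    # slower).
    n_fft = sp_fft.next_fast_len(n_samp, real=True)
    z = rng.standard_normal((n_ch, n_fft), dtype=np.float32)
    spec = sp_fft.rfft(z, axis=1)
    freqs = sp_fft.rfftfreq(n_fft, d=1.0 / srate)
    f_ref = 10.0
    shape = np.ones_like(freqs, dtype=np.float32)
    nz = freqs > 0
    shape[nz] = np.sqrt(1.0 + (freqs[nz] / f_ref) ** (-alpha)).astype(np.float32)
    shape[0] = 0.0
    mix = sp_fft.irfft(spec * shape, n=n_fft, axis=1)[:, :n_samp]
    mix *= sd / mix.std(axis=1, keepdims=True)
    return np.ascontiguousarray(mix, dtype=np.float32)


_BLINK_WIDTH_MS = 300.0
_BLINK_AMP_UV = 180.0


def _blink_waveform(srate: float) -> np.ndarray:
    n = int(round(_BLINK_WIDTH_MS * srate / 1000.0))
    t = np.arange(n)
    return _BLINK_AMP_UV * 0.5 * (1 - np.cos(2 * np.pi * t / n))


# --------------------------------------------------------------------------
# Subject generation
# --------------------------------------------------------------------------

_EPOCH_SPAN_S = 1.5   # -500..1000 ms analysis epoch; ISIs must exceed this


def _draw_trial_times(rng, condition: ConditionSpec, srate: float, t_start_s: float):
    """Stimulus onset samples for one condition block."""
    if condition.isi_range[0] < _EPOCH_SPAN_S:
        raise ConfigError(
            f"ISI low bound {condition.isi_range[0]} s would overlap the "
            f"{_EPOCH_SPAN_S} s analysis epoch"
        )
    isis = rng.uniform(*condition.isi_range, size=condition.n_trials)
    onsets_s = t_start_s + np.cumsum(isis)
    return np.round(onsets_s * srate).astype(int), onsets_s[-1]


def generate_subject(
    subject: SubjectSpec,
    conditions=None,
    montage: Montage | None = None,
    srate: float = 1000.0,
) -> tuple[Recording, GroundTruth]:
    """Generate one subject's continuous recording plus exact ground truth.

    Condition blocks are laid out sequentially; each stimulus marker carries
    its condition.  The returned recording has 63 EEG channels, one EOG and
    one EMG channel, stimulus and button-press markers, and (per the
    subject's noise profile) injected blink and high-amplitude artifacts.
    """
    conditions = conditions if conditions is not None else default_conditions()
    montage = montage or load_montage()
    ss = np.random.SeedSequence(subject.seed)
    rng_prot, rng_lat, rng_noise, rng_art = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    prof = subject.noise_profile

    # --- protocol timeline -------------------------------------------------
    stim_samples, conds = [], []
    t_cursor = 1.0  # lead-in seconds
    for cond in conditions:
        samples, t_end = _draw_trial_times(rng_prot, cond, srate, t_cursor)
        stim_samples.append(samples)
        conds += [cond.name] * cond.n_trials
        t_cursor = t_end + 2.0  # inter-block pause
    stim_samples = np.concatenate(stim_samples)
    n_samples = int(stim_samples[-1] + 1.5 * srate + int(srate))

    labels = tuple(montage.labels) + ("EOG", "EMG")
    kinds = ("eeg",) * len(montage) + ("eog", "emg")
    n_eeg = len(montage)

    # --- per-trial draws ---------------------------------------------------
    rows = []
    for i, (samp, cname) in enumerate(zip(stim_samples, conds)):
        cond = next(c for c in conditions if c.name == cname)
        row = {"trial_id": i, "condition": cname, "stimulus_sample": int(samp)}
        for comp, p in cond.component_params.items():
            lat = (p.latency_mean + subject.latency_offsets.get(comp, 0.0)
                   + rng_lat.normal(0.0, p.latency_sd))
            amp = (p.amplitude_mean * subject.amplitude_scales.get(comp, 1.0)
                   + rng_lat.normal(0.0, p.amplitude_sd))
            row[f"{comp}_latency"] = lat
            row[f"{comp}_amplitude"] = amp
        emg = (cond.emg_delay[0] + subject.emg_offset
               + rng_lat.normal(0.0, cond.emg_delay[1]))
        mot = (cond.motor_time[0] + subject.motor_offset
               + rng_lat.normal(0.0, cond.motor_time[1]))
        mot = max(mot, 1.0)
        emg = max(emg, 20.0)
        row["emg_onset_ms"] = emg
        row["motor_time_ms"] = mot
        row["button_press_ms"] = emg + mot   # exact identity by construction
        row["artifact"] = False
        row["blink_in_window"] = False
        rows.append(row)
    truth = pd.DataFrame(rows)

    # --- assemble signal ---------------------------------------------------
    data = _colored_noise(rng_noise, n_eeg, n_samples, prof.broadband_sd,
                          prof.pink_exponent, srate)
    eog = _colored_noise(rng_noise, 1, n_samples, 10.0, prof.pink_exponent, srate)[0]
    emg_ch = rng_noise.normal(0.0, prof.emg_noise_sd, n_samples).astype(np.float32)

    centers = dict(COMPONENT_CENTERS)
    if subject.mt_anterior:
        centers["N1"] = ("TP7", "TP8")
        centers["N2"] = ("TP7", "TP8")
    patterns = {c: spatial_pattern(montage, centers[c]).astype(np.float32)
                for c in COMPONENT_WIDTHS}

    pad = int(0.3 * srate)
    for row in truth.itertuples():
        samp = row.stimulus_sample
        t_rel = (np.arange(-pad, int(1.2 * srate)) * 1000.0 / srate)
        idx0 = samp - pad
        for comp in COMPONENT_WIDTHS:
            lat_col = f"{comp}_latency"
            if not hasattr(row, lat_col):
                continue
            bump = raised_cosine(t_rel, getattr(row, lat_col),
                                 COMPONENT_WIDTHS[comp])
            nz = np.nonzero(bump)[0]
            if nz.size == 0:
                continue
            sl = slice(idx0 + nz[0], idx0 + nz[-1] + 1)
            contrib = getattr(row, f"{comp}_amplitude") * bump[nz[0]:nz[-1] + 1]
            data[:, sl] += patterns[comp][:, None] * contrib[None, :].astype(np.float32)
        # EMG burst: noise amplitude steps up by the burst gain at onset
        on = samp + int(round(row.emg_onset_ms * srate / 1000.0))
        burst_len = int(0.3 * srate)
        end = min(on + burst_len, n_samples)
        if on < n_samples:
            emg_ch[on:end] *= prof.emg_burst_gain

    # --- events ------------------------------------------------------------
    events = []
    for row in truth.itertuples():
        events.append(Event(int(row.stimulus_sample), "stimulus", row.condition))
        press = int(row.stimulus_sample
                    + round(row.button_press_ms * srate / 1000.0))
        if press < n_samples:
            events.append(Event(press, "response"))

    full = np.concatenate([data, eog[None, :], emg_ch[None, :]], axis=0)
    recording = Recording(
        data=full.astype(np.float32),
        srate=srate,
        channel_labels=labels,
        channel_kinds=kinds,
        events=EventList(events),
    )

    # --- artifacts ---------------------------------------------------------
    recording, art_log = inject_artifacts(recording, prof, rng_art)
    truth.loc[truth["trial_id"].isin(art_log["artifact_trials"]), "artifact"] = True
    truth.loc[truth["trial_id"].isin(art_log["blink_trials"]),
              "blink_in_window"] = True

    subj_rows = []
    for cname in truth["condition"].unique():
        g = truth[truth["condition"] == cname]
        r = {"subject_id": subject.subject_id, "condition": cname,
             "n_trials": len(g)}
        for comp in COMPONENT_WIDTHS:
            col = f"{comp}_latency"
            if col in g:
                r[f"{comp}_latency_mean"] = g[col].mean()
                r[f"{comp}_amplitude_mean"] = g[f"{comp}_amplitude"].mean()
        r["emg_onset_mean"] = g["emg_onset_ms"].mean()
        r["vmrt_mean"] = g["button_press_ms"].mean()
        r["motor_time_mean"] = g["motor_time_ms"].mean()
        # response-locked MT latency implied by the single-component model
        if "N2_latency" in g:
            r["N2r_latency_mean"] = (g["N2_latency"] - g["emg_onset_ms"]).mean()
        subj_rows.append(r)
    gt = GroundTruth(subject.subject_id, truth, pd.DataFrame(subj_rows))
    return recording, gt


def inject_artifacts(
    recording: Recording,
    profile: NoiseProfile,
    rng_or_seed,
) -> tuple[Recording, dict]:
    """Add stereotyped blinks and designated high-amplitude artifact trials.

    Blinks are raised-cosine waveforms at Poisson times on the EOG channel,
    propagated at reduced gain to frontopolar EEG channels.  A random
    ``artifact_fraction`` of trials receives either a > 150 uV excursion or
    a > 50 uV/ms step on one EEG channel inside the -500..500 ms rejection
    interval.  Returns the modified recording and a log with the affected
    trial indices.  With blink rate 0 and artifact fraction 0 the recording
    is returned unchanged.
    """
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    log = {"blink_samples": [], "blink_trials": [], "artifact_trials": [],
           "artifact_kinds": {}}
    if profile.blink_rate == 0 and profile.artifact_fraction == 0:
        return recording, log

    data = recording.data.copy()
    srate = recording.srate
    n = recording.n_samples
    stims = recording.events.stimuli()

    if profile.blink_rate > 0:
        n_blinks = rng.poisson(profile.blink_rate * n / srate / 60.0)
        wave = _blink_waveform(srate)
        ieog = recording.picks("eog")
        frontal = [i for i, lb in enumerate(recording.channel_labels)
                   if lb in ("Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8")]
        for s in sorted(rng.integers(0, n - wave.size, size=n_blinks)):
            data[ieog, s:s + wave.size] += wave
            data[frontal, s:s + wave.size] += 0.35 * wave
            log["blink_samples"].append(int(s))
            # which trials does this blink contaminate (-500..200 ms window)?
            for t, ev in enumerate(stims):
                w0 = ev.sample - int(0.5 * srate)
                w1 = ev.sample + int(0.2 * srate)
                if s < w1 and s + wave.size > w0:
                    log["blink_trials"].append(t)
    log["blink_trials"] = sorted(set(log["blink_trials"]))

    if profile.artifact_fraction > 0 and stims:
        n_art = int(round(profile.artifact_fraction * len(stims)))
        picks = rng.choice(len(stims), size=min(n_art, len(stims)), replace=False)
        eeg_idx = recording.picks("eeg")
        for t in sorted(picks):
            ev = stims[t]
            ch = int(rng.choice(eeg_idx))
            at = ev.sample + int(rng.integers(-400, 400) * srate / 1000.0)
            if rng.random() < 0.5:
                # amplitude artifact: 100 ms excursion beyond +-150 uV
                wlen = int(0.1 * srate)
                amp = rng.uniform(170.0, 280.0) * rng.choice([-1.0, 1.0])
                bump = amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(wlen) / wlen))
                end = min(at + wlen, n)
                data[ch, at:end] += bump[: end - at]
                log["artifact_kinds"][int(t)] = "amplitude"
            else:
                # step artifact (electrode pop): the jump must stay above the
                # 50 uV/ms criterion even after the 35 Hz analysis low-pass
                # spreads it over ~10 ms, so use several hundred uV
                step = rng.uniform(350.0, 600.0) * rng.choice([-1.0, 1.0])
                wlen = int(0.08 * srate)
                end = min(at + wlen, n)
                data[ch, at:end] += step
                log["artifact_kinds"][int(t)] = "step"
            log["artifact_trials"].append(int(t))

    out = recording.copy_with(data=data)
    return out, log


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass
class CohortSample:
    """Subject specs and latent truth of a generated cohort.

    ``subject_truths`` holds the drawn subject-level values (one row per
    subject x condition): N2 and N2-r latencies, the coupled EMG onset,
    motor time, VMRT, and the remaining component latencies.  Recordings
    are realized lazily (they are large) via :meth:`realize` /
    :meth:`iter_recordings`.
    """

    spec: CohortSpec
    conditions: list
    subjects: list                  # of SubjectSpec
    subject_conditions: list        # per subject: list of ConditionSpec
    subject_truths: pd.DataFrame

    def realize(self, i: int, montage: Montage | None = None):
        return generate_subject(self.subjects[i], self.subject_conditions[i],
                                montage=montage)

    def iter_recordings(self, montage: Montage | None = None):
        for i in range(len(self.subjects)):
            yield self.realize(i, montage=montage)


def generate_cohort(cohort: CohortSpec, conditions=None) -> CohortSample:
    """Draw a cohort whose subject-level EMG onsets follow the linear
    coupling model on independently drawn N2 and N2-r latencies.

    For each condition, subject draws are
    ``N2 ~ Normal(mean_N2, sd_N2)``, ``N2r ~ Normal(mean_N2r, sd_N2r)``,
    ``EMG = mean_EMG + a + b*(N2-mean_N2) + c*(N2r-mean_N2r) + eps`` with
    ``eps ~ Normal(0, residual_sd)``.  The generating-model R^2 is
    ``(b^2 sd_N2^2 + c^2 sd_N2r^2) / (b^2 sd_N2^2 + c^2 sd_N2r^2 +
    residual_sd^2)``.  Per-subject seeds derive deterministically from
    ``master_seed``.
    """
    conditions = conditions if conditions is not None else default_conditions()
    sds = {**DEFAULT_BETWEEN_SDS, **cohort.between_subject_sds}
    a, b, c, resid_sd = cohort.coupling
    if all(v == 0 for v in sds.values()) and resid_sd == 0 and cohort.n_subjects > 1:
        import warnings

        warnings.warn("degenerate cohort: all between-subject SDs are zero")

    ss = np.random.SeedSequence(cohort.master_seed)
    subj_seeds = ss.spawn(cohort.n_subjects + 1)
    rng = np.random.default_rng(subj_seeds[-1])

    subjects, subject_conditions, rows = [], [], []
    for i in range(cohort.n_subjects):
        sid = f"S{i + 1:02d}"
        per_subject_conditions = []
        lat_offsets_by_cond = {}
        for cond in conditions:
            mu_n2 = cond.component_params["N2"].latency_mean
            mu_n2r = cohort.n2r_means.get(cond.name, 0.0)
            n2 = rng.normal(mu_n2, sds["N2"])
            n2r = rng.normal(mu_n2r, sds["N2r"])
            emg = (cond.emg_delay[0] + a + b * (n2 - mu_n2)
                   + c * (n2r - mu_n2r) + rng.normal(0.0, resid_sd))
            mot = cond.motor_time[0] + rng.normal(0.0, sds["motor_time"])
            offsets = {
                "N2": n2 - mu_n2,
                "N1": rng.normal(0.0, sds["N1"]),
                "BA6pos": rng.normal(0.0, sds["BA6pos"]),
                "BA6neg": rng.normal(0.0, sds["BA6neg"]),
            }
            lat_offsets_by_cond[cond.name] = offsets
            new_params = {
                comp: replace(
                    p,
                    latency_mean=p.latency_mean + offsets[comp],
                    amplitude_mean=p.amplitude_mean
                    * max(rng.normal(1.0, sds["amplitude_scale"]), 0.2),
                )
                for comp, p in cond.component_params.items()
            }
            per_subject_conditions.append(
                replace(
                    cond,
                    component_params=new_params,
                    emg_delay=(max(emg, 20.0), cond.emg_delay[1]),
                    motor_time=(max(mot, 1.0), cond.motor_time[1]),
                )
            )
            rows.append(
                {
                    "subject_id": sid, "condition": cond.name,
                    "N2_latency": n2, "N2r_latency": n2r,
                    "emg_onset": emg, "motor_time": mot, "vmrt": emg + mot,
                    "N1_latency": cond.component_params["N1"].latency_mean
                    + offsets["N1"],
                    "BA6pos_latency": cond.component_params["BA6pos"].latency_mean
                    + offsets["BA6pos"],
                    "BA6neg_latency": cond.component_params["BA6neg"].latency_mean
                    + offsets["BA6neg"],
                }
            )
        subjects.append(SubjectSpec(subject_id=sid,
                                    seed=int(subj_seeds[i].generate_state(1)[0] % (2**31))))
        subject_conditions.append(per_subject_conditions)
    return CohortSample(cohort, conditions, subjects, subject_conditions,
                        pd.DataFrame(rows))
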
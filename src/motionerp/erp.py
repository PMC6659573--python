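"""ROI pooling, component peak extraction, and response-locked averaging.

Cortical regions of interest follow the electrode-to-cortex projection
tables for the 10:10 system: the visual motion-sensitive area MT is read
from a parieto-occipital electrode pool (with a more anterior alternative
pool for subjects whose MT activity projects further forward), and the
pre-/supplementary motor region BA6 from a frontocentral pool in which the
surrounding electrodes are weighted by their probability of overlying BA6.

Peak picking is fully objective: closed search windows, argmin/argmax with
ties broken toward the earliest sample, and an "edge-peak" flag when the
extremum sits on a window edge with the slope still running outward --
the automated replacement for a visual check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MotionErpError, QualityError
from .preprocess import EpochSet, average_epochs


@dataclass(frozen=True)
class RoiDefinition:
    """Named electrode pool with positive weights."""

    name: str
    members: tuple  # of (label, weight)

    def __post_init__(self):
        if not self.members:
            raise MotionErpError("ROI needs at least one member")
        for _, w in self.members:
            if w <= 0:
                raise MotionErpError("ROI weights must be > 0")

    @property
    def labels(self) -> tuple:
        return tuple(lb for lb, _ in self.members)


#: Standard (parieto-occipital) electrode pool representing area MT.
MT_STANDARD = RoiDefinition(
    "MT_standard",
    tuple((lb, 1.0) for lb in ("PO7", "P7", "P5", "PO8", "P8", "P6")),
)

#: Alternative pool for subjects with a more anterior MT projection.
MT_ANTERIOR = RoiDefinition(
    "MT_anterior",
    tuple((lb, 1.0) for lb in ("TP9", "TP7", "T7", "TP10", "TP8", "P8")),
)

#: BA6 pool: FC1/FCz/FC2 at weight 1; surrounding electrodes weighted by
#: their probability of projecting onto BA6.
BA6_WEIGHTED = RoiDefinition(
    "BA6_weighted",
    (
        ("FC1", 1.0), ("FCz", 1.0), ("FC2", 1.0),
        ("F1", 0.61), ("F2", 0.69), ("Fz", 0.82),
        ("FC3", 0.75), ("FC5", 0.63), ("FC6", 0.57), ("FC4", 0.82),
    ),
)


@dataclass(frozen=True)
class ComponentDef:
    """Search definition for one ERP component."""

    name: str
    polarity: str          # "neg" | "pos"
    window: tuple          # (start_ms, end_ms), closed interval
    lock: str              # "stimulus" | "response"
    roi: RoiDefinition

    def __post_init__(self):
        if self.polarity not in ("neg", "pos"):
            raise MotionErpError("polarity must be 'neg' or 'pos'")


def component_defs(mt_roi: RoiDefinition = MT_STANDARD) -> dict:
    """The five components of the protocol, with their search windows."""
    return {
        "N1": ComponentDef("N1", "neg", (50.0, 150.0), "stimulus", mt_roi),
        "N2": ComponentDef("N2", "neg", (100.0, 300.0), "stimulus", mt_roi),
        "BA6pos": ComponentDef("BA6pos", "pos", (50.0, 150.0), "stimulus", BA6_WEIGHTED),
        "BA6neg": ComponentDef("BA6neg", "neg", (100.0, 300.0), "stimulus", BA6_WEIGHTED),
        "N2r": ComponentDef("N2r", "neg", (-50.0, 50.0), "response", mt_roi),
    }


@dataclass
class ErpPeak:
    """A measured component peak."""

    component: str
    latency_ms: float
    amplitude: float          # uV (sensor) or uV/m^2 (CSD)
    n_trials_averaged: int
    flags: tuple = ()

    def to_dict(self):
        return {
            "component": self.component,
            "latency_ms": self.latency_ms,
            "amplitude": self.amplitude,
            "n_trials": self.n_trials_averaged,
            "flags": ";".join(self.flags),
        }


def pool_roi(data: np.ndarray, roi: RoiDefinition, channel_labels) -> np.ndarray:
    """Weighted mean over ROI members: sum(w_i x_i) / sum(w_i).

    ``data`` is channels x time (or channels x anything); returns the pooled
    time series.  Raises naming the first missing member.
    """
    channel_labels = list(channel_labels)
    idx, weights = [], []
    for lb, w in roi.members:
        if lb not in channel_labels:
            raise MotionErpError(f"ROI {roi.name}: member channel {lb!r} missing")
        idx.append(channel_labels.index(lb))
        weights.append(w)
    w = np.asarray(weights, dtype=float)
    return np.tensordot(w, np.asarray(data)[idx], axes=(0, 0)) / w.sum()


def pick_peak(series: np.ndarray, times_ms: np.ndarray, comp: ComponentDef,
              n_trials: int = 0) -> ErpPeak:
    """Extremum of ``series`` inside the component's closed window.

    Ties go to the earliest sample.  When the extremum lies on a window
    edge and the series keeps running outward past the edge, the peak is
    flagged ``edge-peak``; when the amplitude sign contradicts the defined
    polarity it is flagged ``no-peak``.
    """
    times_ms = np.asarray(times_ms)
    in_win = (times_ms >= comp.window[0]) & (times_ms <= comp.window[1])
    if not in_win.any():
        raise MotionErpError(f"series does not cover window {comp.window}")
    idx = np.nonzero(in_win)[0]
    seg = np.asarray(series)[idx]
    # argmin of the polarity-oriented trace; np.argmin takes the first of
    # tied extrema, which implements the ties-to-earliest rule
    k = int(np.argmin(seg if comp.polarity == "neg" else -seg))
    i = idx[k]
    amplitude = float(series[i])
    flags = []
    # edge check: extremum on a window edge with the slope continuing outward
    if k == 0 and i > 0:
        outside = series[i - 1]
        if (outside < amplitude if comp.polarity == "neg" else outside > amplitude):
            flags.append("edge-peak")
    if k == len(idx) - 1 and i < len(series) - 1:
        outside = series[i + 1]
        if (outside < amplitude if comp.polarity == "neg" else outside > amplitude):
            flags.append("edge-peak")
    if (comp.polarity == "neg" and amplitude > 0) or (
        comp.polarity == "pos" and amplitude < 0
    ):
        flags.append("no-peak")
    return ErpPeak(comp.name, float(times_ms[i]), amplitude, n_trials, tuple(flags))


def select_mt_roi(average: np.ndarray, times_ms: np.ndarray, channel_labels,
                  window=(100.0, 300.0)) -> RoiDefinition:
    """Choose between the standard and anterior MT pools for a subject.

    The published protocol chose the anterior set by visual inspection for
    subjects with a more anterior MT projection; the objective surrogate is
    the pool whose pooled trace reaches the more negative minimum inside
    the N2 search window.  Ties go to the standard pool.
    """
    in_win = (np.asarray(times_ms) >= window[0]) & (np.asarray(times_ms) <= window[1])
    best = MT_STANDARD
    std_min = pool_roi(average, MT_STANDARD, channel_labels)[in_win].min()
    ant_min = pool_roi(average, MT_ANTERIOR, channel_labels)[in_win].min()
    if ant_min < std_min:
        best = MT_ANTERIOR
    return best


def resegment_response_locked(
    epochs: EpochSet,
    onsets_ms: dict,
    window=(-500.0, 200.0),
) -> EpochSet:
    """Re-cut stimulus-locked single-trial epochs around the per-trial EMG
    onset.

    ``onsets_ms`` maps trial index -> detected onset (ms post-stimulus) for
    the trials eligible for response-locked averaging (valid onset, survived
    all exclusions).  Trials whose re-cut window would leave the original
    epoch are flagged ``edge``.  No re-baselining is applied: the original
    stimulus-locked baseline carries over.
    """
    if not onsets_ms:
        raise QualityError("no eligible trials for response-locked averaging")
    sr = epochs.srate
    lo = int(round(window[0] * sr / 1000.0))
    hi = int(round(window[1] * sr / 1000.0))
    n_t = hi - lo
    t_first = int(round(epochs.window[0] * sr / 1000.0))
    trials = sorted(onsets_ms)
    data = np.zeros((len(trials), len(epochs.channel_labels), n_t),
                    dtype=epochs.data.dtype)
    flags: dict[int, set] = {}
    for row, t in enumerate(trials):
        onset_samp = int(round(onsets_ms[t] * sr / 1000.0))
        a = onset_samp + lo - t_first        # index into the original epoch
        b = a + n_t
        if a < 0 or b > epochs.data.shape[2]:
            flags[row] = {"edge"}
            aa, bb = max(a, 0), min(b, epochs.data.shape[2])
            data[row, :, aa - a: aa - a + (bb - aa)] = epochs.data[t, :, aa:bb]
        else:
            data[row] = epochs.data[t, :, a:b]
    return EpochSet(
        data=data,
        srate=sr,
        window=tuple(window),
        channel_labels=epochs.channel_labels,
        channel_kinds=epochs.channel_kinds,
        lock="response",
        trial_ids=np.asarray(trials),
        conditions=np.asarray([epochs.conditions[t] for t in trials], dtype=object),
        flags=flags,
    )


def measure_components(
    stim_epochs: EpochSet,
    onsets_ms: dict,
    mt_roi: RoiDefinition | None = None,
) -> tuple[list, RoiDefinition]:
    """Measure N1, N2, BA6pos, BA6neg (stimulus-locked) and N2-r
    (response-locked) for one subject and condition.

    ``stim_epochs`` are the preprocessed (and, unless CSD is bypassed,
    CSD-transformed) stimulus-locked single-trial epochs with exclusion
    flags set; ``onsets_ms`` are the detected EMG onsets of the included
    trials.  The N2-r latency is reported relative to EMG onset (0 = onset,
    positive = peak after the onset).  Returns the peak list and the MT ROI
    actually used (auto-selected when ``mt_roi`` is None).
    """
    avg, n_inc = average_epochs(stim_epochs)
    times = stim_epochs.times_ms
    if mt_roi is None:
        mt_roi = select_mt_roi(avg, times, stim_epochs.channel_labels)
    defs = component_defs(mt_roi)

    peaks = []
    for name in ("N1", "N2", "BA6pos", "BA6neg"):
        comp = defs[name]
        series = pool_roi(avg, comp.roi, stim_epochs.channel_labels)
        peaks.append(pick_peak(series, times, comp, n_inc))

    eligible = {t: o for t, o in onsets_ms.items()
                if o is not None and stim_epochs.included[t]}
    if eligible:
        resp = resegment_response_locked(stim_epochs, eligible)
        ravg, rn = average_epochs(resp)
        rseries = pool_roi(ravg, defs["N2r"].roi, resp.channel_labels)
        peaks.append(pick_peak(rseries, resp.times_ms, defs["N2r"], rn))
    else:
        peaks.append(ErpPeak("N2r", np.nan, np.nan, 0, ("no-trials",)))
    return peaks, mt_roi


def peaks_to_frame(peaks_by_condition: dict) -> pd.DataFrame:
    """Component table: one row per condition per component."""
    rows = []
    for cond, peaks in peaks_by_condition.items():
        for p in peaks:
            d = p.to_dict()
            d["condition"] = cond
            rows.append(d)
    return pd.DataFrame(rows)[
        ["condition", "component", "latency_ms", "amplitude", "n_trials", "flags"]
    ]
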
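"""End-to-end orchestration: subject runs, cohort statistics, reports.

``run_subject`` takes one continuous recording through filtering, epoching,
baseline correction, blink/artifact flagging, bad-channel interpolation,
(optionally bypassed) CSD, EMG onset detection, behavioral filtering, and
component measurement.  ``run_cohort`` aggregates subject results into the
group-level statistics: the per-condition parameter summary, paired tests
with FDR across the 13-parameter family, Pearson screening of ERP
parameters against EMG onset and VMRT, and stepwise forward regressions
with collinearity and residual diagnostics.

Exclusion bookkeeping: each trial is counted once, under the first
triggering reason in the precedence order eeg_artifact > blink > no_onset >
onset_lt_100 > vmrt_range > vmrt_outlier > motor_outlier, so
``n_trials == included + sum(excluded by reason)`` holds for every subject.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import csd as _csd
from . import emg as _emg
from . import erp as _erp
from . import preprocess as _pre
from .config import PipelineConfig
from .errors import MotionErpError, QualityError
from .io import Recording
from .montage import Montage, load_montage
from .stats import (
    RegressionResult,
    check_collinearity,
    fdr_adjust,
    paired_ttest,
    pearson_screen,
    stepwise_forward,
)

log = logging.getLogger("motionerp")

#: The 13 condition-level parameters of the group summary table.
TABLE1_PARAMS = (
    "emg_onset", "vmrt", "motor_time",
    "N1_latency", "N1_amplitude", "N2_latency", "N2_amplitude",
    "N2r_latency", "N2r_amplitude",
    "BA6pos_latency", "BA6pos_amplitude", "BA6neg_latency", "BA6neg_amplitude",
)

_ERP_PARAMS = tuple(p for p in TABLE1_PARAMS
                    if p.endswith(("latency", "amplitude")))


@dataclass
class SubjectResult:
    """Everything measured for one subject."""

    subject_id: str
    trials: pd.DataFrame            # behavioral trial table with flags
    components: pd.DataFrame        # condition x component peaks
    rejection: pd.DataFrame         # per-channel artifact fractions
    mt_roi: str
    exclusion_counts: pd.DataFrame  # per condition x first-reason counts
    behavioral: pd.DataFrame        # per-condition behavioral summary

    def parameter_row(self, condition: str) -> dict:
        """The 13 summary parameters for one condition (NaN when absent)."""
        out = {"subject_id": self.subject_id, "condition": condition}
        beh = self.behavioral[self.behavioral["condition"] == condition]
        if not beh.empty:
            out["emg_onset"] = beh.iloc[0]["emg_onset_mean"]
            out["vmrt"] = beh.iloc[0]["vmrt_mean"]
            out["motor_time"] = beh.iloc[0]["motor_time_mean"]
        comp = self.components[self.components["condition"] == condition]
        for _, row in comp.iterrows():
            out[f"{row['component']}_latency"] = row["latency_ms"]
            out[f"{row['component']}_amplitude"] = row["amplitude"]
        return out


def _merge_eeg_flags_into_trials(epochs, trials):
    for t in range(epochs.n_trials):
        reasons = epochs.flags.get(t, set())
        if "eeg_artifact" in reasons or "edge" in reasons:
            trials[t].exclude("eeg_artifact")
        if "blink" in reasons:
            trials[t].exclude("blink")
    return trials


def _merge_trial_flags_into_epochs(epochs, trials):
    order = {r: i for i, r in enumerate(_pre.REASONS)}
    for t, rec in enumerate(trials):
        for reason in rec.exclusion_reasons:
            if reason in order:
                epochs.add_flag(t, reason)
    return epochs


def run_subject(
    recording: Recording,
    config: PipelineConfig | None = None,
    montage: Montage | None = None,
) -> SubjectResult:
    """Run the full single-subject pipeline on a continuous recording."""
    config = config or PipelineConfig()
    montage = montage or load_montage(config.montage)

    # --- EEG path ----------------------------------------------------------
    filtered = _pre.bandpass_eeg(recording, config.filter.low_hz,
                                 config.filter.high_hz)
    eeg_eog = [lb for lb, k in zip(recording.channel_labels,
                                   recording.channel_kinds)
               if k in ("eeg", "eog")]
    epochs = _pre.segment(filtered, window=config.epochs.window_ms,
                          channels=eeg_eog)
    epochs = _pre.baseline_subtract(epochs, config.epochs.baseline_ms)
    epochs = _pre.flag_blink_trials(
        epochs,
        interval=config.rejection.blink_interval_ms,
        threshold=config.rejection.blink_threshold_uv,
    )
    reject_kwargs = dict(
        interval=config.rejection.artifact_interval_ms,
        step_thresh=config.rejection.step_thresh_uv,
        amp_thresh=config.rejection.amp_thresh_uv,
    )
    epochs, report = _pre.reject_artifacts(epochs, **reject_kwargs)
    epochs, report = _pre.manage_bad_channels(
        epochs, report, montage,
        frac_thresh=config.rejection.bad_channel_fraction,
        reject_kwargs=reject_kwargs,
    )

    # --- EMG / behavioral path ---------------------------------------------
    emg_epochs = _pre.segment(recording, window=config.epochs.window_ms,
                              channels=["EMG"])
    emg_epochs = _pre.baseline_subtract(emg_epochs, config.epochs.baseline_ms)
    onset_params = _emg.OnsetParams(
        lowpass_hz=config.onset.lowpass_hz,
        smooth_window_ms=config.onset.smooth_window_ms,
        k_sd=config.onset.k_sd,
        baseline_window=tuple(config.epochs.baseline_ms),
        min_hold_ms=config.onset.min_hold_ms,
    )
    stims = recording.events.stimuli()
    trials = []
    for t, ev in enumerate(stims):
        onset = _emg.detect_emg_onset(
            emg_epochs.data[t, 0], recording.srate, onset_params,
            window=config.epochs.window_ms,
        )
        trials.append(_emg.TrialRecord(
            trial_id=t, condition=ev.condition or "",
            stimulus_sample=ev.sample, emg_onset_ms=onset,
        ))
    trials = _emg.compute_vmrt(trials, recording.events, recording.srate)
    trials = _emg.apply_onset_exclusion(trials, config.onset.min_onset_ms)
    trials = _merge_eeg_flags_into_trials(epochs, trials)
    trials = _emg.apply_behavioral_filters(
        trials,
        vmrt_range=config.behavior.vmrt_range_ms,
        z_thresh=config.behavior.outlier_z,
        min_trials=config.behavior.min_trials,
    )
    epochs = _merge_trial_flags_into_epochs(epochs, trials)

    # --- CSD ---------------------------------------------------------------
    if not config.csd.bypass:
        eeg_labels = [lb for lb, k in zip(epochs.channel_labels,
                                          epochs.channel_kinds) if k == "eeg"]
        sub = montage.subset(eeg_labels)
        params = _csd.SplineParams(config.csd.m, config.csd.legendre_terms,
                                   config.csd.lam, config.csd.head_radius)
        op = _csd.build_operator(sub, params)
        eeg_idx = [epochs.channel_index(lb) for lb in eeg_labels]
        data = epochs.data.copy()
        data[:, eeg_idx, :] = op.apply(data[:, eeg_idx, :], channel_axis=1)
        epochs = epochs.copy_with(data=data)

    # --- components per condition ------------------------------------------
    forced_roi = None
    if config.mt_roi == "MT_standard":
        forced_roi = _erp.MT_STANDARD
    elif config.mt_roi == "MT_anterior":
        forced_roi = _erp.MT_ANTERIOR
    peaks_by_cond = {}
    mt_used = None
    conditions = list(dict.fromkeys(epochs.conditions))
    for cond in conditions:
        mask = epochs.conditions == cond
        sub_epochs = epochs.subset(mask)
        onsets = {}
        for new, old in enumerate(np.nonzero(mask)[0]):
            rec = trials[old]
            if rec.include and rec.emg_onset_ms is not None:
                onsets[new] = rec.emg_onset_ms
        peaks, roi = _erp.measure_components(sub_epochs, onsets,
                                             mt_roi=forced_roi)
        peaks_by_cond[cond] = peaks
        mt_used = roi.name
        for p in peaks:
            log.debug("subject component %s/%s: %.1f ms, %.2f",
                      cond, p.component, p.latency_ms, p.amplitude)

    # --- bookkeeping --------------------------------------------------------
    counts = []
    for cond in conditions:
        idx = [t for t, ev in enumerate(stims) if (ev.condition or "") == cond]
        row = {"condition": cond, "n_trials": len(idx),
               "included": sum(trials[t].include for t in idx)}
        for reason in _pre.REASONS[:-1]:
            row[reason] = 0
        for t in idx:
            rec = trials[t]
            if rec.include:
                continue
            first = next(r for r in _pre.REASONS if r in rec.exclusion_reasons)
            row[first] += 1
        counts.append(row)
    counts = pd.DataFrame(counts)

    subject_id = getattr(recording, "subject_id", "")
    return SubjectResult(
        subject_id=subject_id,
        trials=_emg.trials_to_frame(trials),
        components=_erp.peaks_to_frame(peaks_by_cond),
        rejection=report.to_frame(),
        mt_roi=mt_used,
        exclusion_counts=counts,
        behavioral=_emg.condition_summary(trials),
    )


# --------------------------------------------------------------------------
# Cohort level
# --------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Group-level statistics over a cohort of subject results."""

    parameters: pd.DataFrame         # subject x condition x 13 parameters
    summary: pd.DataFrame            # per-condition mean (SD) table
    paired_tests: pd.DataFrame       # fast vs slow with FDR-adjusted p
    correlations: pd.DataFrame       # ERP parameter x outcome Pearson r
    screened: dict                   # condition -> screened predictor names
    regressions: dict                # (outcome, condition) -> RegressionResult
    n_subjects: int = 0

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, RegressionResult):
                return {k: v for k, v in o.__dict__.items() if k != "step_log"}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            raise TypeError(type(o))

        payload = {
            "n_subjects": self.n_subjects,
            "summary": self.summary,
            "paired_tests": self.paired_tests,
            "correlations": self.correlations,
            "screened": self.screened,
            "regressions": {f"{k[0]}::{k[1]}": v
                            for k, v in self.regressions.items()},
        }
        return json.dumps(payload, default=enc, indent=2)


def cohort_parameters(results) -> pd.DataFrame:
    rows = []
    for res in results:
        for cond in res.behavioral["condition"]:
            rows.append(res.parameter_row(cond))
    return pd.DataFrame(rows)


def run_cohort(results_or_params, config: PipelineConfig | None = None) -> CohortResult:
    """Group statistics from subject results (or a precomputed parameter
    table with columns subject_id, condition, and the 13 parameters)."""
    if isinstance(results_or_params, pd.DataFrame):
        params = results_or_params.copy()
        n_sub = params["subject_id"].nunique()
    else:
        results = list(results_or_params)
        if len(results) < 3:
            raise QualityError("cohort statistics need >= 3 usable subjects")
        params = cohort_parameters(results)
        n_sub = len(results)

    conditions = sorted(params["condition"].unique())
    if set(conditions) != {"slow", "fast"}:
        raise MotionErpError("cohort statistics expect 'slow' and 'fast' conditions")

    wide = params.pivot(index="subject_id", columns="condition")

    # summary table
    srows = []
    for cond in ("slow", "fast"):
        row = {"condition": cond}
        for p in TABLE1_PARAMS:
            col = wide[(p, cond)]
            row[f"{p}_mean"] = col.mean()
            row[f"{p}_sd"] = col.std()
        srows.append(row)
    summary = pd.DataFrame(srows)

    # paired tests (fast - slow), FDR across the 13-parameter family
    tests = []
    for p in TABLE1_PARAMS:
        a = wide[(p, "fast")].to_numpy(dtype=float)
        b = wide[(p, "slow")].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        res = paired_ttest(a[ok], b[ok], variable=p)
        tests.append({"parameter": p, "t": res.t, "df": res.df,
                      "p_raw": res.p_raw, "d": res.d, "n": res.n})
    tests = pd.DataFrame(tests)
    tests["p_fdr"] = fdr_adjust(tests["p_raw"].to_numpy())

    # Pearson screening and stepwise regression per condition (screening
    # needs >= 4 complete pairs; a 3-subject cohort still gets the paired
    # tests and summary, with the regression block left empty)
    corr_rows, screened_map, regressions = [], {}, {}
    for cond in ("slow", "fast") if n_sub >= 4 else ():
        pred = pd.DataFrame({p: wide[(p, cond)] for p in _ERP_PARAMS})
        outc = pd.DataFrame({o: wide[(o, cond)] for o in ("emg_onset", "vmrt")})
        pred = pred.dropna(axis=1, how="any")
        corrs, screened, dropped = pearson_screen(pred, outc)
        for c in corrs:
            corr_rows.append({"condition": cond, "predictor": c.predictor,
                              "outcome": c.outcome, "r": c.r, "p": c.p,
                              "n": c.n})
        if screened:
            kept, _tol = check_collinearity(pred[screened])
        else:
            kept = []
        screened_map[cond] = kept
        for outcome in ("emg_onset", "vmrt"):
            if kept:
                reg = stepwise_forward(outc[outcome].to_numpy(dtype=float),
                                       pred[kept], outcome_name=outcome)
            else:
                reg = stepwise_forward(outc[outcome].to_numpy(dtype=float),
                                       pred[[]], outcome_name=outcome)
            regressions[(outcome, cond)] = reg

    return CohortResult(
        parameters=params,
        summary=summary,
        paired_tests=tests,
        correlations=pd.DataFrame(corr_rows),
        screened=screened_map,
        regressions=regressions,
        n_subjects=n_sub,
    )


def run_cohort_recordings(recordings, config: PipelineConfig | None = None,
                          montage: Montage | None = None) -> CohortResult:
    """Run the subject pipeline on an iterable of (recording, subject_id)
    or bare recordings, then the cohort statistics."""
    config = config or PipelineConfig()
    montage = montage or load_montage(config.montage)
    results = []
    for i, item in enumerate(recordings):
        rec, sid = item if isinstance(item, tuple) else (item, f"S{i + 1:02d}")
        res = run_subject(rec, config, montage)
        res.subject_id = sid
        results.append(res)
        log.info("subject %s done (%d/%d)", sid, i + 1, len(results))
    return run_cohort(results, config)


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def make_report(cohort: CohortResult, outdir, figures: bool = False,
                subject_results=None, assumptions: dict | None = None) -> dict:
    """Write the cohort report (TSV tables + JSON stats, optional figures).

    Returns a dict of written paths.  ``assumptions`` (seeds, config
    echoes) are stored in the JSON header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort.parameters.empty:
        raise MotionErpError("empty cohort; nothing to report")
    paths = {}
    for name, df in (
        ("parameters", cohort.parameters),
        ("summary", cohort.summary),
        ("paired_tests", cohort.paired_tests),
        ("correlations", cohort.correlations),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    stats_json = json.loads(cohort.to_json())
    if assumptions:
        stats_json["header"] = assumptions
    p = outdir / "stats.json"
    p.write_text(json.dumps(stats_json, indent=2))
    paths["stats"] = p

    if figures and subject_results:
        paths["figure"] = _grand_average_figure(subject_results, outdir)
    return paths


def _grand_average_figure(subject_results, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    comp = pd.concat([r.components for r in subject_results])
    for cond, g in comp.groupby("condition"):
        n2 = g[g["component"] == "N2"]
        ax.scatter(n2["latency_ms"], n2["amplitude"], label=f"N2 {cond}", s=12)
    ax.set_xlabel("latency (ms)")
    ax.set_ylabel("amplitude")
    ax.legend()
    ax.set_title("N2 peaks across subjects")
    path = outdir / "n2_peaks.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
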
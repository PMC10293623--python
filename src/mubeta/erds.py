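"""Event-related desynchronization/synchronization (ERD/S) quantification.

For each epoch and channel the band power time course is obtained by
zero-phase band-pass filtering and squaring; the ERD/S value is the relative
power change of the activation window A versus the pre-cue reference R:

    ERDS% = 100 * (A - R) / R

with R the mean band power over [-1.5, 0) s and A over [2, 6) s by default.
Negative values (ERD) mark power suppression, positive values (ERS) a power
increase. Channel-level values are averaged over trials per condition, then
over the channels of each region of interest (ROI), then over participants
per group for grand averages.

Time-frequency ERD/S maps use a Tukey-window spectrogram (segment length
250 samples, overlap 225 at 500 Hz -> 2 Hz x 50 ms resolution), averaged
over epochs and ROI channels, with each frequency row expressed as percent
change against its own pre-cue baseline bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .filters import bandpass
from .montage import DEFAULT_ROIS
from .preprocess import Epochs

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "participant", "group", "sex", "task", "band", "condition", "level", "erds_percent",
]


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: {self.lo} >= {self.hi}")


ALPHA = BandDef("alpha", 8.0, 13.0)
BETA = BandDef("beta", 16.0, 24.0)
DEFAULT_BANDS = (ALPHA, BETA)


@dataclass
class TFMap:
    roi: str
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, relative to cue onset (bin centres)
    values: np.ndarray  # (n_freqs, n_times), percent change vs. baseline


def erds_per_epoch(
    epochs: Epochs,
    band: BandDef,
    ref_window: tuple[float, float] = (-1.5, 0.0),
    act_window: tuple[float, float] = (2.0, 6.0),
) -> np.ndarray:
    """ERD/S (%) per kept epoch and channel; shape (n_kept, n_channels).

    Windows are half-open [start, stop) and must lie within the epoch. Cells
    with zero reference power are reported as NaN with a warning rather than
    silently dropped.
    """
    times = epochs.times
    for name, (a, b) in (("ref", ref_window), ("act", act_window)):
        if a < epochs.tmin or b > epochs.tmax or a >= b:
            raise ValueError(f"{name} window {(a, b)} outside epoch [{epochs.tmin}, {epochs.tmax})")
    data = epochs.data[epochs.kept]
    if data.shape[0] == 0:
        return np.empty((0, data.shape[1]))
    power = bandpass(data, epochs.fs, band.lo, band.hi) ** 2
    ref_mask = (times >= ref_window[0]) & (times < ref_window[1])
    act_mask = (times >= act_window[0]) & (times < act_window[1])
    R = power[:, :, ref_mask].mean(axis=-1)
    A = power[:, :, act_mask].mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * (A - R) / R
    bad = R == 0
    if bad.any():
        logger.warning("zero reference power in %d epoch/channel cells -> NaN", bad.sum())
        out[bad] = np.nan
    return out


def erds_trial_average(
    epochs: Epochs,
    band: BandDef,
    ref_window: tuple[float, float] = (-1.5, 0.0),
    act_window: tuple[float, float] = (2.0, 6.0),
    trial_mask: np.ndarray | None = None,
) -> np.ndarray:
    """ERD/S (%) per channel from trial-averaged band powers.

    Band power is averaged over kept trials *before* taking the A/R ratio
    (the classical ERD estimator). Unlike the mean of per-epoch ratios, its
    expectation equals the true relative power change, so this is the
    estimator of choice for ground-truth recovery on simulated data.
    ``trial_mask`` optionally restricts the kept trials (e.g. one condition).
    """
    times = epochs.times
    data = epochs.data[epochs.kept]
    if trial_mask is not None:
        data = data[np.asarray(trial_mask)]
    if data.shape[0] == 0:
        raise ValueError("no trials selected")
    power = bandpass(data, epochs.fs, band.lo, band.hi) ** 2
    ref_mask = (times >= ref_window[0]) & (times < ref_window[1])
    act_mask = (times >= act_window[0]) & (times < act_window[1])
    R = power[:, :, ref_mask].mean(axis=(0, 2))
    A = power[:, :, act_mask].mean(axis=(0, 2))
    return 100.0 * (A - R) / R


def mean_erds_by_condition(
    values: np.ndarray,
    conditions: np.ndarray,
    expected: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Mean ERD/S per condition over trials; values is (n_trials, n_channels).

    If ``expected`` condition labels are given, a condition without any kept
    trial raises a missing-cell error naming it.
    """
    conditions = np.asarray(conditions)
    if len(conditions) != len(values):
        raise ValueError("condition labels and value rows disagree")
    if expected is not None:
        missing = [c for c in expected if not (conditions == c).any()]
        if missing:
            raise ValueError(f"no kept trials for condition(s) {missing}")
    out: dict[str, np.ndarray] = {}
    for cond in np.unique(conditions):
        out[str(cond)] = values[conditions == cond].mean(axis=0)
    return out


def roi_means(channel_table: pd.DataFrame, rois: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Aggregate a channel-level ERD/S table to ROI level (unweighted mean).

    The input is tidy with a ``level`` column holding channel labels; the
    output replaces it with ROI names. A ROI channel missing from the table
    raises, naming both.
    """
    rois = DEFAULT_ROIS if rois is None else rois
    keys = [c for c in TABLE_COLUMNS if c not in ("level", "erds_percent")]
    rows = []
    for group_key, sub in channel_table.groupby(keys, sort=False):
        present = set(sub["level"])
        for roi, channels in rois.items():
            missing = [ch for ch in channels if ch not in present]
            if missing:
                raise ValueError(f"ROI {roi!r} is missing channels {missing}")
            mean = sub.loc[sub["level"].isin(channels), "erds_percent"].mean()
            rows.append(dict(zip(keys, group_key), level=roi, erds_percent=mean))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def erds_table_for_participant(
    epochs: Epochs,
    participant: str,
    group: str,
    sex: str,
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
    ref_window: tuple[float, float] = (-1.5, 0.0),
    act_window: tuple[float, float] = (2.0, 6.0),
) -> pd.DataFrame:
    """Channel-level ERD/S table rows for one participant, split by task,
    band and condition."""
    rows = []
    kept_task = epochs.task[epochs.kept]
    kept_cond = epochs.condition[epochs.kept]
    for band in bands:
        values = erds_per_epoch(epochs, band, ref_window, act_window)
        for task in np.unique(kept_task):
            tmask = kept_task == task
            means = mean_erds_by_condition(values[tmask], kept_cond[tmask])
            for cond, per_channel in means.items():
                for ch, v in zip(epochs.channel_labels, per_channel):
                    if epochs.channel_kinds[epochs.channel_labels.index(ch)] != "EEG":
                        continue
                    rows.append(
                        dict(
                            participant=participant, group=group, sex=sex,
                            task=str(task), band=band.name, condition=cond,
                            level=ch, erds_percent=float(v),
                        )
                    )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def grand_average(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over participants within each group."""
    keys = ["group", "task", "band", "condition", "level"]
    return table.groupby(keys, sort=False, as_index=False)["erds_percent"].mean()


def tf_erds(
    epochs: Epochs,
    roi: str,
    roi_channels: list[str] | None = None,
    segment_length: int = 250,
    overlap: int = 225,
    window: str | tuple = ("tukey", 0.25),
    fmin: float = 1.0,
    fmax: float = 35.0,
    trange: tuple[float, float] = (-1.5, 7.0),
    baseline: tuple[float, float] = (-1.5, 0.0),
) -> TFMap:
    """Baseline-normalised time-frequency ERD/S map for one ROI.

    A one-sided power spectrogram is computed per kept epoch and ROI channel,
    averaged over epochs then channels, and each frequency row is converted
    to percent change relative to its mean over time bins whose centres fall
    in ``baseline``.
    """
    if roi_channels is None:
        roi_channels = DEFAULT_ROIS[roi]
    if overlap >= segment_length:
        raise ValueError("overlap must be smaller than segment_length")
    times = epochs.times
    if trange[0] < epochs.tmin or trange[1] > epochs.tmax:
        raise ValueError(f"trange {trange} outside epoch bounds [{epochs.tmin}, {epochs.tmax})")
    tmask = (times >= trange[0]) & (times < trange[1])
    if tmask.sum() < segment_length:
        raise ValueError("trange too short for the requested segment length")
    ch_idx = [epochs.channel_labels.index(ch) for ch in roi_channels]
    data = epochs.data[epochs.kept][:, ch_idx][:, :, tmask]

    freqs, seg_times, Sxx = signal.spectrogram(
        data, fs=epochs.fs, window=window, nperseg=segment_length,
        noverlap=overlap, scaling="spectrum", mode="psd", detrend=False,
    )
    mean_map = Sxx.mean(axis=(0, 1))  # epochs then channels
    centres = trange[0] + seg_times
    fsel = (freqs >= fmin) & (freqs <= fmax)
    mean_map = mean_map[fsel]
    base_mask = (centres >= baseline[0]) & (centres < baseline[1])
    if not base_mask.any():
        raise ValueError("no spectrogram bins fall inside the baseline window")
    base = mean_map[:, base_mask].mean(axis=1, keepdims=True)
    values = 100.0 * (mean_map - base) / base
    return TFMap(roi=roi, freqs=freqs[fsel], times=centres, values=values)
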
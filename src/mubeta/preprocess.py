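"""EEG cleaning chain: channel repair, re-referencing, ocular-artifact
removal, zero-phase band-pass filtering, epoching and amplitude rejection.

The canonical order, applied by :func:`preprocess_raw`, is

    flat-channel interpolation -> average reference -> ocular-component
    removal -> 1-40 Hz FIR -> epoch extraction -> peak-to-peak rejection.

Ocular components are removed by a deterministic rule (absolute Pearson
correlation of an independent component with an EOG channel above a
threshold) rather than by manual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import spline
from .filters import design_fir, filter_zero_phase
from .montage import positions_array
from .simulate import RawRecording

logger = logging.getLogger(__name__)


@dataclass
class Epochs:
    """Cue-locked trials: (n_trials, n_channels, n_samples) in microvolts.

    Time axis is the half-open window [tmin, tmax) relative to cue onset,
    so ``n_samples = round((tmax - tmin) * fs)`` exactly.
    """

    data: np.ndarray
    fs: float
    tmin: float
    tmax: float
    condition: np.ndarray  # per-trial label
    task: np.ndarray  # per-trial "ME"/"MI"
    kept: np.ndarray  # per-trial bool mask
    channel_labels: list[str]
    channel_kinds: list[str]
    montage: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin + np.arange(n) / self.fs

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EEG"])

    def copy(self) -> "Epochs":
        return Epochs(
            self.data.copy(), self.fs, self.tmin, self.tmax,
            self.condition.copy(), self.task.copy(), self.kept.copy(),
            list(self.channel_labels), list(self.channel_kinds), dict(self.montage),
        )


@dataclass
class RejectionReport:
    n_total: int
    n_rejected: int
    threshold_uV: float
    ptp_uV: np.ndarray  # per-trial max peak-to-peak over EEG channels


@dataclass
class OcularReport:
    n_components: int
    removed: list[int]
    correlations: np.ndarray  # (n_components, n_eog) absolute Pearson r


def detect_flat_channels(raw: RawRecording, min_std_uV: float = 1e-2) -> list[str]:
    """Channels whose sample standard deviation falls below ``min_std_uV``."""
    if raw.data.size == 0:
        raise ValueError("empty recording")
    stds = raw.data.std(axis=1)
    return [raw.channel_labels[i] for i in np.flatnonzero(stds < min_std_uV)]


def interpolate_spherical_spline(raw: RawRecording, bad: list[str]) -> RawRecording:
    """Replace bad EEG channels with their Perrin spherical-spline estimate.

    Interpolation weights depend only on the montage geometry; good channels
    (and EOG channels) are untouched.
    """
    out = raw.copy()
    if not bad:
        return out
    eeg = set(np.asarray(raw.channel_labels)[raw.eeg_indices])
    for ch in bad:
        if ch not in eeg:
            raise ValueError(f"bad channel {ch!r} is not an EEG channel")
    good = [raw.channel_labels[i] for i in raw.eeg_indices if raw.channel_labels[i] not in bad]
    if len(good) < 4:
        raise ValueError(f"only {len(good)} good EEG channels remain; need >= 4")
    W = spline.interpolation_weights(
        positions_array(good, raw.montage), positions_array(bad, raw.montage)
    )
    good_idx = [raw.channel_index(ch) for ch in good]
    bad_idx = [raw.channel_index(ch) for ch in bad]
    out.data[bad_idx] = W @ raw.data[good_idx]
    return out


def apply_average_reference(raw: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean over EEG channels from every EEG
    channel; EOG channels are left untouched. Idempotent."""
    eeg = raw.eeg_indices
    if len(eeg) < 2:
        raise ValueError("average reference needs >= 2 EEG channels")
    out = raw.copy()
    out.data[eeg] -= raw.data[eeg].mean(axis=0, keepdims=True)
    return out


def bandpass_fir(raw: RawRecording, l_freq: float = 1.0, h_freq: float = 40.0) -> RawRecording:
    """Zero-phase windowed-sinc band-pass of all channels."""
    out = raw.copy()
    out.data = filter_zero_phase(raw.data, design_fir(raw.fs, l_freq, h_freq))
    return out


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows of a (n, t) and rows of b (m, t) -> (n, m)."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ b.T) / np.outer(na, nb)
    return np.abs(np.nan_to_num(r))


def remove_ocular_components(
    raw: RawRecording,
    eog_labels: tuple[str, ...] = ("EOGV", "EOGH"),
    corr_threshold: float = 0.7,
    n_components: int = 20,
    random_state: int = 0,
    max_fit_samples: int = 30_000,
) -> tuple[RawRecording, OcularReport]:
    """FastICA-based removal of eye-movement components.

    The decomposition is fitted on a 1 Hz high-passed copy of the EEG (on a
    uniform subsample of at most ``max_fit_samples`` time points for speed);
    component time courses are then computed on the full-length data.
    Components whose absolute Pearson correlation with any high-passed EOG
    channel reaches ``corr_threshold`` have their contribution subtracted.
    """
    from sklearn.decomposition import FastICA

    eog_idx = [raw.channel_index(ch) for ch in eog_labels]
    if not eog_idx:
        raise ValueError("no EOG channels given")
    eeg_idx = raw.eeg_indices
    X = raw.data[eeg_idx]  # (n_eeg, t)

    hp = filter_zero_phase(np.vstack([X, raw.data[eog_idx]]), design_fir(raw.fs, 1.0, None))
    X_hp, eog_hp = hp[: len(eeg_idx)], hp[len(eeg_idx):]

    # average reference (applied upstream) leaves the EEG rank-deficient by
    # one, so keep n_components below the channel count
    n_components = min(n_components, len(eeg_idx) - 1)
    step = max(1, X_hp.shape[1] // max_fit_samples)
    ica = FastICA(
        n_components=n_components, whiten="unit-variance",
        max_iter=500, tol=1e-3, random_state=random_state,
    )
    try:
        ica.fit(X_hp[:, ::step].T)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "ICA decomposition failed (rank-deficient data?); consider dropping "
            "flat channels or reducing n_components"
        ) from err

    # full-length sources of the high-passed data, for the correlation rule
    S_hp = (X_hp - ica.mean_[:, None]).T @ ica.components_.T  # (t, n_comp)
    corr = _pearson_matrix(S_hp.T, eog_hp)
    removed = sorted(np.flatnonzero((corr >= corr_threshold).any(axis=1)).tolist())

    out = raw.copy()
    if removed:
        # project the *unfiltered* data onto the removed components and subtract
        S_full = (X - X.mean(axis=1, keepdims=True)).T @ ica.components_.T
        out.data[eeg_idx] = (
            X - (S_full[:, removed] @ ica.mixing_[:, removed].T).T
        )
    report = OcularReport(n_components=n_components, removed=removed, correlations=corr)
    return out, report


def extract_epochs(raw: RawRecording, tmin: float = -2.0, tmax: float = 7.0) -> Epochs:
    """Cut cue-locked epochs over the half-open window [tmin, tmax).

    Events too close to a recording edge are dropped with a logged warning.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    n_samp = int(round((tmax - tmin) * raw.fs))
    blocks, conds, tasks = [], [], []
    for ev in raw.events:
        start = ev.sample_index + int(round(tmin * raw.fs))
        stop = start + n_samp
        if start < 0 or stop > raw.data.shape[1]:
            logger.warning(
                "dropping event at sample %d (%s/%s): epoch window outside recording",
                ev.sample_index, ev.task, ev.condition,
            )
            continue
        blocks.append(raw.data[:, start:stop])
        conds.append(ev.condition)
        tasks.append(ev.task)
    data = np.stack(blocks) if blocks else np.empty((0, raw.data.shape[0], n_samp))
    return Epochs(
        data=data, fs=raw.fs, tmin=tmin, tmax=tmax,
        condition=np.array(conds, dtype=object), task=np.array(tasks, dtype=object),
        kept=np.ones(len(blocks), dtype=bool),
        channel_labels=list(raw.channel_labels), channel_kinds=list(raw.channel_kinds),
        montage=dict(raw.montage),
    )


def reject_by_ptp(epochs: Epochs, threshold_uV: float = 120.0) -> tuple[Epochs, RejectionReport]:
    """Mark epochs whose maximum EEG peak-to-peak amplitude exceeds the
    threshold as rejected. EOG channels do not enter the criterion."""
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    out = epochs.copy()
    eeg = epochs.eeg_indices
    if epochs.n_trials:
        ptp = (epochs.data[:, eeg].max(axis=2) - epochs.data[:, eeg].min(axis=2)).max(axis=1)
    else:
        ptp = np.empty(0)
    out.kept = epochs.kept & (ptp <= threshold_uV)
    report = RejectionReport(
        n_total=epochs.n_trials,
        n_rejected=int(epochs.n_trials - out.kept.sum()),
        threshold_uV=threshold_uV,
        ptp_uV=ptp,
    )
    return out, report


def preprocess_raw(
    raw: RawRecording,
    flat_std_uV: float = 1e-2,
    l_freq: float = 1.0,
    h_freq: float = 40.0,
    corr_threshold: float = 0.7,
    skip_ica: bool = False,
    tmin: float = -2.0,
    tmax: float = 7.0,
    ptp_threshold_uV: float = 120.0,
    ica_random_state: int = 0,
) -> tuple[Epochs, RejectionReport, dict]:
    """Run the full cleaning chain on one recording.

    Returns the rejected-marked epochs, the rejection report, and a log dict
    recording interpolated channels and removed ICA components.
    """
    info: dict = {}
    bad = detect_flat_channels(raw, flat_std_uV)
    info["interpolated"] = bad
    stage = interpolate_spherical_spline(raw, bad)
    stage = apply_average_reference(stage)
    if skip_ica:
        info["ica_removed"] = []
    else:
        stage, ocular = remove_ocular_components(
            stage, corr_threshold=corr_threshold, random_state=ica_random_state
        )
        info["ica_removed"] = ocular.removed
        info["ica_correlations"] = ocular.correlations.max(axis=1).round(3).tolist()
    stage = bandpass_fir(stage, l_freq, h_freq)
    epochs = extract_epochs(stage, tmin, tmax)
    epochs, report = reject_by_ptp(epochs, ptp_threshold_uV)
    info["rejected_indices"] = np.flatnonzero(~epochs.kept).tolist()
    return epochs, report, info
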
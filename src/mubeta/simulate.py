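"""Synthetic EEG cohorts for a cued motor-execution / motor-imagery paradigm.

The generator reproduces the structure of a ball-squeezing study: runs of 30
cued trials (10 per condition LEFT/RIGHT/BOTH, randomised), each trial being
2 s fixation, 7 s cue and a 3-5 s jittered break, recorded from 32 scalp
channels plus two EOG channels at 500 Hz.

Signals are built from three ingredients:

* 1/f background noise per channel,
* band-limited mu (8-13 Hz) and beta (16-24 Hz) rhythms — Gaussian noise
  filtered into the band — whose amplitude is scaled by sqrt(g) during the
  activation window of each trial, so the injected event-related power change
  is exactly ``(g - 1) * 100`` percent,
* optional blink transients projected onto frontal channels and the EOG pair.

Everything is a pure function of the seeds, which makes the full pipeline's
parameter recovery testable against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .filters import bandpass
from .montage import ALL_CHANNELS, EEG_CHANNELS, EOG_CHANNELS, default_montage, hemisphere_of

CONDITIONS = ("LEFT", "RIGHT", "BOTH")
TASKS = ("ME", "MI")

#: Trial timing (seconds): fixation cross, cue presentation, pre-run lead-in.
FIXATION_S = 2.0
CUE_S = 7.0
PRE_RUN_S = 5.0

#: Activation window of the injected power modulation, relative to cue onset.
ACTIVATION_WINDOW_S = (2.0, 6.0)
RAMP_S = 0.25


@dataclass(frozen=True)
class TrialEntry:
    run_index: int
    task: str  # "ME" | "MI"
    condition: str  # "LEFT" | "RIGHT" | "BOTH"
    cue_onset_s: float  # seconds from run start
    break_s: float


@dataclass(frozen=True)
class TrialSchedule:
    entries: tuple[TrialEntry, ...]

    @property
    def n_runs(self) -> int:
        return 1 + max(e.run_index for e in self.entries)

    def run_entries(self, run_index: int) -> list[TrialEntry]:
        return [e for e in self.entries if e.run_index == run_index]

    def run_duration_s(self, run_index: int) -> float:
        last = self.run_entries(run_index)[-1]
        return last.cue_onset_s + CUE_S + last.break_s


@dataclass(frozen=True)
class EventMarker:
    sample_index: int
    run_index: int
    task: str
    condition: str


@dataclass
class RawRecording:
    """Continuous multichannel recording (microvolts) with event markers."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_labels: list[str]
    channel_kinds: list[str]  # "EEG" | "EOG" per channel
    montage: dict[str, tuple[float, float, float]]
    events: list[EventMarker]
    meta: dict

    def copy(self) -> "RawRecording":
        return RawRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
            montage=dict(self.montage),
            events=list(self.events),
            meta=dict(self.meta),
        )

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EEG"])

    @property
    def eog_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EOG"])

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


def default_rhythm_amplitudes() -> dict[str, dict[str, float]]:
    """Baseline RMS amplitude (microvolts) of each rhythm per channel.

    Mu/alpha is strongest over the sensorimotor hand areas and the
    parieto-occipital cortex; beta is weaker and concentrated centrally.
    """
    central = {"FC1", "FC5", "C3", "CP1", "CP5", "FC2", "FC6", "C4", "CP2", "CP6"}
    posterior = {"P3", "P7", "O1", "P4", "P8", "O2", "Pz", "Oz"}
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    for ch in EEG_CHANNELS:
        if ch in central:
            alpha[ch], beta[ch] = 8.0, 4.0
        elif ch in posterior:
            alpha[ch], beta[ch] = 7.0, 1.5
        elif ch == "Cz":
            alpha[ch], beta[ch] = 6.0, 3.0
        else:
            alpha[ch], beta[ch] = 2.5, 1.5
    return {"alpha": alpha, "beta": beta}


def default_erd_profile() -> dict[tuple[str, str, str, str, str], float]:
    """Ground-truth power scaling g per (group, task, condition, band, hemisphere).

    The defaults encode the canonical sensorimotor picture: contralateral
    alpha suppression with mild ipsilateral enhancement for unimanual
    movement, bilateral suppression for bimanual movement, and broader but
    weaker beta suppression. Imagery mirrors execution.
    """
    profile: dict[tuple[str, str, str, str, str], float] = {}
    for group in ("left", "right"):
        for task in TASKS:
            for band, (g_contra, g_ipsi, g_both) in {
                "alpha": (0.6, 1.15, 0.7),
                "beta": (0.75, 0.95, 0.8),
            }.items():
                profile[(group, task, "LEFT", band, "right")] = g_contra
                profile[(group, task, "LEFT", band, "left")] = g_ipsi
                profile[(group, task, "RIGHT", band, "left")] = g_contra
                profile[(group, task, "RIGHT", band, "right")] = g_ipsi
                profile[(group, task, "BOTH", band, "left")] = g_both
                profile[(group, task, "BOTH", band, "right")] = g_both
    return profile


def uniform_erd_profile(
    g: float, band: str = "alpha", hemisphere: str = "left"
) -> dict[tuple[str, str, str, str, str], float]:
    """Profile injecting one scaling g on a single band/hemisphere for every
    group, task and condition (all other cells stay at 1). Useful for
    parameter-recovery experiments on designated channels."""
    profile = {key: 1.0 for key in default_erd_profile()}
    for group in ("left", "right"):
        for task in TASKS:
            for cond in CONDITIONS:
                profile[(group, task, cond, band, hemisphere)] = g
    return profile


@dataclass
class SimulationConfig:
    """All knobs of the generative model; defaults follow the study paradigm."""

    fs: float = 500.0
    n_runs: int = 6
    trials_per_condition: int = 10
    jitter_range: tuple[float, float] = (3.0, 5.0)
    first_task: str = "alternate"  # "ME" | "MI" | "alternate" (across cohort)
    montage: dict[str, tuple[float, float, float]] = field(default_factory=default_montage)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (8.0, 13.0), "beta": (16.0, 24.0)}
    )
    rhythm_amplitudes: dict[str, dict[str, float]] = field(
        default_factory=default_rhythm_amplitudes
    )
    erd_profile: dict[tuple[str, str, str, str, str], float] = field(
        default_factory=default_erd_profile
    )
    noise_psd_exponent: float = 1.0
    noise_rms_uv: float = 5.0
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        f_hi = max(hi for _, hi in self.bands.values())
        if self.fs <= 2 * f_hi:
            raise ValueError(f"fs={self.fs} must exceed twice the highest rhythm edge {f_hi}")
        for key, g in self.erd_profile.items():
            if g <= 0:
                raise ValueError(f"erd_profile gain must be positive, got {g} for {key}")
        for band, per_ch in self.rhythm_amplitudes.items():
            if band not in self.bands:
                raise ValueError(f"rhythm amplitudes reference unknown band {band!r}")
            for ch in per_ch:
                if ch not in self.montage:
                    raise ValueError(f"rhythm channel {ch!r} missing from montage")
        if self.first_task not in TASKS + ("alternate",):
            raise ValueError(f"first_task must be 'alternate' or one of {TASKS}")


def build_schedule(
    n_runs: int,
    trials_per_condition: int,
    jitter_range: tuple[float, float] = (3.0, 5.0),
    seed: int = 0,
    first_task: str = "ME",
) -> TrialSchedule:
    """Randomised trial schedule: per run, an exact permutation of
    ``trials_per_condition`` trials of each condition with uniformly jittered
    breaks; runs alternate between ME and MI tasks."""
    if n_runs < 1 or trials_per_condition < 1:
        raise ValueError("n_runs and trials_per_condition must be >= 1")
    lo, hi = jitter_range
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid jitter range {jitter_range}")
    if first_task not in TASKS:
        raise ValueError(f"first_task must be one of {TASKS}")

    rng = np.random.default_rng(seed)
    other = "MI" if first_task == "ME" else "ME"
    entries: list[TrialEntry] = []
    for run in range(n_runs):
        task = first_task if run % 2 == 0 else other
        conditions = np.repeat(np.array(CONDITIONS), trials_per_condition)
        rng.shuffle(conditions)
        breaks = rng.uniform(lo, hi, size=len(conditions))
        t = PRE_RUN_S
        for cond, brk in zip(conditions, breaks):
            cue_onset = t + FIXATION_S
            entries.append(TrialEntry(run, task, str(cond), cue_onset, float(brk)))
            t = cue_onset + CUE_S + brk
    return TrialSchedule(tuple(entries))


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-flattened below 1 Hz."""
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n_samples, real=True)
    white = rng.standard_normal((n_channels, n_fft))
    spec = rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    shape = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = irfft(spec * shape, n=n_fft, axis=-1)[:, :n_samples]
    x *= rms / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise; last axis is time."""
    x = bandpass(rng.standard_normal(shape), fs, lo, hi)
    return x / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))


def _gain_envelope(n_samples: int, fs: float, cue_samples: list[int],
                   gains: list[float]) -> np.ndarray:
    """Amplitude envelope: 1 at baseline, sqrt(g) on the activation plateau.

    The plateau covers [cue+2, cue+6] s exactly; 250 ms cosine ramps sit just
    outside it so that the expected band-power ratio over the activation
    window equals g without ramp bias.
    """
    env = np.ones(n_samples)
    t_act0, t_act1 = ACTIVATION_WINDOW_S
    n_ramp = int(round(RAMP_S * fs))
    ramp_up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    for cue, g in zip(cue_samples, gains):
        a = np.sqrt(g)
        i0 = cue + int(round(t_act0 * fs))
        i1 = cue + int(round(t_act1 * fs))
        up0 = max(i0 - n_ramp, 0)
        env[up0:i0] = 1 + (a - 1) * ramp_up[n_ramp - (i0 - up0):]
        env[i0:i1] = a
        dn1 = min(i1 + n_ramp, n_samples)
        env[i1:dn1] = a + (1 - a) * ramp_up[: dn1 - i1]
    return env


def _blink_template(fs: float) -> np.ndarray:
    """300 ms biphasic eyelid transient, zero at both ends."""
    t = np.arange(int(round(0.3 * fs))) / fs
    return np.sin(2 * np.pi * t / 0.3) * np.sin(np.pi * t / 0.3)


def _blink_weights(config: SimulationConfig, labels: list[str]) -> np.ndarray:
    """Per-channel projection of the ocular source: exponential fall-off with
    angular distance from the nearer of Fp1/Fp2; fixed large weights on EOG."""
    from .montage import positions_array

    pos = positions_array(labels, config.montage)
    fp = positions_array(["Fp1", "Fp2"], config.montage)
    cosang = np.clip(pos @ fp.T, -1, 1)
    dist = np.arccos(cosang).min(axis=1)
    w = 0.8 * np.exp(-2.5 * dist)
    for i, ch in enumerate(labels):
        if ch == "EOGV":
            w[i] = 1.0
        elif ch == "EOGH":
            w[i] = 0.6
    return w


def simulate_participant(
    config: SimulationConfig,
    schedule: TrialSchedule,
    participant_seed: int,
    group: str = "right",
    participant_id: str = "P000",
    sex: str = "female",
) -> RawRecording:
    """Render one participant's recording from a schedule.

    Runs are rendered independently (rhythms, noise and blinks restart per
    run, as the study stopped the recording between runs) and concatenated,
    with event markers carrying run, task and condition.
    """
    config.validate()
    if not schedule.entries:
        raise ValueError("schedule is empty")
    if group not in ("left", "right"):
        raise ValueError("group must be 'left' or 'right'")
    fs = config.fs
    labels = ALL_CHANNELS
    kinds = ["EEG"] * len(EEG_CHANNELS) + ["EOG"] * len(EOG_CHANNELS)
    hemis = {ch: hemisphere_of(ch) for ch in labels}
    root = np.random.SeedSequence([participant_seed, config.seed])
    run_seeds = root.spawn(schedule.n_runs)

    run_blocks: list[np.ndarray] = []
    events: list[EventMarker] = []
    run_starts: list[int] = []
    offset = 0
    blink_tpl = _blink_template(fs) * config.blink_amplitude_uv
    blink_w = _blink_weights(config, labels)

    for run in range(schedule.n_runs):
        rng = np.random.default_rng(run_seeds[run])
        run_trials = schedule.run_entries(run)
        n_samples = int(np.ceil(schedule.run_duration_s(run) * fs))
        task = run_trials[0].task
        cue_samples = [int(round(e.cue_onset_s * fs)) for e in run_trials]

        data = _one_over_f_noise(
            rng, len(labels), n_samples, fs, config.noise_psd_exponent, config.noise_rms_uv
        )

        for band, (lo, hi) in config.bands.items():
            amps = config.rhythm_amplitudes.get(band, {})
            # one envelope per hemisphere; midline channels stay unmodulated
            envs = {}
            for hemi in ("left", "right"):
                gains = [
                    config.erd_profile.get((group, task, e.condition, band, hemi), 1.0)
                    for e in run_trials
                ]
                envs[hemi] = _gain_envelope(n_samples, fs, cue_samples, gains)
            envs["mid"] = np.ones(n_samples)
            active = [
                (ci, ch) for ci, ch in enumerate(labels)
                if kinds[ci] == "EEG" and amps.get(ch, 0.0) > 0
            ]
            if not active:
                continue
            noise = _band_noise(rng, (len(active), n_samples), fs, lo, hi)
            for (ci, ch), x in zip(active, noise):
                data[ci] += amps[ch] * envs[hemis[ch]] * x

        if config.blink_rate_per_min > 0:
            n_blinks = rng.poisson(config.blink_rate_per_min * n_samples / fs / 60.0)
            starts = rng.integers(0, max(n_samples - len(blink_tpl), 1), size=n_blinks)
            source = np.zeros(n_samples)
            for s in starts:
                source[s : s + len(blink_tpl)] += blink_tpl[: n_samples - s]
            data += blink_w[:, None] * source[None, :]

        run_starts.append(offset)
        for e, cs in zip(run_trials, cue_samples):
            events.append(EventMarker(offset + cs, run, e.task, e.condition))
        run_blocks.append(data)
        offset += n_samples

    return RawRecording(
        data=np.concatenate(run_blocks, axis=1),
        fs=fs,
        channel_labels=list(labels),
        channel_kinds=kinds,
        montage=dict(config.montage),
        events=events,
        meta={
            "participant_id": participant_id,
            "group": group,
            "sex": sex,
            "run_starts": run_starts,
            "participant_seed": int(participant_seed),
        },
    )


def participant_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-participant seed derived from a cohort seed."""
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0] % (2**31))


def cohort_manifest(config: SimulationConfig, n_left: int, n_right: int,
                    cohort_seed: int):
    """Plan a cohort: ids, groups, alternating sex within group, alternating
    starting task across the cohort, and per-participant seeds."""
    import pandas as pd

    if n_left < 0 or n_right < 0:
        raise ValueError("cohort sizes must be non-negative")
    rows = []
    groups = ["left"] * n_left + ["right"] * n_right
    sex_counter = {"left": 0, "right": 0}
    for i, group in enumerate(groups):
        sex = ("female", "male")[sex_counter[group] % 2]
        sex_counter[group] += 1
        rows.append(
            {
                "participant_id": f"P{i + 1:03d}",
                "group": group,
                "sex": sex,
                "first_task": TASKS[i % 2] if config.first_task == "alternate" else config.first_task,
                "seed": participant_seed(cohort_seed, i),
            }
        )
    return pd.DataFrame(rows)


def iter_cohort(config: SimulationConfig, n_left: int, n_right: int, cohort_seed: int):
    """Yield (manifest_row, RawRecording) lazily — memory-friendly for large cohorts."""
    manifest = cohort_manifest(config, n_left, n_right, cohort_seed)
    for _, row in manifest.iterrows():
        cfg = config if row["first_task"] == config.first_task else replace(
            config, first_task=row["first_task"]
        )
        schedule = build_schedule(
            cfg.n_runs, cfg.trials_per_condition, cfg.jitter_range,
            seed=int(row["seed"]), first_task=row["first_task"],
        )
        rec = simulate_participant(
            cfg, schedule, int(row["seed"]), group=row["group"],
            participant_id=row["participant_id"], sex=row["sex"],
        )
        yield row, rec


def simulate_cohort(config: SimulationConfig, n_left: int, n_right: int,
                    cohort_seed: int):
    """Materialise a full cohort; returns (recordings, manifest DataFrame)."""
    manifest = cohort_manifest(config, n_left, n_right, cohort_seed)
    recordings = [rec for _, rec in iter_cohort(config, n_left, n_right, cohort_seed)]
    return recordings, manifest
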
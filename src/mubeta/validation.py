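"""End-to-end validation experiments on synthetic ground truth.

Each function runs a self-contained simulation through the actual pipeline
and returns the measured quantity: parameter recovery of injected ERD/S,
empirical type-I error of the mixed RM-ANOVA under a null, the stationary
behaviour of time-frequency maps, and the power of the full chain to detect
a contralateral-ERD interaction. They are the package's acceptance surface
and are deliberately cheap enough to run routinely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .erds import ALPHA, erds_table_for_participant, erds_trial_average, roi_means, tf_erds
from .montage import DEFAULT_ROIS
from .preprocess import preprocess_raw
from .report import long_design_from_roi_table
from .simulate import (
    SimulationConfig,
    build_schedule,
    default_rhythm_amplitudes,
    iter_cohort,
    simulate_participant,
    uniform_erd_profile,
)
from .stats import mixed_rm_anova, simulate_long_design


def _alpha_only_config(g: float, trials_per_condition: int) -> SimulationConfig:
    """Single-run, mu-rhythm-only recording with gain g injected on the left
    hemisphere for every condition (blinks off: effect isolation)."""
    return SimulationConfig(
        n_runs=1,
        trials_per_condition=trials_per_condition,
        first_task="MI",
        bands={"alpha": (8.0, 13.0)},
        rhythm_amplitudes={"alpha": default_rhythm_amplitudes()["alpha"]},
        erd_profile=uniform_erd_profile(g, band="alpha", hemisphere="left"),
        blink_rate_per_min=0.0,
    )


def erds_recovery(
    g: float,
    seed: int,
    trials_per_condition: int = 67,
    target_roi: str = "CL",
) -> dict:
    """Simulate ~3x``trials_per_condition`` trials with power scaling g on the
    left-hemisphere mu rhythm, run the full preprocessing + ERD/S chain, and
    return the recovered ERD/S (%) on the designated left-central channels.

    The generative ground truth is ``(g - 1) * 100`` percent.
    """
    config = _alpha_only_config(g, trials_per_condition)
    schedule = build_schedule(
        config.n_runs, trials_per_condition, config.jitter_range,
        seed=seed, first_task="MI",
    )
    rec = simulate_participant(config, schedule, participant_seed=seed + 1)
    epochs, report, _ = preprocess_raw(rec, skip_ica=True)
    values = erds_trial_average(epochs, ALPHA)
    idx = [epochs.channel_labels.index(ch) for ch in DEFAULT_ROIS[target_roi]]
    return {
        "recovered_percent": float(values[idx].mean()),
        "truth_percent": (g - 1.0) * 100.0,
        "n_trials": int(epochs.kept.sum()),
    }


def anova_null_type1(n_replicates: int, seed: int, n_per_cell: int = 7,
                     alpha_level: float = 0.05) -> dict:
    """Empirical rejection rate of the GG-corrected ROI main effect when the
    long design is drawn from a moderately nonspherical global null."""
    hits = 0
    for r in range(n_replicates):
        table = simulate_long_design(n_per_cell, seed=(seed * 1_000_003 + r) % 2**31)
        result = mixed_rm_anova(table)
        hits += result.effect("ROI")["p_gg"] < alpha_level
    return {"rate": hits / n_replicates, "n_replicates": n_replicates}


def tf_stationary_check(seed: int, trials_per_condition: int = 100,
                        roi: str = "CL") -> dict:
    """TF-map geometry plus the largest |ERD/S| of a stationary (g = 1)
    simulation over the map interior (time edges excluded)."""
    config = _alpha_only_config(1.0, trials_per_condition)
    schedule = build_schedule(1, trials_per_condition, config.jitter_range,
                              seed=seed, first_task="MI")
    rec = simulate_participant(config, schedule, participant_seed=seed + 7)
    epochs, _, _ = preprocess_raw(rec, skip_ica=True)
    tfm = tf_erds(epochs, roi)
    interior = (tfm.times > -1.0) & (tfm.times < 6.5)
    return {
        "freq_resolution_hz": float(tfm.freqs[1] - tfm.freqs[0]),
        "time_step_s": float(tfm.times[1] - tfm.times[0]),
        "max_abs_percent": float(np.abs(tfm.values[:, interior]).max()),
        "n_epochs": int(epochs.kept.sum()),
    }


def interaction_power(
    n_replicates: int,
    seed: int,
    n_left: int = 4,
    n_right: int = 4,
    trials_per_condition: int = 3,
    alpha_level: float = 0.05,
) -> dict:
    """Power of the full chain: simulate a small cohort with the default
    contralateral alpha-ERD profile, run simulate -> preprocess -> ERD/S ->
    RM-ANOVA, and count replicates with a significant ROI x Condition
    interaction in the MI / alpha analysis."""
    hits = 0
    for r in range(n_replicates):
        config = SimulationConfig(
            n_runs=1, trials_per_condition=trials_per_condition,
            first_task="MI", blink_rate_per_min=0.0,
        )
        tables = []
        for row, rec in iter_cohort(config, n_left, n_right,
                                    cohort_seed=(seed + 17 * r) % 2**31):
            epochs, _, _ = preprocess_raw(rec, skip_ica=True)
            tables.append(
                erds_table_for_participant(
                    epochs, row["participant_id"], row["group"], row["sex"],
                    bands=(ALPHA,),
                )
            )
        roi_table = roi_means(pd.concat(tables, ignore_index=True))
        design = long_design_from_roi_table(roi_table, "MI", "alpha")
        result = mixed_rm_anova(design)
        hits += result.effect("ROI*Condition")["p_gg"] < alpha_level
    return {"power": hits / n_replicates, "n_replicates": n_replicates}
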
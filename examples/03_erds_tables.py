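"""Compute ERD/S values: per epoch, per condition, and per region of interest.

ERD/S is the percent band-power change of the activation window (2-6 s after
the cue) against the pre-cue reference (-1.5-0 s): negative values (ERD) mean
power suppression, i.e. cortical activation. The simulated participant has
contralateral mu-rhythm suppression, so LEFT-hand trials should show ERD over
the right central ROI (CR) and vice versa.
"""

from mubeta import SimulationConfig, build_schedule, preprocess_raw, simulate_participant
from mubeta.erds import erds_table_for_participant, roi_means

config = SimulationConfig(n_runs=2, trials_per_condition=10, first_task="MI",
                          blink_rate_per_min=0.0)
schedule = build_schedule(2, 10, (3, 5), seed=8, first_task="MI")
rec = simulate_participant(config, schedule, participant_seed=80)
epochs, _, _ = preprocess_raw(rec, skip_ica=True)

channel_table = erds_table_for_participant(epochs, "P001", "right", "female")
rois = roi_means(channel_table)

mi_alpha = rois[(rois["task"] == "MI") & (rois["band"] == "alpha")]
print("MI / alpha ERD/S (%) per ROI and condition:")
print(mi_alpha.pivot(index="level", columns="condition", values="erds_percent")
      .round(1).to_string())
print("\nNegative = ERD (activation). Note CR < 0 for LEFT and CL < 0 for "
      "RIGHT: contralateral activation.")
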
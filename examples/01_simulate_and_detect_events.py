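"""Generate a small synthetic gaze dataset and recover its planted events.

Builds 10 trials at the 250 Hz / 10 s recording regime, runs blink /
fixation / saccade detection, and compares detected fixation counts with
the generator's ground truth.
"""

import gazeits as g

cfg = g.preset("switch_like", n_participants=1, trials_per_participant=10,
               seed=42)
ds = g.generate_dataset(cfg)

print("trial        planted_fix detected_fix blinks saccades")
exact = 0
for trial in ds.trials:
    ev = g.detect_events(trial)
    planted = len(ds.truth_for(trial.trial_id, "fixation"))
    exact += planted == len(ev.fixations)
    print(f"{trial.trial_id}  {planted:11d} {len(ev.fixations):12d} "
          f"{len(ev.blinks):6d} {len(ev.saccades):8d}")

print(f"\nexact fixation-count recovery: {exact}/10 trials")
print("Each row is one 10-s trial; detection uses the 50 ms blink and "
      "1-degree dispersion thresholds.")
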
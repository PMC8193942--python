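"""Train the SimpleNet CNN on image panels of a separable dataset.

Builds panels at 24 px for speed, trains on 4 of 5 participants and tests
on the held-out one (a miniature person-independent split).
"""

import numpy as np

import gazeits as g
from gazeits.cnn import CNNClassifier, TrainConfig, build_simplenet
from gazeits.events import EventConfig
from gazeits.pipeline import prepare_panel_stack

print("SimpleNet parameters at default 48 px input:",
      build_simplenet().n_params)

cfg = g.GeneratorConfig(sampling_rate_hz=60, trial_length_s=5,
                        n_participants=5, trials_per_participant=20,
                        effect_size=2.0, seed=11)
ds = g.generate_dataset(cfg)
stack, meta = prepare_panel_stack(ds.trials, EventConfig(),
                                  g.PanelConfig(image_size=24))
labels = meta["condition"].to_numpy()
test = (meta["participant_id"] == "p004").to_numpy()

clf = CNNClassifier("simplenet",
                    TrainConfig(epochs=10, batch_size=8, learning_rate=1e-3,
                                seed=0))
clf.fit(stack[~test], labels[~test])
acc = np.mean(clf.predict(stack[test]) == labels[test])
print(f"held-out participant accuracy: {acc:.2f} (chance = 0.5)")
print(f"final training loss: {clf.losses_[-1]:.3f}")
print("The CNN separates conditions from the panel images alone — the "
      "planted effect alters scanpath structure and fixation timing.")
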
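"""Train the CNN–LSTM confirmation classifier and evaluate the full pipeline.

Uses a reduced corpus and epoch count so the demo runs in seconds; the full
protocol (10 subjects, 70 epochs) is what scripts/acceptance.py executes.
The evaluation table mirrors the two-stage view: how many traces the 3 g
threshold flagged, and how many of those the classifier confirmed/rejected.
"""

import numpy as np

import fallkit as fk
from fallkit.classifier import ClassifierConfig, train

config = fk.SyntheticConfig(seed=1, n_subjects=5, falls_per_subject=6, adls_per_subject=8)
traces, _ = fk.generate_dataset(config)
patterns = fk.patterns_from_traces(traces)
train_p, val_p, test_p = fk.partition_by_subject(patterns, split=1, expected_subjects=5)

model = train(train_p, val_p, ClassifierConfig(seed=42, epochs=20))
print(f"trained on {len(train_p)} windows; "
      f"final val accuracy {model.history['val_accuracy'][-1]:.3f}")

X = np.stack([p.values for p in test_p])
y = np.array([p.label for p in test_p])
probs = model.predict_batch(X)
acc = np.mean((probs >= 0.5) == (y == 1))
print(f"held-out window accuracy: {100 * acc:.2f}% on {len(y)} windows "
      "from subjects never seen in training\n")

test_subjects = {p.subject_id for p in test_p}
report = fk.evaluate_pipeline([t for t in traces if t.subject_id in test_subjects], model)
print(report.format_tables())
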
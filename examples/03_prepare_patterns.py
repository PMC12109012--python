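"""Build the training corpus: generate traces, window them, split by subject.

Each fall trace contributes one 4-s window centered on its impact peak; each
ADL trace contributes up to three windows around its highest local maxima.
Windows are decimated to 20 Hz (80 samples) and split 6/2/2 by subject so no
subject leaks between train, validation and test.
"""

import fallkit as fk

traces, manifest = fk.generate_dataset(fk.SyntheticConfig(seed=0))
print(f"{len(traces)} traces from {len({t.subject_id for t in traces})} subjects "
      f"({sum(t.is_fall for t in traces)} falls, "
      f"{sum(not t.is_fall for t in traces)} ADLs)")

patterns = fk.patterns_from_traces(traces)
print(f"{len(patterns)} patterns "
      f"({sum(p.label for p in patterns)} fall windows, "
      f"{sum(1 - p.label for p in patterns)} ADL windows), 80 samples each")

train_p, val_p, test_p = fk.partition_by_subject(patterns, split=0)
for name, part in (("train", train_p), ("val", val_p), ("test", test_p)):
    subjects = sorted({p.subject_id for p in part})
    print(f"  {name:5s}: {len(part):3d} patterns from subjects {subjects}")
print("\nsubject-wise splitting is what makes the held-out accuracy an "
      "estimate for unseen wearers, not just unseen repetitions.")
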
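"""Simulate a multimodal session and recover trial labels from response times.

Builds a 10-participant synthetic dataset (350 trials) with the default RT
parameters, runs the moving-median + subject-specific-interval labeling
pipeline, and compares its Fast/Slow calls with the generator's ground
truth.  The agreement shows how much label noise the behavioral pipeline
itself introduces before any neural decoding happens.
"""

import numpy as np

from bmnabc import SynthConfig, generate_dataset, label_dataset

# small epochs: this example only exercises the behavioral (RT) pathway
cfg = SynthConfig(eeg_epoch_s=0.1, fnirs_epoch_s=2.0, seed=1)
ds = generate_dataset(cfg)
labels = label_dataset(ds)

fast = labels["label"] == "Fast"
agreement = float((labels["label"].to_numpy() == ds.true_label).mean())

print(f"trials: {ds.n_trials}  (true Fast: {(ds.true_label == 'Fast').sum()})")
print(f"labeled Fast: {int(fast.sum())}")
print(f"mean DRT of labeled-Fast trials: {labels.loc[fast, 'drt'].mean():.1f} ms")
print(f"mean URT overall:                {labels['urt'].mean():.1f} ms")
print(f"agreement with ground truth:     {agreement:.3f}")
print()
print("The DRT of Fast trials sits far below the ~1028 ms baseline because")
print("the fourth question's hidden rule has been implicitly learned; ~95%")
print("label agreement is the ceiling the RT pipeline passes downstream.")
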
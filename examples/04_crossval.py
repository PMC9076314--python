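"""Leave-one-trial-out evaluation of the full pipeline.

Filter (20-500 Hz band-pass + 50 Hz notch), 250 ms disjoint windows,
per-channel features, per-fold ULDA to 9 dimensions, then a classifier.
Reported metrics are macro averages over movements, mean ± SD over the
six folds, in percent.
"""

from myofeat import SynthConfig, generate_dataset, trialwise_cv

recs = generate_dataset(SynthConfig(seed=0))

for model in ("lda", "knn"):
    for set_name in ("FS2", "PROPOSED"):
        rep = trialwise_cv(recs, set_name, model)
        mm, sd = rep.macro_mean, rep.macro_sd
        print(f"{set_name:>8} / {model}: accuracy {mm.accuracy:6.2f}±{sd.accuracy:.2f}%  "
              f"macro F1 {mm.f1:6.2f}±{sd.f1:.2f}%")

# Each fold trains on 1000 windows (5 trials x 10 movements x 20 windows)
# and tests on the held-out trial's 200 windows, so train and test never
# share a contraction.
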
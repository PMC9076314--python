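"""Window-size and SNR robustness of the LMAV/NSV augmentation.

Both sweeps compare a base feature set against base ∪ {LMAV, NSV}: the
window sweep re-segments at 50-350 ms; the SNR sweep injects white noise
into the raw trials at 0-20 dB before preprocessing.  Run here at reduced
dataset size and coarser grids to stay quick.
"""

from myofeat import SynthConfig, generate_dataset
from myofeat.evaluate import sweep_snr, sweep_window

amps = {"W1": (0.04, 0.05), "W2": (0.055, 0.04), "S1": (0.2, 0.15), "S2": (0.35, 0.3)}
cfg = SynthConfig(movements=tuple(amps), amplitudes=amps, n_trials=3,
                  duration_s=1.4, seed=4)
recs = generate_dataset(cfg)

win = sweep_window(recs, "FS2", "lda", grid=(50, 150, 250, 350))
print("window sweep (macro F1 %):")
for x, b, a in zip(win.axis, win.f1_curves()["base"], win.f1_curves()["augmented"]):
    print(f"  {x:3.0f} ms: FS2 {b:6.2f}  FS2+LMAV/NSV {a:6.2f}")

snr = sweep_snr(recs, "FS2", "lda", seed=4, grid=(0, 5, 10, 15, 20))
print("SNR sweep (macro F1 %):")
for x, b, a in zip(snr.axis, snr.f1_curves()["base"], snr.f1_curves()["augmented"]):
    print(f"  {x:3.0f} dB: FS2 {b:6.2f}  FS2+LMAV/NSV {a:6.2f}")

# Low SNR degrades every feature set; the nonlinear pair is most valuable
# where weak movements sit close to the noise floor.
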
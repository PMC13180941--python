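"""Wavelet decomposition of a hemodynamic-like fNIRS epoch.

A 30 s HbO2 epoch at 10 Hz is decomposed with the Daubechies-8 wavelet.
The detail levels L5 (0.156-0.3125 Hz) and L6 (0.078-0.156 Hz) jointly
cover the ~0.07-0.31 Hz task-related band, leaving cardiac pulsation and
slow drifts to other levels; their reconstructions' energy, energy/entropy
ratio, and peak amplitude are the fNIRS features.
"""

import numpy as np

from bmnabc import WaveletSpec, detail_band, level_diagnostics, reconstruct_detail, wavelet_decompose

fs = 10.0
t = np.arange(300) / fs
rng = np.random.default_rng(0)
epoch = (
    0.6 * np.sin(2 * np.pi * 0.1 * t)    # task-evoked oxygenation (0.1 Hz)
    + 0.2 * np.sin(2 * np.pi * 1.0 * t)  # cardiac
    + 0.3 * np.sin(2 * np.pi * 0.02 * t) # baseline drift
    + 0.1 * rng.normal(size=t.size)
)

coeffs = wavelet_decompose(epoch, WaveletSpec())
total = float(np.sum(epoch**2))
print(f"{'level':>5s} {'band (Hz)':>18s} {'energy':>8s} {'share':>7s}")
for lvl in range(1, 7):
    lo, hi = detail_band(lvl, fs)
    d = level_diagnostics(coeffs, lvl)
    rec_energy = float(np.sum(reconstruct_detail(coeffs, lvl) ** 2))
    print(f"L{lvl:<4d} {lo:8.4f}-{hi:<8.4f} {rec_energy:8.2f} {rec_energy/total:6.1%}")
print()
print("The 0.1 Hz task component concentrates in L6, the cardiac tone far")
print("above L5 — selecting L5/L6 is a band filter in disguise.")
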
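"""Quantify a carbachol-like gamma oscillation from 400 s of recording.

The raw Welch spectrum of 1/f-background + 35 Hz tone is whitened by
multiplying power by frequency, z-scored over 3-300 Hz, and the gamma peak
read off the z spectrum — the group comparison statistic for slice gamma.
"""

from ripplestats import SynthLfpConfig, gamma_spectrum, generate_lfp

for amp in (0.15, 0.3, 0.6):
    cfg = SynthLfpConfig(
        duration_s=400.0, swr_rate_hz=0.0, gamma_amplitude_uv=amp, seed=7
    )
    rec, _ = generate_lfp(cfg)
    spec = gamma_spectrum(rec)
    print(
        f"tone amplitude {amp:>4} uV -> peak {spec.peak_freq_hz:5.1f} Hz, "
        f"peak z = {spec.peak_power_z:5.2f}, 20-60 Hz mean z = {spec.band_mean_z:5.2f}"
    )
# The peak z-score grows with oscillation amplitude — the ordering that
# separates genotypes in slice experiments; the peak stays at the tone's
# 35 Hz to within the 0.5 Hz spectral resolution.
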
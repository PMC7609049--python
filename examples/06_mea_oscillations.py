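"""Field-potential readout: two-tone spectra and the oscillation metric.

Generates phase-locked 1 Hz + 14 Hz field potentials on four
electrodes, recovers both tones from the Blackman-windowed spectrum,
and computes the 15-s absolute-sum oscillation metric for an "agonist"
recording with a doubled 14 Hz component.
"""

from orgscreen.synthetic_data import generate_field_potential
from orgscreen.timeseries import oscillation_metric, spectrum

basal = generate_field_potential([(1.0, 5.0), (14.0, 3.0)], rate_hz=1000.0,
                                 duration_s=30.0, noise_sd=0.5, seed=23)
out = spectrum(basal.traces[0], basal.rate_hz)
print("dominant spectral peaks (Hz, power):")
for freq, power in out["dominant_peaks"]:
    print(f"  {freq:6.2f} Hz   {power:.3e}")

treated = generate_field_potential([(1.0, 5.0), (14.0, 6.0)], rate_hz=1000.0,
                                   duration_s=30.0, noise_sd=0.5, seed=23)
ratio = oscillation_metric(basal.traces[0], treated.traces[0], 1000.0)
print(f"\noscillation metric (treated / basal over 15 s): {ratio:.3f}")

print("""
The spectrum shows exactly the two planted network rhythms (1 and
14 Hz) — concurrent slow and fast synchronized waves.  The oscillation
metric compares total field-potential activity before and after a
compound: 1.0 means no change; here the selective doubling of the
14 Hz component raises it partway toward 2, reflecting that only part
of the signal energy responded.""")
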
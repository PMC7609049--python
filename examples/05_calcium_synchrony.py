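"""Calcium-imaging readout: periodic synchronized spikes and synchrony.

Generates 4-min, 10 Hz traces for four ROIs sharing periodic spikes
(30 s period), detects events via a rolling-baseline ΔF/F₀ threshold,
and quantifies synchrony; then shows the channel-blocker scenario in
which spikes stop mid-recording.
"""

import numpy as np

from orgscreen.synthetic_data import generate_calcium_traces, planted_calcium_events
from orgscreen.timeseries import detect_spikes, synchrony_index

ts = generate_calcium_traces(n_rois=4, period_s=30.0, duration_s=240.0,
                             rate_hz=10.0, noise_sd=2.0, seed=19)
trains = [detect_spikes(tr, ts.rate_hz) for tr in ts.traces]
planted = planted_calcium_events(30.0, 240.0)

print(f"planted synchronized events: {len(planted)} at {planted} s")
for name, train in zip(ts.names, trains):
    print(f"  {name}: {train.n_events} events at {np.round(train.times_s, 1)} s")

sync = synchrony_index(ts, trains, window_s=1.0)
print(f"mean pairwise correlation: {sync['pairwise_correlation_mean']:.3f}")
print(f"coactive event fraction  : {sync['coactive_fraction']:.2f}")

blocked = generate_calcium_traces(n_rois=1, period_s=30.0, duration_s=240.0,
                                  noise_sd=2.0, seed=19, spikes_until_s=120.0)
train = detect_spikes(blocked.traces[0], 10.0)
print(f"\nblocker scenario: {train.n_events} events, "
      f"all before 120 s: {bool(np.all(train.times_s < 125.0))}")

print("""
Correlation near 1 and a coactive fraction near 1 mean every region of
the aggregate spikes together — network-wide functional coupling.  The
blocker run shows the readout collapsing once calcium entry is blocked,
the expected pharmacological control.""")
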
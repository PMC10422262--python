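"""Generate one synthetic movement trial and segment it.

A knee-extension-like burst is embedded in rest noise, band-pass filtered
to the 5-100 Hz MMG band, and recovered by short-time-energy thresholding.
The printed boundaries should bracket the planted 1 s burst.
"""

import numpy as np

from mmgsel import GeneratorConfig, bandpass_filter, generate_movement, segment_movements

cfg = GeneratorConfig(seed=0)
rec = generate_movement(0, cfg, np.random.default_rng(0))
filtered = bandpass_filter(rec)
segments = segment_movements(filtered)

print(f"recording: {rec.n_samples} samples x {rec.n_channels} channels at {rec.fs} Hz")
for seg in segments:
    print(
        f"segment [{seg.start}, {seg.end}) = "
        f"{seg.start / rec.fs:.2f}-{seg.end / rec.fs:.2f} s "
        f"({seg.n_samples / rec.fs:.2f} s long)"
    )
# The generator plants its burst between 0.75 s and 1.75 s; the detected
# segment should cover essentially that interval.
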
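"""Extract the four feature families from a small labeled dataset.

Builds 40 synthetic movement segments (10 per class), expands each into the
108-column feature bank (4 channels x 27 features), and prints a few named
features of the first segment.  RMS/MAV describe burst amplitude, MPF the
spectral centroid, the WE columns band-wise wavelet energy, and the
entropies the signal's regularity.
"""

from mmgsel import GeneratorConfig, build_feature_matrix, generate_dataset

cfg = GeneratorConfig(reps_per_class=10, seed=0)
segments = generate_dataset(cfg)
fm = build_feature_matrix(segments, cfg.fs)

print(f"{fm.X.shape[0]} segments x {fm.n_features} features")
print(f"labels: {sorted(map(str, set(fm.y)))}")
for name in ("ch1:TD:RMS", "ch1:TD:MAV", "ch1:FD:MPF", "ch1:NLD:SEn"):
    j = fm.names.index(name)
    print(f"{name:14s} first segment: {fm.X[0, j]:8.4f}")
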
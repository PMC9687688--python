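"""Turn feature vectors into Morlet-wavelet scalogram images.

Computes the continuous wavelet transform of one scaled feature vector
over scales 1..20 and renders the 240x240x3 image the classifier consumes.
Writes the PNGs and a manifest into ./scalograms_demo.
"""

import numpy as np

from wavetap import (
    SimConfig,
    WaveletConfig,
    cwt,
    extract_matrix,
    matrix_to_images,
    minmax_scale,
    simulate_cohort,
)

logs = simulate_cohort(SimConfig(n_healthy=2, n_parkinson=2, events_per_subject=100, seed=3))
scaled, _, _ = minmax_scale(extract_matrix(logs))

s = cwt(scaled.values[0], WaveletConfig())
print(f"scalogram: {s.coefficients.shape[0]} scales x {s.coefficients.shape[1]} positions")
print(f"coefficient magnitude range: [{np.abs(s.coefficients).min():.3f}, {np.abs(s.coefficients).max():.3f}]")

manifest = matrix_to_images(scaled, outdir="scalograms_demo", size=(240, 240))
print(f"\nwrote {len(manifest)} PNGs under class directories:")
print(manifest.to_string(index=False))
print("\nlow scales (top rows) capture rapid feature-to-feature variation; high scales, broad trends")
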
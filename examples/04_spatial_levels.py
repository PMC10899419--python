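"""Decode the same session at all five spatial resolutions.

Spike counts are pooled progressively: single neurons, E/I populations per
area, whole areas, whole regions, the whole brain.  Each level substitutes
its own spatial identity HVs in the encoder (receptive-field encodings at
neuron level, E/I-bound area HVs at population level, and so on).
"""

import warnings

from spikehd import (
    DecodeSettings, HDConfig, ResolutionConfig, SynthConfig,
    decode_at_resolution, generate,
)

warnings.filterwarnings("ignore", message=".*clipped.*")

ds = generate(SynthConfig(task="gabor", n_areas=3, units_per_area=10,
                          reps_per_class=5, signal_timescale_ms=250,
                          noise_corr=0.3, seed=9))
hd = HDConfig(D=2000, seed=2)
settings = DecodeSettings(n_folds=4, seed=0)

print(f"{'level':>12}  mean grid error  (chance ~ 4.7)")
for level in ("neuron", "population", "area", "region", "whole_brain"):
    res = ResolutionConfig(bin_size_ms=125, spatial_level=level, fano_bin_ms=25)
    ev = decode_at_resolution(ds, "gabor", res, hd, settings)
    print(f"{level:>12}  {ev.mean_error:>10.2f}")
# The Euclidean grid error counts how many 9x9 cells the predicted Gabor
# position is away from the truth; lower is better.
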
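"""Turn one PCG record into the network's input image.

Builds a synthetic unhealthy record, computes the Hamming-window STFT
(window 400 samples, overlap 50), and converts it to the 200x200 dB-scaled
image. The printed grid shape follows the frame-count formula
floor((L - 400)/350) + 1; pixel values are min-max normalized to [0, 1].
"""

import numpy as np

from heartpcg.spectrogram import STFTConfig, save_png, stft_magnitude, to_image
from heartpcg.synthetic import SynthConfig, generate_dataset

rec = generate_dataset(SynthConfig(n_healthy=0, n_unhealthy=2, duration=10.0, seed=3))[0]
cfg = STFTConfig()
grid = stft_magnitude(rec, cfg)
print(f"record {rec.id}: {len(rec.samples)} samples at {rec.rate} Hz")
print(f"magnitude grid: {grid.shape[0]} frequency bins x {grid.shape[1]} frames")

img = to_image(grid, record=rec, cfg=cfg)
print(f"image: {img.pixels.shape}, range [{img.pixels.min():.2f}, {img.pixels.max():.2f}]")
path = save_png(img, "scratch/spectrogram_demo.png", colormap="viridis")
print(f"saved {path}")
# Murmur energy shows up as bright rows between the S1/S2 bands
# (150-400 Hz, i.e. rows ~30-80 of the 201-bin grid).
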
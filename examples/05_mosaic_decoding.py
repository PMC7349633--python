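"""Decode a raw 5x5 snapshot-mosaic frame into a 25-band cube.

The sensor interleaves all 25 filters on the focal plane: each 5x5 pixel
tile holds one sample of every band. Decoding de-interleaves the frame;
re-interleaving reproduces it bit-for-bit.
"""

import numpy as np

from spadmap import cube_to_mosaic, get_band, mosaic_to_cube, reference_profile

profile = reference_profile()
rng = np.random.default_rng(0)
raw = rng.integers(0, 1024, size=(40, 60)).astype(np.uint16)  # 10-bit frame

cube = mosaic_to_cube(raw, profile)
print(f"raw frame {raw.shape} -> cube {cube.shape} x {cube.n_bands} bands")
print(f"band centers span {cube.wavelengths[0]:.0f}-{cube.wavelengths[-1]:.0f} nm")

band = get_band(cube, 888)
print(f"band at 888 nm: shape {band.shape}, "
      f"first pixel {band[0, 0]} == raw tile sample {raw[3, 2]}")

restored = cube_to_mosaic(cube, profile)
print(f"re-interleaved equals raw frame: {np.array_equal(restored, raw)}")
# each band is 1/25th of the raw resolution; (row 3, col 2) of the first
# tile is where the default row-major layout places the 888 nm filter.
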
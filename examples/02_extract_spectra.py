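"""From imaging scene to mean ROI spectrum: ENVI I/O, segmentation, extraction.

Writes one synthetic scene to an ENVI cube, reads it back, segments the
oil disk with Otsu's threshold and averages the pixel spectra over the ROI
— the standard reduction from hypercube to one spectrum per sample.
"""

import tempfile

import numpy as np

from oleospec import (
    SpectralSceneSpec,
    generate_hypercube,
    generate_oil_spectrum,
    mean_spectrum,
    read_envi,
    segment_roi,
    write_envi,
)

spec = SpectralSceneSpec(texture_coupling=0.6)
cube, truth = generate_hypercube(av=0.8, spec=spec, shape=(80, 80), seed=7)

with tempfile.TemporaryDirectory() as tmp:
    hdr, img = write_envi(cube, f"{tmp}/sample")
    back = read_envi(hdr)
    print(f"roundtrip exact: {np.array_equal(back.data, cube.data)}")

roi = segment_roi(cube)
print(f"ROI pixels: {roi.count} (true disk: {int(truth.sum())})")

spectrum = mean_spectrum(cube, roi)
clean = generate_oil_spectrum(0.8, spec, seed=7, noise_sd=0.0)
err = np.abs(spectrum[40:-40] - clean[40:-40]).max()
print(f"max |ROI mean - true spectrum| away from band edges: {err:.2e}")
# Averaging ~2500 ROI pixels recovers the sample spectrum to a few 1e-4
# reflectance units; the disk is segmented to within a pixel ring.
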
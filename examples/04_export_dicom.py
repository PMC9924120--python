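"""Export a reconstructed dose volume as a DICOM series and read it back.

Dose is stored in 16-bit secondary-capture-style slices with the rescale
slope/intercept carrying physical units (stored * slope + intercept = mGy);
stored value 0 is reserved for points outside the phantom.  The round trip
is lossless up to the quantization step (0.01 mGy by default).
"""

import tempfile
from pathlib import Path

import numpy as np

import filmdose3d as fd
from filmdose3d import synthetic as sy
from filmdose3d.reconstruct3d import build_volume

workdir = Path(tempfile.mkdtemp())
cfg = sy.preset("infant", dpi=50.0, film_size_mm=(110.0, 60.0), beam_center_mm=30.0)

field = sy.generate_phantom_dose(cfg)
tiff, _ = sy.render_film_scan(field, cfg, workdir / "film.tif")
net = fd.net_pixel_value(fd.read_film_scan(tiff), cfg.baseline)
dose_map = fd.apply_calibration(net, cfg.curve)
volume = build_volume(dose_map, cfg.geometry, center=sy.phantom_center_col(cfg),
                      row_step=10)

paths = fd.write_dicom_series(volume, fd.ExportSettings(), workdir / "dicom")
print(f"wrote {len(paths)} slices, e.g. {paths[0].name}")

back = fd.read_dicom_series(workdir / "dicom")
finite = np.isfinite(volume.slices)
max_err = np.max(np.abs(back.slices[finite] - volume.slices[finite]))
print(f"read back {back.n_slices} slices at "
      f"{back.in_plane_spacing_mm:.3f} mm pixel spacing")
print(f"max round-trip error: {max_err:.4f} mGy (quantization step 0.01 mGy)")
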
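"""Shared fixtures: reference calibration data and rendered synthetic scans.

Heavy pipeline products (rendered scans, dose maps, volumes) are session
scoped so the unit tests and the acceptance tests reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import filmdose3d as fd
from filmdose3d import reconstruct3d as r3
from filmdose3d import synthetic as sy


@pytest.fixture(scope="session")
def ref_table():
    return fd.reference_table()


@pytest.fixture(scope="session")
def fitted_curve(ref_table):
    return fd.fit_calibration(ref_table)


@pytest.fixture(scope="session")
def infant_cfg():
    return sy.preset("infant")


@pytest.fixture(scope="session")
def adult_cfg():
    return sy.preset("adult")


def _pipeline(cfg, tmp_dir):
    """Render -> read -> net -> calibrate -> downsample -> reconstruct."""
    field = sy.generate_phantom_dose(cfg)
    tiff, _ = sy.render_film_scan(field, cfg, tmp_dir / "film.tif")
    scan = fd.read_film_scan(tiff)
    net = fd.net_pixel_value(scan, cfg.baseline)
    dose_map = fd.apply_calibration(net, cfg.curve)
    dose_map_50 = fd.downsample(dose_map, 50.0)
    center = r3.estimate_center(dose_map_50, cfg.geometry)
    volume = r3.build_volume(dose_map_50, cfg.geometry, center=center)
    return {
        "field": field,
        "tiff": tiff,
        "scan": scan,
        "net": net,
        "dose_map": dose_map,
        "dose_map_50": dose_map_50,
        "center": center,
        "volume": volume,
    }


@pytest.fixture(scope="session")
def infant_pipeline(infant_cfg, tmp_path_factory):
    return _pipeline(infant_cfg, tmp_path_factory.mktemp("infant"))


@pytest.fixture(scope="session")
def adult_pipeline(adult_cfg, tmp_path_factory):
    return _pipeline(adult_cfg, tmp_path_factory.mktemp("adult"))


def angular_spread(slice_values: np.ndarray, n_angles: int = 360) -> float:
    """Worst-case std (absolute units) over sampled angles at any radius
    bin, with bilinear sampling along circles about the slice centre."""
    from scipy.ndimage import map_coordinates

    side = slice_values.shape[0]
    half = side // 2
    filled = np.nan_to_num(slice_values, nan=0.0)
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    worst = 0.0
    # stop one ring short of the disk edge: bilinear samples there would
    # blend in the NaN fill outside the phantom, which is not signal
    for radius in range(1, half - 1):
        rows = half + radius * np.sin(theta)
        cols = half + radius * np.cos(theta)
        samples = map_coordinates(filled, [rows, cols], order=1)
        worst = max(worst, float(np.std(samples)))
    return worst


def assert_rotationally_symmetric(slice_values: np.ndarray, floor_mGy: float = 0.05):
    """Angular std at every radius <= 1% of the slice maximum.

    Slices whose maximum dose sits at the scanner-quantization floor (one
    16-bit count maps to a few hundredths of a mGy) carry no signal to
    normalise by; for those the spread must instead stay below 0.01 mGy,
    the export quantization step.
    """
    spread = angular_spread(slice_values)
    max_val = float(np.nanmax(slice_values))
    if max_val >= floor_mGy:
        assert spread <= 0.01 * max_val
    else:
        assert spread <= 0.01
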
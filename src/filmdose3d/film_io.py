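"""Reading and preprocessing of scanned radiochromic-film images.

Reflective radiochromic film (e.g. Gafchromic XR-QA2) darkens with absorbed
dose, so the raw red-channel scanner value *decreases* as dose increases.
All downstream analysis therefore works on the *net pixel value*

    net = max(baseline - raw_red, 0)

where ``baseline`` is the raw value of unexposed film.  Net values start at
zero for unexposed film and increase monotonically with dose.

Coordinate convention: images are indexed ``[row, column]`` with row 0 at the
top of the scan.  The phantom long axis runs along rows, the short axis
(across the phantom diameter) along columns.  Physical position in mm is
``index * 25.4 / dpi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FilmScan",
    "NetImage",
    "read_film_scan",
    "write_rgb_tiff",
    "net_pixel_value",
    "downsample",
    "save_net_image",
    "load_net_image",
]

MM_PER_INCH = 25.4


@dataclass
class FilmScan:
    """Raw red-channel image of a scanned film.

    Parameters
    ----------
    red_channel
        2D integer array of raw scanner intensities in
        ``[0, 2**bit_depth - 1]``.
    dpi
        Scan resolution in dots per inch (> 0).
    bit_depth
        Bits per channel of the original scan (8 or 16).
    """

    red_channel: np.ndarray
    dpi: float
    bit_depth: int

    def __post_init__(self) -> None:
        self.red_channel = np.asarray(self.red_channel)
        if self.red_channel.ndim != 2 or self.red_channel.size == 0:
            raise ValueError("red_channel must be a non-empty 2D array")
        if self.dpi <= 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        vmax = 2**self.bit_depth - 1
        if self.red_channel.min() < 0 or self.red_channel.max() > vmax:
            raise ValueError(f"pixel values outside [0, {vmax}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red_channel.shape


@dataclass
class NetImage:
    """Baseline-subtracted film image: values grow with optical density.

    ``values`` are non-negative floats on the 16-bit scanner-count scale;
    ``baseline`` is the raw count corresponding to zero dose.
    """

    values: np.ndarray
    dpi: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2D array")
        if self.dpi <= 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")
        if np.nanmin(self.values) < 0:
            raise ValueError("net pixel values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def spacing_mm(self) -> float:
        """Physical size of one pixel in mm."""
        return MM_PER_INCH / self.dpi


def _dpi_from_tiff(path: Path) -> float | None:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if "XResolution" not in tags:
            return None
        num, den = tags["XResolution"].value
        if den == 0 or num == 0:
            return None
        res = num / den
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
        unit = int(unit)
        if unit == 1:  # RESUNIT.NONE: no absolute unit recorded
            return None
        if unit == 3:  # pixels per centimetre
            return res * 2.54
        return res


def _dpi_from_png(path: Path) -> float | None:
    from PIL import Image

    with Image.open(path) as im:
        dpi = im.info.get("dpi")
    if dpi is None:
        return None
    return float(dpi[0])


def read_film_scan(path: str | Path, dpi_override: float | None = None) -> FilmScan:
    """Read an RGB film scan and keep only the red channel.

    The red channel carries the strongest dose response of reflective
    radiochromic film and is the channel used for analysis throughout.

    Parameters
    ----------
    path
        TIFF or PNG file, RGB(A), 8 or 16 bits per channel.
    dpi_override
        Use this resolution instead of (or in absence of) file metadata.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not RGB, or no DPI metadata is present and no
        ``dpi_override`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"film scan not found: {path}")

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        meta_dpi = _dpi_from_tiff(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        meta_dpi = _dpi_from_png(path) if suffix == ".png" else None

    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(
            f"expected an RGB image, got array of shape {arr.shape}; "
            "grayscale scans are not supported"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported pixel type {arr.dtype}; expected uint8/uint16")

    dpi = dpi_override if dpi_override is not None else meta_dpi
    if dpi is None:
        raise ValueError(
            f"no DPI metadata found in {path.name} and no dpi_override given; "
            "pass dpi_override to set the scan resolution"
        )
    return FilmScan(red_channel=arr[:, :, 0].copy(), dpi=float(dpi), bit_depth=bit_depth)


def write_rgb_tiff(path: str | Path, rgb: np.ndarray, dpi: float) -> Path:
    """Write a 16-bit RGB TIFF with resolution metadata (lossless)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must have shape (rows, cols, 3)")
    path = Path(path)
    tifffile.imwrite(
        path,
        rgb.astype(np.uint16),
        resolution=(dpi, dpi),
        resolutionunit="INCH",
        photometric="rgb",
    )
    return path


def _roi_median(raw: np.ndarray, roi: tuple[int, int, int, int]) -> float:
    r0, c0, r1, c1 = roi
    nr, nc = raw.shape
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise ValueError(f"ROI {roi} outside image of shape {raw.shape}")
    return float(np.median(raw[r0:r1, c0:c1]))


def net_pixel_value(
    scan: FilmScan,
    baseline: float | tuple[int, int, int, int] | None = None,
) -> NetImage:
    """Convert raw scanner values to net pixel values.

    ``net = max(baseline - raw, 0)``.  The baseline may be given as a scalar
    raw value, as a ``(r0, c0, r1, c1)`` region of interest over unexposed
    film (its median raw value is used — robust to dust specks), or omitted,
    in which case the 99.5th percentile of the whole image is used as a
    fallback estimate of the unexposed level.

    8-bit scans are rescaled to the 16-bit range (factor 257) first so that a
    single calibration scale applies to all inputs.
    """
    raw = scan.red_channel.astype(float)
    scale = 1.0
    if scan.bit_depth == 8:
        scale = 257.0  # 255 * 257 == 65535
        raw = raw * scale
        warnings.warn(
            "8-bit scan rescaled to the 16-bit range (x257) before baseline "
            "subtraction",
            stacklevel=2,
        )

    if baseline is None:
        base = float(np.percentile(raw, 99.5))
    elif np.isscalar(baseline):
        base = float(baseline) * scale
        if not (0 <= base <= 65535):
            raise ValueError(f"baseline {base} outside the 16-bit scanner range")
    else:
        base = _roi_median(raw, tuple(baseline))

    if base < raw.min():
        raise ValueError(
            f"baseline {base:.0f} is below the minimum raw value "
            f"{raw.min():.0f}: net values would be negative everywhere"
        )
    net = np.maximum(base - raw, 0.0)
    return NetImage(values=net, dpi=scan.dpi, baseline=base)


def _block_reduce_mean(a: np.ndarray, block: int) -> np.ndarray:
    """Block-average with edge blocks averaged over available pixels."""
    nr, nc = a.shape
    row_edges = np.arange(0, nr, block)
    col_edges = np.arange(0, nc, block)
    sums = np.add.reduceat(np.add.reduceat(a, row_edges, axis=0), col_edges, axis=1)
    row_counts = np.diff(np.append(row_edges, nr))
    col_counts = np.diff(np.append(col_edges, nc))
    return sums / np.outer(row_counts, col_counts)


def downsample(image, target_dpi: float):
    """Reduce resolution by block averaging.

    Accepts a :class:`NetImage` or a calibrated dose map (anything with
    ``values`` and ``dpi`` attributes) and returns the same type.  The
    current dpi must be an integer multiple of ``target_dpi`` (e.g. 150 to
    50 dpi).  Averaging — rather than decimation — reduces scanner noise.
    """
    if target_dpi <= 0:
        raise ValueError("target_dpi must be positive")
    if target_dpi > image.dpi:
        raise ValueError(f"cannot upsample: target {target_dpi} > current {image.dpi}")
    factor = image.dpi / target_dpi
    block = round(factor)
    if abs(factor - block) > 1e-9:
        raise ValueError(
            f"dpi ratio {factor:.4f} is not an integer; block averaging "
            "requires current dpi to be a multiple of target dpi"
        )
    if block == 1:
        return image
    values = _block_reduce_mean(np.asarray(image.values, dtype=float), block)
    new_dpi = image.dpi / block
    if isinstance(image, NetImage):
        return NetImage(values=values, dpi=new_dpi, baseline=image.baseline)
    # dose-map path: rebuild via the same class, preserving the mask by
    # propagating any flagged pixel in each block
    from .calibration import DoseMap2D

    if isinstance(image, DoseMap2D):
        mask = None
        if image.mask is not None:
            nr, nc = image.mask.shape
            re = np.arange(0, nr, block)
            ce = np.arange(0, nc, block)
            mask = np.maximum.reduceat(
                np.maximum.reduceat(image.mask, re, axis=0), ce, axis=1
            )
        return DoseMap2D(values=values, dpi=new_dpi, mask=mask)
    raise TypeError(f"cannot downsample object of type {type(image).__name__}")


def save_net_image(image: NetImage, path: str | Path) -> Path:
    """Persist a net image as an ``.npz`` container with its metadata."""
    path = Path(path)
    np.savez(path, values=image.values, dpi=image.dpi, baseline=image.baseline)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_net_image(path: str | Path) -> NetImage:
    with np.load(path) as data:
        return NetImage(
            values=data["values"],
            dpi=float(data["dpi"]),
            baseline=float(data["baseline"]),
        )
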
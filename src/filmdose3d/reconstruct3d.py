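"""Rotational reconstruction of axial dose slices from the film plane.

The film sits in the central plane of a cylindrical phantom that was
scanned with the X-ray tube orbiting a full 360 degrees about the phantom
axis.  The dose deposit is then rotationally symmetric about that axis, so
each film row (one long-axis position) carries a full diameter of dose data
whose half-profile, swept through 360 degrees, reconstructs the entire
axial dose plane.  Stacking the reconstructed planes along the long axis
yields a 3D dose volume.

This construction is exact only for a phantom centred on the rotation axis;
an off-centre phantom breaks the symmetry, which :func:`estimate_center`
can detect via the left-right mismatch of the exposure row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import DoseMap2D
from .film_io import MM_PER_INCH
from .profiles import PhantomGeometry

__all__ = [
    "RadiusProfile",
    "AxialSlice",
    "DoseVolume",
    "estimate_center",
    "radius_profile",
    "rotate_to_slice",
    "build_volume",
    "pseudo_color",
    "default_lut",
    "save_volume",
    "load_volume",
]


@dataclass
class RadiusProfile:
    """Dose (or net value) as a function of radius, r = 0 .. R."""

    values: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("radius profile must be a non-empty 1D array")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def radius_mm(self) -> float:
        return (len(self.values) - 1) * self.spacing_mm


@dataclass
class AxialSlice:
    """One reconstructed axial dose plane on a square grid.

    The grid side is odd (``2 * R_px + 1``) so the rotation centre falls on
    the centre pixel; points outside the phantom disk hold ``fill``
    (NaN by default, marking "no measurement" rather than zero dose).
    """

    values: np.ndarray
    spacing_mm: float
    fill: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nr, nc = self.values.shape
        if nr != nc or nr % 2 == 0:
            raise ValueError("axial slice must be a square grid with odd side")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def center_index(self) -> tuple[int, int]:
        c = self.values.shape[0] // 2
        return (c, c)

    @property
    def center_value(self) -> float:
        return float(self.values[self.center_index])


@dataclass
class DoseVolume:
    """Stack of axial dose slices with physical spacings (mGy / mm)."""

    slices: np.ndarray  # shape (n_slices, side, side)
    in_plane_spacing_mm: float
    inter_slice_spacing_mm: float
    long_axis_origin_mm: float = 0.0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a 3D array (n, side, side)")
        if self.in_plane_spacing_mm <= 0 or self.inter_slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_positions_mm(self) -> np.ndarray:
        return self.long_axis_origin_mm + np.arange(self.n_slices) * (
            self.inter_slice_spacing_mm
        )


def estimate_center(
    dose_map: DoseMap2D,
    geometry: PhantomGeometry,
    override: int | None = None,
    refine: bool = False,
    search_px: int = 10,
) -> int:
    """Column index of the phantom (rotation) axis on the film.

    Default is the image-column midpoint (the phantom is normally centred
    on the film crop).  With ``refine`` the centre is nudged within
    ``+-search_px`` to maximise the left-right correlation of the exposure
    row (the row with the highest mean dose).  An explicit ``override``
    always wins.
    """
    nc = dose_map.shape[1]
    if override is not None:
        if not (0 <= override < nc):
            raise ValueError(f"center override {override} outside [0, {nc - 1}]")
        return int(override)
    mid = (nc - 1) // 2
    if not refine:
        return mid

    row_idx = int(np.nanargmax(np.nanmean(dose_map.values, axis=1)))
    row = dose_map.values[row_idx]
    r_px = int(round(geometry.radius_mm * dose_map.dpi / MM_PER_INCH))
    best: tuple[float, int] | None = None
    for c in range(mid - search_px, mid + search_px + 1):
        k = min(r_px, c, nc - 1 - c)
        if k < 3:
            continue
        left = row[c - k : c][::-1]
        right = row[c + 1 : c + 1 + k]
        denom = np.std(left) * np.std(right)
        if denom == 0:
            continue
        score = float(np.mean((left - left.mean()) * (right - right.mean())) / denom)
        if best is None or score > best[0]:
            best = (score, c)
    if best is None:
        warnings.warn(
            "center refinement found no valid candidate; falling back to the "
            "column midpoint",
            stacklevel=2,
        )
        return mid
    return best[1]


def radius_profile(
    row: np.ndarray,
    center: int,
    side: str = "mean",
    spacing_mm: float = 1.0,
    max_radius_px: int | None = None,
) -> RadiusProfile:
    """Half-profile from ``center`` outward.

    ``side='right'`` takes ``row[center:]``, ``'left'`` the mirrored left
    half, ``'mean'`` the average of both (truncated to the shorter half).
    ``max_radius_px`` optionally crops the profile to the phantom radius.
    """
    row = np.asarray(row, dtype=float)
    n = len(row)
    if not (0 <= center < n):
        raise ValueError(f"center {center} outside row of length {n}")
    right = row[center:]
    left = row[: center + 1][::-1]
    if side == "right":
        values = right
    elif side == "left":
        values = left
    elif side == "mean":
        k = min(len(left), len(right))
        values = 0.5 * (left[:k] + right[:k])
    else:
        raise ValueError(f"side must be 'left', 'right' or 'mean', got {side!r}")
    if values.size == 0:
        raise ValueError(f"requested side {side!r} is empty at center {center}")
    if max_radius_px is not None:
        values = values[: max_radius_px + 1]
    return RadiusProfile(values=values.copy(), spacing_mm=spacing_mm)


def rotate_to_slice(
    profile: RadiusProfile,
    out_side_px: int | None = None,
    interpolation: str = "linear",
    fill: float = np.nan,
) -> AxialSlice:
    """Sweep a radius profile through 360 degrees onto a Cartesian grid.

    Each grid point takes the profile value at its Euclidean distance from
    the grid centre (in units of the profile spacing); distances beyond the
    profile extent get ``fill``.  The centre pixel equals ``values[0]``
    exactly.  ``interpolation`` is ``'linear'`` or ``'nearest'``.
    """
    n = len(profile.values)
    if out_side_px is None:
        out_side_px = 2 * (n - 1) + 1
    if out_side_px % 2 == 0:
        raise ValueError(f"out_side_px must be odd, got {out_side_px}")
    half = out_side_px // 2
    coords = np.arange(-half, half + 1, dtype=float)
    r = np.hypot(coords[:, None], coords[None, :])  # in pixel (spacing) units

    if interpolation == "nearest":
        idx = np.rint(r).astype(int)
        inside = idx <= n - 1
        values = np.full(r.shape, fill, dtype=float)
        values[inside] = profile.values[idx[inside]]
    elif interpolation == "linear":
        values = np.interp(r, np.arange(n, dtype=float), profile.values)
        values[r > n - 1] = fill
    else:
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    values[half, half] = profile.values[0]  # exact on-axis anchoring
    return AxialSlice(values=values, spacing_mm=profile.spacing_mm, fill=fill)


def build_volume(
    dose_map: DoseMap2D,
    geometry: PhantomGeometry,
    center: int,
    row_step: int = 1,
    side: str = "mean",
    interpolation: str = "linear",
    fill: float = np.nan,
) -> DoseVolume:
    """Reconstruct the 3D dose volume from a calibrated film map.

    One axial slice is built from every ``row_step``-th film row within the
    phantom length; the inter-slice spacing is ``row_step`` film pixels.
    The slice grid side is ``2 * R_px + 1`` where ``R_px`` is the phantom
    radius in pixels.
    """
    if row_step < 1:
        raise ValueError("row_step must be >= 1")
    spacing = dose_map.spacing_mm
    nr = dose_map.shape[0]
    r0 = int(round(geometry.film_long_axis_origin_mm / spacing))
    r1 = min(nr, r0 + int(round(geometry.length_mm / spacing)) + 1)
    rows = np.arange(max(r0, 0), r1, row_step)
    if rows.size == 0:
        raise ValueError("no film rows fall inside the phantom length")

    r_px = int(round(geometry.radius_mm * dose_map.dpi / MM_PER_INCH))
    side_px = 2 * r_px + 1
    slices = np.empty((len(rows), side_px, side_px), dtype=float)
    for i, row_idx in enumerate(rows):
        prof = radius_profile(
            dose_map.values[row_idx],
            center,
            side=side,
            spacing_mm=spacing,
            max_radius_px=r_px,
        )
        slices[i] = rotate_to_slice(
            prof, out_side_px=side_px, interpolation=interpolation, fill=fill
        ).values
    return DoseVolume(
        slices=slices,
        in_plane_spacing_mm=spacing,
        inter_slice_spacing_mm=row_step * spacing,
        long_axis_origin_mm=rows[0] * spacing,
    )


def default_lut() -> np.ndarray:
    """256-entry RGB colour table (jet) for pseudo-colour dose display."""
    import matplotlib

    cmap = matplotlib.colormaps["jet"]
    return (cmap(np.linspace(0, 1, 256))[:, :3] * 255).astype(np.uint8)


def pseudo_color(
    slice_: AxialSlice,
    lut: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
    background: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Map a dose slice through a colour lookup table.

    ``window = (lo, hi)`` sets the dose range mapped onto LUT entries
    0..255 (values at or below ``lo`` take entry 0, at or above ``hi``
    entry 255).  Fill (NaN) pixels take the ``background`` colour.
    Defaults: full-range window, jet LUT.
    """
    lut = default_lut() if lut is None else np.asarray(lut, dtype=np.uint8)
    if lut.shape != (256, 3):
        raise ValueError(f"LUT must have shape (256, 3), got {lut.shape}")
    v = slice_.values
    finite = np.isfinite(v)
    if window is None:
        window = (float(np.nanmin(v)), float(np.nanmax(v)))
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    idx = np.zeros(v.shape, dtype=np.uint8)
    scaled = (v[finite] - lo) / (hi - lo)
    idx[finite] = np.clip(np.rint(scaled * 255), 0, 255).astype(np.uint8)
    rgb = lut[idx]
    rgb[~finite] = background
    return rgb


def save_volume(volume: DoseVolume, path: str | Path) -> Path:
    """Persist a volume as ``.npz`` with its spacing metadata."""
    path = Path(path)
    np.savez(
        path,
        slices=volume.slices,
        in_plane_spacing_mm=volume.in_plane_spacing_mm,
        inter_slice_spacing_mm=volume.inter_slice_spacing_mm,
        long_axis_origin_mm=volume.long_axis_origin_mm,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_volume(path: str | Path) -> DoseVolume:
    with np.load(path) as data:
        return DoseVolume(
            slices=data["slices"],
            in_plane_spacing_mm=float(data["in_plane_spacing_mm"]),
            inter_slice_spacing_mm=float(data["inter_slice_spacing_mm"]),
            long_axis_origin_mm=float(data["long_axis_origin_mm"]),
        )
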
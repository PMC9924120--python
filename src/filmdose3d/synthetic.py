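"""Synthetic dose fields and film-scan renderer with known ground truth.

A single axial CT scan of a cylindrical phantom deposits dose in a pattern
with two regimes along the phantom long axis ``z``: a primary-beam band of
roughly the collimated beam width (with a penumbra), and exponentially
decaying scatter tails beyond it.  Across the radius ``r`` the two regimes
behave oppositely: the primary beam enters at the surface and is attenuated
toward the centre (surface dose highest), while lateral scatter accumulates
on-axis (centre dose highest).

The reference dose model used here is the separable two-term form

    D(r, z) = A(z) * P(r)  +  S(z) * Q(r)

with

    A(z) = normalised top-hat of width ``beam_width_mm`` convolved with a
           Gaussian penumbra (A = 1 at the beam centre),
    P(r) = surface_dose * exp(-radial_coefficient * (R - r)),
    S(z) = scatter_peak * (1 - A(z)) * exp(-max(0, |z - z0| - w/2) / L),
    Q(r) = 1 - (r / R)**2            (vanishes at the surface).

The ``(1 - A(z))`` factor makes the scatter term vanish at the beam centre,
so at ``(r = R, z = z0)`` the field equals ``surface_dose`` exactly.  The
model is deliberately simple: its job is to exhibit the qualitative
centre-versus-periphery behaviour of real phantom exposures with an exact,
analytically known ground truth — not to be a transport calculation.

Rendering inverts the measurement chain: dose -> net pixel value through a
forward calibration curve -> raw red value ``baseline - net`` -> 16-bit RGB
TIFF with optional Gaussian scanner noise.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import erf

from .calibration import CalibrationCurve, dose_to_pixel
from .film_io import MM_PER_INCH, FilmScan, write_rgb_tiff
from .profiles import PhantomGeometry

__all__ = [
    "SyntheticConfig",
    "default_forward_curve",
    "preset",
    "dose_field",
    "generate_phantom_dose",
    "phantom_center_col",
    "render_film_scan",
    "generate_calibration_strip",
    "ground_truth_volume",
]


def default_forward_curve() -> CalibrationCurve:
    """Idealised forward response used by the renderer.

    Same double-exponential family and comparable magnitudes as the fitted
    reference film response, but with amplitudes chosen so the zero-dose
    response is exactly 0 — convenient for exact round-trip checks.
    """
    return CalibrationCurve(
        y0=30000.0, A1=-16000.0, B1=0.016, A2=-14000.0, B2=0.09,
        dose_range=(0.0, 200.0),
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic exposure, phantom and scanner.

    Lengths in mm, doses in mGy, scanner quantities in 16-bit counts.
    ``film_size_mm`` is (short side across the diameter, long side along the
    phantom axis); the film is cut larger than the phantom diameter, as in
    practice, so unexposed margins are present on the scan.
    """

    geometry: PhantomGeometry
    film_size_mm: tuple[float, float]
    beam_center_mm: float = 125.0
    beam_width_mm: float = 20.0
    penumbra_sigma_mm: float = 3.0
    scatter_length_mm: float = 40.0
    surface_dose_mGy: float = 30.0
    radial_coefficient_per_mm: float = 0.001
    scatter_peak_mGy: float = 8.0
    curve: CalibrationCurve = field(default_factory=default_forward_curve)
    baseline: float = 58000.0
    noise_sd: float = 0.0
    dpi: float = 150.0
    center_offset_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.film_size_mm[0] < self.geometry.diameter_mm:
            raise ValueError(
                "film short side must be at least the phantom diameter"
            )
        if self.beam_width_mm <= 0 or self.scatter_length_mm <= 0:
            raise ValueError("beam width and scatter length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")


#: Default study conditions: a 100 mm (infant) and a 160 mm (adult) phantom,
#: 300 mm long, film cut 10 mm wider than the diameter and 250 mm long,
#: scanned at 150 dpi.  The radial attenuation coefficient gives a nearly
#: flat exposure-plane profile for the infant phantom and a clearly
#: centre-depressed one for the adult, matching the qualitative contrast
#: between the two diameters; surface doses are typical for a single axial
#: body scan at 120 kVp.
_PRESETS = {
    "infant": dict(
        geometry=PhantomGeometry(diameter_mm=100.0, length_mm=300.0),
        film_size_mm=(110.0, 250.0),
        surface_dose_mGy=30.0,
        radial_coefficient_per_mm=0.0006,
        scatter_peak_mGy=8.0,
    ),
    "adult": dict(
        geometry=PhantomGeometry(diameter_mm=160.0, length_mm=300.0),
        film_size_mm=(170.0, 250.0),
        surface_dose_mGy=25.0,
        radial_coefficient_per_mm=0.004,
        scatter_peak_mGy=8.0,
    ),
}


def preset(name: str, **overrides) -> SyntheticConfig:
    """Named study configuration (``'infant'`` or ``'adult'``)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    cfg = SyntheticConfig(**_PRESETS[name])
    return replace(cfg, **overrides) if overrides else cfg


def _axial_weight(cfg: SyntheticConfig, z):
    """A(z): beam top-hat convolved with a Gaussian penumbra, A(z0) = 1."""
    z = np.asarray(z, dtype=float)
    s = cfg.penumbra_sigma_mm * np.sqrt(2.0)
    half = cfg.beam_width_mm / 2.0
    u = z - cfg.beam_center_mm
    raw = 0.5 * (erf((u + half) / s) - erf((u - half) / s))
    return raw / erf(half / s)


def _scatter_weight(cfg: SyntheticConfig, z):
    """S(z)/scatter_peak: complement of the beam, decaying beyond its edge."""
    z = np.asarray(z, dtype=float)
    beyond = np.maximum(np.abs(z - cfg.beam_center_mm) - cfg.beam_width_mm / 2, 0.0)
    return (1.0 - _axial_weight(cfg, z)) * np.exp(-beyond / cfg.scatter_length_mm)


def dose_field(cfg: SyntheticConfig, r, z):
    """Ground-truth dose D(r, z) in mGy; r, z broadcast (mm).

    Radii beyond the phantom surface return 0 (the film margins receive no
    dose in this model).
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    R = cfg.geometry.radius_mm
    primary = cfg.surface_dose_mGy * np.exp(
        -cfg.radial_coefficient_per_mm * (R - r)
    )
    scatter_radial = 1.0 - (r / R) ** 2
    D = _axial_weight(cfg, z) * primary + (
        cfg.scatter_peak_mGy * _scatter_weight(cfg, z)
    ) * scatter_radial
    return np.where(r <= R, np.maximum(D, 0.0), 0.0)


def phantom_center_col(cfg: SyntheticConfig) -> int:
    """Film column index of the phantom axis."""
    center_mm = cfg.film_size_mm[0] / 2.0 + cfg.center_offset_mm
    return int(round(center_mm * cfg.dpi / MM_PER_INCH))


def generate_phantom_dose(cfg: SyntheticConfig) -> np.ndarray:
    """Sample the ground-truth dose field on the film pixel grid.

    Rows run along the phantom long axis, columns across the diameter;
    spacing is ``25.4 / dpi`` mm.
    """
    px = MM_PER_INCH / cfg.dpi
    n_rows = int(round(cfg.film_size_mm[1] / px))
    n_cols = int(round(cfg.film_size_mm[0] / px))
    z = np.arange(n_rows) * px
    x = np.arange(n_cols) * px
    center_mm = phantom_center_col(cfg) * px
    r = np.abs(x - center_mm)
    return dose_field(cfg, r[None, :], z[:, None])


def render_film_scan(
    field: np.ndarray,
    cfg: SyntheticConfig,
    path: str | Path,
    write_truth: bool = True,
) -> tuple[Path, Path | None]:
    """Render a dose field to a 16-bit RGB film scan on disk.

    The red channel carries ``baseline - dose_to_pixel(curve, D)``; green
    and blue stay at the baseline.  Independent Gaussian noise of
    ``cfg.noise_sd`` counts is added per pixel and channel (seeded by
    ``cfg.seed``), then values are rounded and clipped to the 16-bit range.
    Returns the TIFF path and the ground-truth ``.npy`` sidecar path.
    """
    field = np.asarray(field, dtype=float)
    lo, hi = cfg.curve.dose_range
    if field.max() > hi or field.min() < lo:
        raise ValueError(
            f"dose field range [{field.min():.1f}, {field.max():.1f}] mGy "
            f"exceeds the calibratable range [{lo}, {hi}] mGy"
        )
    net = dose_to_pixel(cfg.curve, field)
    rgb = np.empty(field.shape + (3,), dtype=float)
    rgb[:, :, 0] = cfg.baseline - net
    rgb[:, :, 1] = cfg.baseline
    rgb[:, :, 2] = cfg.baseline
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        rgb += rng.normal(0.0, cfg.noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 65535).astype(np.uint16)

    path = Path(path)
    write_rgb_tiff(path, rgb, dpi=cfg.dpi)
    truth_path = None
    if write_truth:
        truth_path = path.with_suffix(".truth.npy")
        np.save(truth_path, field)
    return path, truth_path


def generate_calibration_strip(
    doses,
    curve: CalibrationCurve | None = None,
    cfg: SyntheticConfig | None = None,
    segment_size_mm: tuple[float, float] = (12.0, 40.0),
    dpi: float = 150.0,
    baseline: float = 58000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FilmScan, list[tuple[float, tuple[int, int, int, int]]]]:
    """Render a segmented calibration strip and its segment layout.

    One uniformly exposed segment per dose, stacked along the strip length
    (the segmented exposure method).  Returns the raw scan and a layout of
    ``(dose, roi)`` pairs suitable for
    :func:`filmdose3d.calibration.extract_segments`.  Scanner parameters
    default to the synthetic-config defaults unless ``cfg`` is given.
    """
    doses = np.asarray(doses, dtype=float)
    if curve is None:
        curve = cfg.curve if cfg is not None else default_forward_curve()
    if cfg is not None:
        dpi, baseline, noise_sd, seed = cfg.dpi, cfg.baseline, cfg.noise_sd, cfg.seed
    lo, hi = curve.dose_range
    if doses.min() < lo or doses.max() > hi:
        raise ValueError(f"strip doses must lie within the curve range [{lo}, {hi}]")

    px = MM_PER_INCH / dpi
    seg_rows = int(round(segment_size_mm[0] / px))
    seg_cols = int(round(segment_size_mm[1] / px))
    raw = np.empty((seg_rows * len(doses), seg_cols), dtype=float)
    layout = []
    for i, d in enumerate(doses):
        net = max(dose_to_pixel(curve, float(d)), 0.0)
        r0 = i * seg_rows
        raw[r0 : r0 + seg_rows, :] = baseline - net
        layout.append((float(d), (r0, 0, r0 + seg_rows, seg_cols)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw += rng.normal(0.0, noise_sd, size=raw.shape)
    raw = np.clip(np.rint(raw), 0, 65535).astype(np.uint16)
    return FilmScan(red_channel=raw, dpi=dpi, bit_depth=16), layout


def ground_truth_volume(cfg: SyntheticConfig, volume) -> np.ndarray:
    """Evaluate the analytic dose field on a reconstructed volume's grids.

    Returns an array of the volume's shape with NaN outside the phantom
    disk, for direct comparison against a reconstruction.
    """
    n, side, _ = volume.slices.shape
    half = side // 2
    coords = (np.arange(side) - half) * volume.in_plane_spacing_mm
    r = np.hypot(coords[:, None], coords[None, :])
    R = cfg.geometry.radius_mm
    # radius grid extends to the slice corners; mask outside the phantom
    out = np.empty_like(volume.slices)
    z = volume.slice_positions_mm
    for i in range(n):
        D = dose_field(cfg, r, z[i])
        D[r > R] = np.nan
        out[i] = D
    # match the reconstruction's own fill region (beyond the profile extent)
    out[np.isnan(volume.slices)] = np.nan
    return out
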
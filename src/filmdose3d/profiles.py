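"""Short-axis profile extraction across the phantom diameter.

A single axial CT scan exposes the film in a narrow band (the primary
beam), flanked by penumbra ("adjusted") and scatter-only regions along the
phantom long axis.  Profiles across the short axis at characteristic
long-axis positions summarise how dose varies from the phantom surface to
its centre:

* ``A`` — peripheral region, far from the beam (essentially unexposed)
* ``B`` — scattered-radiation region
* ``C`` — adjusted (beam-edge / penumbra) region
* ``D`` — centre of the exposure region

The diagnostic quantity is the centre-to-periphery ratio of a profile: in
the exposure plane the primary beam is attenuated toward the centre (ratio
<= 1, more so for larger diameters), while in scatter regions lateral
scatter accumulates on-axis (ratio > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .film_io import MM_PER_INCH

__all__ = [
    "PhantomGeometry",
    "ProfileSpec",
    "Profile",
    "PROFILE_LABELS",
    "extract_profile",
    "summarize_profile",
]

PROFILE_LABELS = {
    "A": "peripheral",
    "B": "scattered",
    "C": "adjusted",
    "D": "exposure-center",
}


@dataclass
class PhantomGeometry:
    """Cylindrical phantom dimensions and placement on the film.

    ``film_long_axis_origin_mm`` is the long-axis (row) position on the film
    where the phantom starts; the film is cut larger than the phantom so
    profiles are always cropped to the phantom diameter, not the film width.
    """

    diameter_mm: float
    length_mm: float = 300.0
    film_long_axis_origin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("phantom dimensions must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class ProfileSpec:
    """A labelled long-axis position at which to take a short-axis profile."""

    label: str
    long_axis_position_mm: float

    def __post_init__(self) -> None:
        if self.label not in PROFILE_LABELS:
            raise ValueError(
                f"label must be one of {sorted(PROFILE_LABELS)}, got {self.label!r}"
            )


@dataclass
class Profile:
    """A 1D short-axis profile (net pixel value or mGy)."""

    values: np.ndarray
    spacing_mm: float
    label: str = "D"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile values must be a non-empty 1D array")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def positions_mm(self) -> np.ndarray:
        """Positions relative to the profile centre, in mm."""
        n = len(self.values)
        return (np.arange(n) - (n - 1) / 2) * self.spacing_mm


def profile_length(diameter_mm: float, dpi: float) -> int:
    """Number of samples in a profile spanning the phantom diameter."""
    return int(round(diameter_mm * dpi / MM_PER_INCH)) + 1


def extract_profile(
    image,
    spec: ProfileSpec,
    geometry: PhantomGeometry,
    center_col: int,
    average_rows: bool = True,
) -> Profile:
    """Extract a short-axis profile at the spec's long-axis position.

    ``image`` is a :class:`~filmdose3d.film_io.NetImage` or
    :class:`~filmdose3d.calibration.DoseMap2D`.  The row at the requested
    position is cropped symmetrically about ``center_col`` to the phantom
    diameter.  With ``average_rows`` the row is averaged with its two
    neighbours to suppress single-row scanner noise (disable for bit-exact
    extraction).
    """
    arr = np.asarray(image.values, dtype=float)
    dpi = image.dpi
    nr, nc = arr.shape

    if not (0 <= spec.long_axis_position_mm <= geometry.length_mm):
        raise ValueError(
            f"profile position {spec.long_axis_position_mm} mm outside the "
            f"phantom length [0, {geometry.length_mm}] mm"
        )
    row = int(
        round(
            (geometry.film_long_axis_origin_mm + spec.long_axis_position_mm)
            * dpi
            / MM_PER_INCH
        )
    )
    if not (0 <= row < nr):
        raise ValueError(f"profile row {row} outside image with {nr} rows")

    n = profile_length(geometry.diameter_mm, dpi)
    left = (n - 1) // 2
    right = n - 1 - left
    c0, c1 = center_col - left, center_col + right
    if c0 < 0 or c1 >= nc:
        raise ValueError(
            f"profile window [{c0}, {c1}] exceeds image columns [0, {nc - 1}]; "
            "check center_col and the phantom diameter"
        )
    if average_rows:
        r0, r1 = max(row - 1, 0), min(row + 1, nr - 1)
        values = arr[r0 : r1 + 1, c0 : c1 + 1].mean(axis=0)
    else:
        values = arr[row, c0 : c1 + 1].copy()
    return Profile(values=values, spacing_mm=MM_PER_INCH / dpi, label=spec.label)


def summarize_profile(
    profile: Profile,
    center_fraction: float = 0.05,
    peripheral_fraction: float = 0.10,
) -> dict:
    """Centre value, peripheral mean and their ratio for one profile.

    ``center_value`` is the mean over the central ``center_fraction`` of
    samples (at least one); ``peripheral_mean`` averages the outer
    ``peripheral_fraction`` of samples on each side.  The window fractions
    are adjustable because "centre" and "periphery" have no canonical
    widths.
    """
    v = profile.values
    n = len(v)
    if n < 11:
        raise ValueError(f"profile too short to summarise ({n} samples)")

    n_center = max(int(round(n * center_fraction)), 1)
    start = (n - n_center) // 2
    center_value = float(v[start : start + n_center].mean())

    n_per = max(int(round(n * peripheral_fraction)), 1)
    peripheral_mean = float(np.concatenate([v[:n_per], v[-n_per:]]).mean())

    ratio = center_value / peripheral_mean if peripheral_mean != 0 else np.nan
    return {
        "label": profile.label,
        "center_value": center_value,
        "peripheral_mean": peripheral_mean,
        "center_to_periphery_ratio": float(ratio),
        "ratio_defined": bool(peripheral_mean != 0),
    }
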
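"""Dose-response calibration for reflective radiochromic film.

The net pixel value ``y`` of the film as a function of air-kerma dose
``x`` (mGy) saturates at high dose and is modelled as a sum of two decaying
exponentials,

    y(x) = y0 + A1 * exp(-B1 * x) + A2 * exp(-B2 * x)

with ``y0`` the saturation asymptote, ``A1, A2 <= 0`` the amplitudes and
``B1, B2 > 0`` the decay rates (canonically ordered ``B1 < B2``).  The model
is fitted by unweighted nonlinear least squares; because the two-exponential
model is sensitive to its starting point, initial decay rates are picked
from a log-spaced grid with a linear solve for the amplitudes at each node,
which makes the fit deterministic.

Dose is recovered from a net value by monotone bisection of the fitted
curve, which is the workhorse for converting whole film scans to dose maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .film_io import MM_PER_INCH, NetImage

__all__ = [
    "CalibrationTable",
    "CalibrationCurve",
    "DoseMap2D",
    "FLAG_OK",
    "FLAG_BELOW_RANGE",
    "FLAG_SATURATED",
    "reference_table",
    "extract_segments",
    "fit_calibration",
    "dose_to_pixel",
    "pixel_to_dose",
    "apply_calibration",
]

# per-pixel flags used in dose-map masks
FLAG_OK = 0
FLAG_BELOW_RANGE = 1  # net value below the curve's zero-dose response
FLAG_SATURATED = 2  # net value above the response at the top of the range


@dataclass
class CalibrationTable:
    """Measured (dose, net pixel value) pairs.

    ``doses`` must be strictly increasing and non-negative; at least six
    points are required so the five model coefficients are identifiable.
    """

    doses: np.ndarray
    net_values: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.net_values = np.asarray(self.net_values, dtype=float)
        if self.doses.shape != self.net_values.shape or self.doses.ndim != 1:
            raise ValueError("doses and net_values must be 1D arrays of equal length")
        if self.n < 6:
            raise ValueError(f"need at least 6 calibration points, got {self.n}")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.doses[0] < 0:
            raise ValueError("doses must be non-negative")
        if np.any(self.net_values < 0):
            raise ValueError("net values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.doses)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        try:
            dose_col = cols["dose_mgy"]
            val_col = cols["net_pixel_value"]
        except KeyError as exc:
            raise ValueError(
                "calibration CSV needs columns 'dose_mGy' and 'net_pixel_value'"
            ) from exc
        return cls(doses=df[dose_col].to_numpy(), net_values=df[val_col].to_numpy())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"dose_mGy": self.doses, "net_pixel_value": self.net_values}
        ).to_csv(path, index=False)
        return path


def reference_table() -> CalibrationTable:
    """The packaged XR-QA2 red-channel dose-response table.

    Fourteen segments of one film sheet exposed to 0-200 mGy at 80 kV,
    scanned at 150 dpi; net pixel values are on the 16-bit scale.  This is
    the default calibration dataset of the package.
    """
    with resources.files("filmdose3d.data").joinpath(
        "xr_qa2_dose_response.csv"
    ).open("rb") as fh:
        df = pd.read_csv(fh)
    return CalibrationTable(
        doses=df["dose_mGy"].to_numpy(), net_values=df["net_pixel_value"].to_numpy()
    )


@dataclass
class CalibrationCurve:
    """Fitted double-exponential dose-response curve.

    ``dose_range`` is the interval over which the curve is valid (typically
    ``(0, 200)`` mGy for XR-QA2); ``stderr`` holds the coefficient standard
    errors from the linearised fit covariance when available.
    """

    y0: float
    A1: float
    B1: float
    A2: float
    B2: float
    dose_range: tuple[float, float] = (0.0, 200.0)
    stderr: dict[str, float] | None = None
    rms_residual: float | None = None

    def __post_init__(self) -> None:
        if self.B1 <= 0 or self.B2 <= 0:
            raise ValueError("decay rates B1, B2 must be positive")
        lo, hi = self.dose_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid dose_range {self.dose_range}")

    def __call__(self, dose):
        dose = np.asarray(dose, dtype=float)
        return (
            self.y0
            + self.A1 * np.exp(-self.B1 * dose)
            + self.A2 * np.exp(-self.B2 * dose)
        )

    def coefficients(self) -> dict[str, float]:
        return {
            "y0": self.y0,
            "A1": self.A1,
            "B1": self.B1,
            "A2": self.A2,
            "B2": self.B2,
        }

    def is_monotone(self, step_mGy: float = 1.0) -> bool:
        """Strict increase of the forward curve, checked on a dose grid."""
        lo, hi = self.dose_range
        grid = np.arange(lo, hi + step_mGy / 2, step_mGy)
        return bool(np.all(np.diff(self(grid)) > 0))

    def validate(self) -> None:
        """Raise if the curve violates its physical invariants."""
        if not self.is_monotone():
            raise ValueError("calibration curve is not monotone on its dose range")
        f0 = self(0.0)
        if abs(f0) > 0.05 * abs(self.y0):
            raise ValueError(
                f"zero-dose response {f0:.1f} exceeds 5% of the asymptote "
                f"{self.y0:.1f}; the fit does not pass near the origin"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": "y0 + A1*exp(-B1*x) + A2*exp(-B2*x)",
            "coefficients": self.coefficients(),
            "stderr": self.stderr,
            "dose_range_mGy": list(self.dose_range),
            "rms_residual": self.rms_residual,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        c = payload["coefficients"]
        return cls(
            y0=c["y0"],
            A1=c["A1"],
            B1=c["B1"],
            A2=c["A2"],
            B2=c["B2"],
            dose_range=tuple(payload.get("dose_range_mGy", (0.0, 200.0))),
            stderr=payload.get("stderr"),
            rms_residual=payload.get("rms_residual"),
        )


@dataclass
class DoseMap2D:
    """Calibrated 2D dose image on the film plane (mGy).

    ``mask`` flags pixels whose net value fell outside the calibrated
    response range (see ``FLAG_*`` constants).
    """

    values: np.ndarray
    dpi: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2D array")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def spacing_mm(self) -> float:
        return MM_PER_INCH / self.dpi


def _central_roi(
    roi: tuple[int, int, int, int], area_fraction: float
) -> tuple[int, int, int, int]:
    """Shrink an ROI about its centre to the given area fraction."""
    r0, c0, r1, c1 = roi
    keep = np.sqrt(area_fraction)  # per-axis linear fraction
    h, w = r1 - r0, c1 - c0
    dh = int(round(h * (1 - keep) / 2))
    dw = int(round(w * (1 - keep) / 2))
    # keep at least one pixel
    dh = min(dh, (h - 1) // 2)
    dw = min(dw, (w - 1) // 2)
    return (r0 + dh, c0 + dw, r1 - dh, c1 - dw)


def extract_segments(
    strip: NetImage,
    layout: list[tuple[float, tuple[int, int, int, int]]],
    area_fraction: float = 0.5,
) -> CalibrationTable:
    """Build a calibration table from a segmented exposure strip.

    ``layout`` lists ``(nominal_dose_mGy, (r0, c0, r1, c1))`` per segment.
    The net value of each segment is the mean over the central
    ``area_fraction`` of its ROI (margins trimmed to avoid segment-edge
    gradients).  Rows are returned sorted by dose.
    """
    nr, nc = strip.shape
    seen: list[tuple[int, int, int, int]] = []
    doses, values = [], []
    for dose, roi in layout:
        r0, c0, r1, c1 = roi
        if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
            raise ValueError(f"segment ROI {roi} outside strip of shape {strip.shape}")
        for other in seen:
            o0, oc0, o1, oc1 = other
            if r0 < o1 and o0 < r1 and c0 < oc1 and oc0 < c1:
                raise ValueError(f"segment ROIs overlap: {roi} and {other}")
        seen.append(roi)
        cr0, cc0, cr1, cc1 = _central_roi(roi, area_fraction)
        doses.append(float(dose))
        values.append(float(strip.values[cr0:cr1, cc0:cc1].mean()))
    order = np.argsort(doses)
    return CalibrationTable(
        doses=np.asarray(doses)[order], net_values=np.asarray(values)[order]
    )


def _double_exp(x, y0, A1, B1, A2, B2):
    return y0 + A1 * np.exp(-B1 * x) + A2 * np.exp(-B2 * x)


def _linear_solve(x, y, B1, B2):
    """Best (y0, A1, A2) for fixed decay rates; returns (params, SSE)."""
    M = np.column_stack([np.ones_like(x), np.exp(-B1 * x), np.exp(-B2 * x)])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    return coef, float(resid @ resid)


def _grid_init(x, y, n_nodes: int = 20, lo: float = 1e-3, hi: float = 0.5):
    """Deterministic starting point from a log-spaced (B1, B2) grid."""
    rates = np.geomspace(lo, hi, n_nodes)
    best = None
    for i, b1 in enumerate(rates):
        for b2 in rates[i + 1 :]:
            coef, sse = _linear_solve(x, y, b1, b2)
            if best is None or sse < best[0]:
                best = (sse, coef, b1, b2)
    sse, (y0, a1, a2), b1, b2 = best
    return np.array([y0, a1, b1, a2, b2])


def fit_calibration(
    table: CalibrationTable,
    init: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> CalibrationCurve:
    """Fit the double-exponential response to a calibration table.

    Unweighted least squares.  Unless ``init`` (order ``y0, A1, B1, A2, B2``)
    is supplied, the starting point comes from a 20x20 log-spaced grid over
    the two decay rates with a linear solve for the amplitudes at each node;
    Levenberg-Marquardt then refines all five coefficients.  Standard errors
    are taken from the linearised covariance at the optimum.  The two
    exponential terms are relabelled if needed so that ``B1 < B2``.
    """
    x, y = table.doses, table.net_values
    if np.ptp(y) == 0:
        raise ValueError("degenerate calibration table: constant net values")
    p0 = np.asarray(init, dtype=float) if init is not None else _grid_init(x, y)

    try:
        popt, pcov = curve_fit(
            _double_exp,
            x,
            y,
            p0=p0,
            maxfev=max_iter * 20,
            ftol=tol,
            xtol=1e-12,
        )
    except RuntimeError as exc:
        _, sse0 = _linear_solve(x, y, p0[2], p0[4])
        raise RuntimeError(
            f"calibration fit did not converge (best grid SSE {sse0:.3g}): {exc}"
        ) from exc

    perr = np.sqrt(np.diag(pcov))
    y0, a1, b1, a2, b2 = popt
    e0, ea1, eb1, ea2, eb2 = perr
    if b1 > b2:  # canonical ordering: slow term first
        a1, a2, b1, b2 = a2, a1, b2, b1
        ea1, ea2, eb1, eb2 = ea2, ea1, eb2, eb1
    resid = y - _double_exp(x, y0, a1, b1, a2, b2)
    curve = CalibrationCurve(
        y0=float(y0),
        A1=float(a1),
        B1=float(b1),
        A2=float(a2),
        B2=float(b2),
        dose_range=(0.0, float(x[-1])),
        stderr={
            "y0": float(e0),
            "A1": float(ea1),
            "B1": float(eb1),
            "A2": float(ea2),
            "B2": float(eb2),
        },
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )
    curve.validate()
    return curve


def dose_to_pixel(curve: CalibrationCurve, dose):
    """Forward model: net pixel value(s) expected at the given dose(s).

    Doses outside ``curve.dose_range`` are evaluated anyway (the model is
    defined everywhere) but negative doses are rejected.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = curve(dose)
    return float(out) if out.ndim == 0 else out


def pixel_to_dose(
    curve: CalibrationCurve,
    net_value,
    tol_mGy: float = 1e-3,
    return_flags: bool = False,
):
    """Invert the calibration curve by monotone bisection.

    Net values below the zero-dose response clamp to dose 0; values above
    the response at the top of the dose range clamp to that maximum dose.
    With ``return_flags=True`` a second array marks those pixels
    (``FLAG_BELOW_RANGE`` / ``FLAG_SATURATED``).
    """
    if not curve.is_monotone():
        raise ValueError(
            "calibration curve is not monotone on its dose range; inversion "
            "is undefined"
        )
    net = np.asarray(net_value, dtype=float)
    scalar = net.ndim == 0
    net = np.atleast_1d(net)
    lo_dose, hi_dose = curve.dose_range
    f_lo, f_hi = curve(lo_dose), curve(hi_dose)

    flags = np.zeros(net.shape, dtype=np.uint8)
    flags[net < f_lo] = FLAG_BELOW_RANGE
    flags[net > f_hi] = FLAG_SATURATED

    lo = np.full(net.shape, lo_dose)
    hi = np.full(net.shape, hi_dose)
    n_iter = int(np.ceil(np.log2((hi_dose - lo_dose) / tol_mGy))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = curve(mid) < net
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    dose = 0.5 * (lo + hi)
    dose[flags == FLAG_BELOW_RANGE] = lo_dose
    dose[flags == FLAG_SATURATED] = hi_dose
    # exact range endpoints invert exactly (no bisection residual)
    dose[net == f_lo] = lo_dose
    dose[net == f_hi] = hi_dose

    if scalar:
        dose = float(dose[0])
        flags = int(flags[0])
    if return_flags:
        return dose, flags
    return dose


def apply_calibration(image: NetImage, curve: CalibrationCurve) -> DoseMap2D:
    """Convert a net image to a dose map, flagging out-of-range pixels."""
    curve.validate()
    dose, flags = pixel_to_dose(curve, image.values, return_flags=True)
    return DoseMap2D(values=dose, dpi=image.dpi, mask=flags)
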
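"""Fit the dose-response calibration curve to the packaged film data.

The packaged table holds net red-channel pixel values of an XR-QA2 film
strip whose 14 segments were exposed to 0-200 mGy.  The double-exponential
model y(x) = y0 + A1*exp(-B1*x) + A2*exp(-B2*x) is fitted by unweighted
least squares; the coefficients below fully determine the pixel-to-dose
mapping used by the rest of the pipeline.
"""

import filmdose3d as fd

table = fd.reference_table()
curve = fd.fit_calibration(table)

print(f"fitted on {table.n} (dose, net value) pairs")
for name, value in curve.coefficients().items():
    print(f"  {name:>2} = {value:12.6g}  (se {curve.stderr[name]:.3g})")
print(f"  rms residual = {curve.rms_residual:.1f} counts "
      f"({100 * curve.rms_residual / curve.y0:.2f}% of the asymptote y0)")

# y0 is the saturation level the darkening approaches at high dose; B1 and
# B2 (per mGy) are the slow and fast response rates.  The inverse mapping
# turns a measured net value back into dose:
net = fd.dose_to_pixel(curve, 25.0)
print(f"forward: 25 mGy -> net value {net:.0f}")
print(f"inverse: net value {net:.0f} -> {fd.pixel_to_dose(curve, net):.3f} mGy")
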
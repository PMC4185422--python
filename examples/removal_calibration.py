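"""Quantify label-removal efficiency from a serial-dilution standard curve.

Standards (labelled lysate diluted into unlabelled lysate) calibrate signal
against label fraction; the treated lane is inverted through the curve.
When the treated signal drops below the lowest standard only a bound can be
reported: "more than X% removed".
"""

from vesiflux import calibration, scenes

# residual within the standard range: interpolated exactly
series = scenes.generate_dilution_series(
    [1.0, 0.1, 0.01, 1e-3, 1e-4], gain=1e6, noise_cv=0.0,
    residual_fraction=5e-4,
)
est = calibration.estimate_removal(series)
print(f"true residual 5e-4 -> {est.describe()}")

# residual below the lowest standard: reported as a bound
series = scenes.generate_dilution_series(
    [1.0, 0.1, 0.01, 1e-3], gain=1e6, noise_cv=0.0, residual_fraction=1e-4,
)
est = calibration.estimate_removal(series)
print(f"true residual 1e-4, standards stop at 1e-3 -> {est.describe()}")
print("The bound never overstates removal: the true value (99.99%) exceeds "
      "the reported 99.9% floor.")
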
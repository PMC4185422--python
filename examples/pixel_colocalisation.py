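"""Pixel-mask co-localisation with the 500 nm offset chance-overlap control.

The cargo channel is blurred, thresholded at the base of its histogram and
dilated into a binary mask; the reported percentage is the share of the
signal channel's intensity falling on mask-positive pixels. Repeating the
measurement with the mask shifted 500 nm along x estimates the overlap
expected by chance.
"""

from vesiflux import coloc, scenes

spec = scenes.SceneSpec(
    image_shape=(16, 512, 512),
    n_vesicles=300,
    cargo_positive_fraction=1.0,
    membrane_background={},
    macropinosome_rate=0.0,
    rng_seed=3,
    density_check="ignore",
)
stack, truth = scenes.generate_scene(spec)
signal = stack.channel("streptavidin").max(axis=0)
cargo = stack.channel("transferrin").max(axis=0)

mask_spec = coloc.MaskSpec(blur_sigma=0.7, dilation_radius=4)
mask = coloc.build_mask(cargo, mask_spec)
in_register = coloc.masked_fraction(signal, mask, roi=truth.cell_mask)
offset = coloc.offset_overlap_control(
    signal, cargo, mask_spec, roi=truth.cell_mask,
    offset_nm=500.0, pixel_size_nm=spec.voxel_size[2],
)

print(f"in-register co-localisation: {in_register.percent_coloc:.1f}%")
print(f"500 nm offset control:       {offset.percent_coloc:.1f}%")
print("Every vesicle carries cargo here, so the in-register value is near "
      "100% while the offset control falls to the chance-overlap level.")
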
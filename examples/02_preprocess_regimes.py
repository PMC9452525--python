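"""Turn one phantom mouse into the three network input regimes.

Shows the preprocessing chain (crop to body, then slice / whole-volume /
sliding-window conversion) and the training-sample filters: slices must
contain at least one organ voxel, patches more than 10% organ volume.
"""

from cryoseg import preprocess as pp
from cryoseg.phantom import PhantomSpec, generate_phantom

vol, lab = generate_phantom(PhantomSpec(seed=7))
cropped, clab = pp.crop_to_body(vol, lab, threshold=0.05)
print(f"cropped {vol.shape} -> {cropped.shape} (origin {cropped.origin_crop})")

slices = pp.make_slices(cropped, clab, slice_size=(160, 64))
kept = pp.filter_slices(slices)
print(f"2D-slices : {len(slices)} coronal slices, {len(kept)} contain organs")

whole = pp.make_whole(cropped, clab, size=(96, 32, 16))
print(f"3D-whole  : resampled to {whole.image.shape[:3]} from {whole.source_shape}")

patches = pp.make_patches(cropped, clab, window=(64, 32, 16), overlap=(16, 8, 4))
kept_p = pp.filter_patches(patches, min_fraction=0.10)
print(f"3D-patches: {len(patches)} windows (pad {patches[0].pad}), "
      f"{len(kept_p)} exceed the 10% organ filter")
# The filters concentrate training on informative samples: roughly half the
# coronal slices and a small minority of patches carry enough organ signal.
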
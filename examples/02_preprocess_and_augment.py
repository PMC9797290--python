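"""Walk one phantom through the stage-one preprocessing chain: intensity
window, Z-score, isotropic resampling, slice triplets, and both
augmentation schemes."""

from nodulenet import phantom, preprocess

vol, annotations = phantom.generate_volume(
    seed=3, shape=(40, 64, 64), spacing=(1.5, 1.5, 2.0), n_nodules=1,
    diameters_mm=[22.0],
)
print(f"native: shape {vol.shape}, spacing {vol.spacing} mm")

prepped = preprocess.preprocess_volume(vol)  # clip -> zscore -> 1 mm resample
print(f"resampled: shape {prepped.shape}, spacing {prepped.spacing} mm, "
      f"mean {prepped.voxels.mean():.2e}, sd {prepped.voxels.std():.3f}")

triplets = preprocess.augment_2d(prepped, annotations, out_size=128)
print(f"2D augmentation: {len(triplets)} triplets for one {annotations[0].diameter_mm:.0f} mm "
      f"nodule (centre slice plus +-1/+-2 neighbours; >20 mm bucket)")

cubes = preprocess.extract_multiscale_patches(prepped, annotations[0].center_world)
crops = preprocess.augment_3d(cubes, seed=0, label=1)
print(f"3D augmentation: {len(cubes)} enclosing cubes "
      f"{[c.shape[0] for c in cubes]} -> {len(crops)} multiscale samples "
      f"(25 shared-offset crops x 8 axis flips)")

# The 22 mm nodule lands in the >20 mm bucket, so stage one sees 5 triplets;
# stage two always multiplies each candidate by exactly 200.
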
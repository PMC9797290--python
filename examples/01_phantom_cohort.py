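"""Generate a synthetic CT phantom cohort and write it in the standard
on-disk formats (MetaImage volumes + a LUNA16-dialect annotation CSV)."""

from pathlib import Path

from nodulenet import io, phantom

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)

all_annotations = []
for i in range(3):
    vol, annotations = phantom.generate_volume(
        seed=i, shape=(64, 128, 128), n_nodules=2, n_distractors=3
    )
    io.write_volume(vol, out / f"{vol.scan_id}.mhd")
    all_annotations.extend(annotations)
    print(f"{vol.scan_id}: shape {vol.shape}, intensity range "
          f"[{vol.voxels.min()}, {vol.voxels.max()}] HU")

io.write_annotations(all_annotations, out / "annotations.csv")
for a in all_annotations:
    print(f"  nodule d={a.diameter_mm:5.1f} mm at world {tuple(round(c, 1) for c in a.center_world)}")

# Each scan has lung-like background near -850 HU with two bright
# quasi-spherical nodules (3-40 mm, soft-tissue intensity) plus unannotated
# vessel-like distractors; the CSV lists one world-coordinate row per nodule.
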
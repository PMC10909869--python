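"""Simulate a small multi-modal cohort with a planted disease effect.

Builds a toy atlas (ellipsoidal brain, 10 Voronoi-grown regions plus a
skull-like shell), then a cohort of 12 subjects with per-visit MRI and PET
scans. The disease effect is an intensity increase planted in one atlas
region per modality (different regions, so the modalities carry
complementary evidence); diagnosis timelines carry occasional label flips.
"""

import numpy as np

from neurofuse.synth import (
    TimelineParams,
    default_mri_spec,
    default_pet_spec,
    make_toy_atlas,
    simulate_cohort,
)

atlas = make_toy_atlas(grid_shape=(32, 32, 32), n_regions=10, seed=0)
print(f"atlas: {atlas.grid_shape} grid, {len(atlas.region_ids)} regions, "
      f"{int(atlas.brain_mask.sum())} brain voxels")

records, events = simulate_cohort(
    n_subjects=12, prevalence=0.5, atlas=atlas,
    mri_spec=default_mri_spec(), pet_spec=default_pet_spec(),
    timeline_params=TimelineParams(n_visits=3, flip_prob=0.1), seed=42)

n_pos = len({r.subject_id for r in records if r.meta["true_label"] == 1})
print(f"cohort: {len(records)} scans from 12 subjects "
      f"({n_pos} ever-positive), {len(events)} diagnosis events")

mri = next(r for r in records if r.modality == "MRI")
pet = next(r for r in records if r.modality == "PET")
print(f"MRI volume shape: {np.asarray(mri.volume_ref).shape} (3D)")
print(f"PET volume shape: {np.asarray(pet.volume_ref).shape} (4D: time frames)")
# The 4D PET axis is the acquisition time series; its per-voxel mean is the
# quantity the preprocessing pipeline condenses to a single 3D image.
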
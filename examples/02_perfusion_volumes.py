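"""Segment nested SPECT perfusion volumes (p20 ... p50) from a phantom.

The perfused lung is built in two steps: a boundary around all
tracer-containing voxels, then one mask per fractional-max threshold
(voxels holding >= 20%, 25%, 30%, 40%, 50% of the maximum voxel count
within the boundary).  The volumes shrink monotonically with the
threshold, and all perfused volumes are smaller than the anatomic lung
because the tumour-adjacent perfusion defect carries no tracer.
"""

from perflung import (
    PhantomSpec,
    anatomic_lung_volume,
    build_perfusion_set,
    generate_phantom,
    mask_volume_ml,
)

dose, spect, structures = generate_phantom(PhantomSpec(seed=1))
pset = build_perfusion_set(spect, structures.lungs)
anat = anatomic_lung_volume(structures)

print(f"max voxel perfusion count: {pset.max_count:.0f}")
print(f"anatomic lung: {mask_volume_ml(anat):7.0f} ml")
print(f"boundary:      {mask_volume_ml(pset.boundary):7.0f} ml")
for threshold, volume_ml in pset.volumes_ml().items():
    print(f"p{threshold * 100:.0f}:           {volume_ml:7.0f} ml")
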
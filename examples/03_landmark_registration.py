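"""Undo a simulated SPECT misalignment with landmark registration.

SPECT is acquired free-breathing while the planning CT is a breath-hold
scan, so the two volumes are misaligned.  This example shifts the
phantom SPECT 10 mm caudally, then recovers the alignment with a Kabsch
fit through five paired landmarks (the two lung apices, two hilar
points and the tumour-associated perfusion defect) and resamples onto
the planning grid.  The RMS landmark residual is the misregistration
diagnostic; the Dice overlap of the p20 volume against the unshifted
truth shows the registration quality.
"""

import numpy as np

from perflung import (
    ImageVolume,
    PhantomSpec,
    build_perfusion_set,
    generate_phantom,
    register_spect,
)

spec = PhantomSpec(seed=1)
dose, spect, structures = generate_phantom(spec)
truth_p20 = build_perfusion_set(spect, structures.lungs).p20.data.astype(bool)

# simulate a 10 mm caudal shift of the SPECT frame
shifted = ImageVolume(
    spect.data,
    spect.spacing,
    origin=(spect.origin[0], spect.origin[1], spect.origin[2] - 10.0),
    role="spect_counts",
)

landmarks_ct = np.array(
    [
        [75.0, 95.0, 230.0],  # left apex
        [205.0, 95.0, 230.0],  # right apex
        [120.0, 95.0, 145.0],  # left hilum
        [160.0, 95.0, 145.0],  # right hilum
        [190.0, 95.0, 160.0],  # tumour perfusion defect
    ]
)
landmarks_spect = landmarks_ct - [0.0, 0.0, 10.0]

aligned, result = register_spect(
    shifted, landmarks_spect, landmarks_ct, structures.grid
)
p20 = build_perfusion_set(aligned, structures.lungs).p20.data.astype(bool)
dice = 2 * (p20 & truth_p20).sum() / (p20.sum() + truth_p20.sum())

print(f"RMS landmark residual: {result.rms_residual_mm:.2e} mm")
print(f"Dice(p20 after registration, truth): {dice:.3f}")
# A residual near zero means the landmarks were consistent with a rigid
# motion; Dice ~1 confirms the perfusion volume is restored.
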
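"""Build a gray-white matter transition shell from a synthetic parcellation.

The shell is the one-voxel layer of white matter in face contact with gray
matter; each shell voxel is assigned to its adjacent region by majority
voting over the six faces, with seeded random draw resolution.
"""

import numpy as np

from gmac import build_shell, unite_gray_mask
from gmac.phantom import default_template_spec, make_phantom

phantom = make_phantom(default_template_spec(seed=0))
gray = unite_gray_mask(phantom.parcellation)

shell = build_shell(phantom.parcellation, phantom.wm_mask, seed=0)

print(f"gray matter voxels:        {int(gray.data.sum())}")
print(f"white matter voxels:       {int(phantom.wm_mask.data.sum())}")
print(f"transition shell voxels:   {len(shell)}")
for roi in shell.labels():
    print(f"  shell voxels owned by ROI {roi}: {len(shell.voxels_of(int(roi)))}")

# every shell voxel touches gray matter on at least one face and is white
from gmac import face_neighbor_labels

checked = all(face_neighbor_labels(phantom.parcellation, v) for v in shell.voxels)
print(f"all shell voxels face-adjacent to gray: {checked}")
# The per-ROI counts are the seed masks used for tractography: each region
# is seeded from its own shell segment, not from the gray matter itself.
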
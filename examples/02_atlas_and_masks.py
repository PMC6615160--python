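"""The built-in 19-node visual-network atlas and voxel mask utilities.

The atlas covers three intrinsic connectivity networks of visual cortex:
the primary visual network (PVN, 2 nodes), higher visual network (HVN,
4 nodes) and visuospatial network (VSN, 13 nodes).  Each node is a sphere
around an MNI coordinate on a 3 mm grid.
"""

import numpy as np

from visconn import attach_spherical_masks, extract_roi_timeseries, load_builtin_atlas
from visconn.atlas import atlas_to_label_volume

atlas = load_builtin_atlas()
print(f"{len(atlas)} nodes; sizes per network: {atlas.network_sizes()}")
for node in atlas.nodes[:3]:
    print(f"  {node.label:8s} {node.network:4s} center {node.mni_center}")

# Attach 6 mm spherical voxel masks (raises if any two spheres overlap).
masked = attach_spherical_masks(atlas, radius=6.0)
sizes = [len(n.mask) for n in masked.nodes]
print(f"6 mm spheres hold {min(sizes)}-{max(sizes)} voxels on the 3 mm grid")

# Render the atlas as an integer label volume (0 = background, k+1 = node k)
vol = np.asarray(atlas_to_label_volume(masked).dataobj)
print(f"label volume shape {vol.shape}, {np.count_nonzero(vol)} labeled voxels")

# Extract per-node voxel x time matrices from a synthetic 4-D image.
rng = np.random.default_rng(1)
img4d = rng.standard_normal((*vol.shape, 20))
roi_data = extract_roi_timeseries(img4d, masked)
print("extracted:", {k: v.shape for k, v in list(roi_data.items())[:2]})
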
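"""Node definitions for the three visual intrinsic connectivity networks.

The analysis graph is built on 19 regions of interest (ROIs) spanning the
primary visual network (PVN), the higher visual network (HVN) and the
visuospatial network (VSN).  Each node carries a short anatomical label, its
network membership and an MNI-space center (mm).  Volumetric data are mapped
onto the nodes through voxel masks; because the original group-level
parcellation volumes are not redistributable, spherical masks around the
published MNI centers are provided as a stand-in.

Node order is fixed forever (VSN block, then HVN, then PVN) so that row and
column ``i`` of every downstream matrix always refers to node ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NETWORKS = ("HVN", "PVN", "VSN")

# label, network, MNI center (x, y, z) in mm — fixed pipeline node order.
_BUILTIN_NODES = [
    ("lFEF", "VSN", (-27, -6, 55)),
    ("lPFt", "VSN", (-45, -39, 47)),
    ("lhIP3", "VSN", (-33, -55, 46)),
    ("lBA7p", "VSN", (-24, -73, 45)),
    ("lBA7a", "VSN", (-27, -61, 56)),
    ("lBA44", "VSN", (-48, 5, 33)),
    ("lBA45", "VSN", (-48, 21, 21)),
    ("lIT", "VSN", (-52, -68, -11)),
    ("rFEF", "VSN", (27, -3, 59)),
    ("rhIP3", "VSN", (30, -61, 49)),
    ("rPFt", "VSN", (48, -30, 44)),
    ("rBA44", "VSN", (48, 8, 30)),
    ("rIT", "VSN", (48, -61, -18)),
    ("lV3v", "HVN", (-30, -90, -12)),
    ("rV3v", "HVN", (27, -92, -16)),
    ("rV4", "HVN", (42, -83, -16)),
    ("rV2", "HVN", (21, -97, 11)),
    ("rV1", "PVN", (0, -81, 6)),
    ("lV1", "PVN", (-12, -62, 0)),
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular voxel grid with an affine index -> mm (MNI) mapping."""

    shape: tuple[int, int, int] = (61, 73, 61)
    voxel_size: float = 3.0
    origin: tuple[float, float, float] = (-90.0, -126.0, -72.0)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def mni_to_index(self, xyz) -> np.ndarray:
        """Nearest voxel index of an MNI mm coordinate (may be out of bounds)."""
        xyz = np.asarray(xyz, dtype=float)
        return np.rint((xyz - np.asarray(self.origin)) / self.voxel_size).astype(int)

    def index_to_mni(self, ijk) -> np.ndarray:
        return np.asarray(ijk, dtype=float) * self.voxel_size + np.asarray(self.origin)

    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        return np.ravel_multi_index(tuple(np.asarray(ijk).T), self.shape)

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        return np.column_stack(np.unravel_index(np.asarray(flat), self.shape))


@dataclass(frozen=True)
class RoiNode:
    label: str
    network: str
    mni_center: tuple[int, int, int]
    #: flat, sorted voxel indices on the atlas grid (None until masks attached)
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.network not in NETWORKS:
            raise ValueError(
                f"node {self.label!r}: network must be one of {NETWORKS}, "
                f"got {self.network!r}"
            )


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered node set; matrix row/column ``i`` refers to ``nodes[i]``."""

    nodes: tuple[RoiNode, ...]
    grid: VoxelGrid = field(default_factory=VoxelGrid)

    def __post_init__(self):
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels in atlas")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    @property
    def networks(self) -> list[str]:
        return [n.network for n in self.nodes]

    def network_indices(self, network: str) -> np.ndarray:
        if network not in NETWORKS:
            raise KeyError(network)
        return np.array([i for i, n in enumerate(self.nodes) if n.network == network])

    def network_sizes(self) -> dict[str, int]:
        return {k: len(self.network_indices(k)) for k in NETWORKS}

    def node(self, label: str) -> RoiNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def has_masks(self) -> bool:
        return all(n.mask is not None for n in self.nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "network": self.networks,
                "x": [n.mni_center[0] for n in self.nodes],
                "y": [n.mni_center[1] for n in self.nodes],
                "z": [n.mni_center[2] for n in self.nodes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_builtin_atlas() -> RoiAtlas:
    """The 19-node visual-network atlas (13 VSN, 4 HVN, 2 PVN), no masks."""
    return RoiAtlas(
        nodes=tuple(RoiNode(lab, net, xyz) for lab, net, xyz in _BUILTIN_NODES)
    )


def atlas_from_tsv(path, grid: VoxelGrid | None = None) -> RoiAtlas:
    df = pd.read_csv(path, sep="\t")
    nodes = tuple(
        RoiNode(r.label, r.network, (int(r.x), int(r.y), int(r.z)))
        for r in df.itertuples()
    )
    return RoiAtlas(nodes=nodes, grid=grid or VoxelGrid())


def attach_spherical_masks(
    atlas: RoiAtlas, radius: float = 6.0, grid: VoxelGrid | None = None
) -> RoiAtlas:
    """Attach spherical voxel masks of ``radius`` mm around each MNI center.

    Masks of distinct nodes must not overlap at the given radius, and every
    mask must contain at least one voxel.  Voxel membership is decided by the
    Euclidean distance between the voxel's mm coordinate and the node center.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0 mm, got {radius}")
    grid = grid or atlas.grid
    half = int(np.ceil(radius / grid.voxel_size)) + 1

    masks: list[np.ndarray] = []
    owner: dict[int, str] = {}
    for node in atlas.nodes:
        ci, cj, ck = grid.mni_to_index(node.mni_center)
        sel = []
        for i in range(ci - half, ci + half + 1):
            for j in range(cj - half, cj + half + 1):
                for k in range(ck - half, ck + half + 1):
                    if not (
                        0 <= i < grid.shape[0]
                        and 0 <= j < grid.shape[1]
                        and 0 <= k < grid.shape[2]
                    ):
                        continue
                    mm = grid.index_to_mni((i, j, k))
                    if np.linalg.norm(mm - np.asarray(node.mni_center, float)) <= radius:
                        sel.append((i, j, k))
        if not sel:
            raise ValueError(
                f"node {node.label!r}: empty mask at radius {radius} mm"
            )
        flat = np.sort(grid.ravel(np.asarray(sel)))
        for v in flat:
            v = int(v)
            if v in owner:
                raise ValueError(
                    f"mask overlap between nodes {owner[v]!r} and "
                    f"{node.label!r} at radius {radius} mm"
                )
            owner[v] = node.label
        masks.append(flat)

    nodes = tuple(replace(n, mask=m) for n, m in zip(atlas.nodes, masks))
    return RoiAtlas(nodes=nodes, grid=grid)


def atlas_to_label_volume(atlas: RoiAtlas):
    """Integer NIfTI label volume (label ``k + 1`` marks node ``k``)."""
    import nibabel as nib

    if not atlas.has_masks():
        raise ValueError("atlas has no masks attached")
    data = np.zeros(atlas.grid.shape, dtype=np.int16)
    for k, node in enumerate(atlas.nodes):
        ijk = atlas.grid.unravel(node.mask)
        data[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = k + 1
    return nib.Nifti1Image(data, atlas.grid.affine)


def atlas_from_label_volume(img, reference: RoiAtlas) -> RoiAtlas:
    """Rebuild masks from a label volume, preserving ``reference`` node order."""
    data = np.asarray(img.dataobj)
    grid = reference.grid
    if data.shape != grid.shape:
        raise ValueError(f"label volume shape {data.shape} != grid {grid.shape}")
    nodes = []
    for k, node in enumerate(reference.nodes):
        ijk = np.column_stack(np.nonzero(data == k + 1))
        if ijk.size == 0:
            raise ValueError(f"label {k + 1} ({node.label}) missing from volume")
        nodes.append(replace(node, mask=np.sort(grid.ravel(ijk))))
    return RoiAtlas(nodes=tuple(nodes), grid=grid)


def extract_roi_timeseries(volume4d, atlas: RoiAtlas):
    """Extract one voxel x time matrix per atlas node from a 4D image.

    ``volume4d`` may be a nibabel image or a plain 4D array on the atlas
    grid.  Voxels appear in sorted flat-index order.  Returns a dict
    ``label -> (n_voxels, t) array``.
    """
    if not atlas.has_masks():
        raise ValueError("atlas has no masks attached; call attach_spherical_masks")
    data = np.asarray(volume4d.dataobj if hasattr(volume4d, "dataobj") else volume4d)
    if data.ndim != 4:
        raise ValueError(f"expected 4D data, got shape {data.shape}")
    if data.shape[:3] != atlas.grid.shape:
        raise ValueError(
            f"grid mismatch: volume {data.shape[:3]} vs atlas {atlas.grid.shape}"
        )
    flat = data.reshape(-1, data.shape[3])
    out = {}
    for node in atlas.nodes:
        out[node.label] = np.array(flat[node.mask, :], dtype=float)
    return out


def pack_roi_volume(roi_data: dict, atlas: RoiAtlas):
    """Inverse of :func:`extract_roi_timeseries`: write ROI matrices into a
    4D NIfTI on the atlas grid (non-ROI voxels zero)."""
    import nibabel as nib

    if not atlas.has_masks():
        raise ValueError("atlas has no masks attached")
    t = next(iter(roi_data.values())).shape[1]
    flat = np.zeros((int(np.prod(atlas.grid.shape)), t), dtype=np.float32)
    for node in atlas.nodes:
        mat = np.asarray(roi_data[node.label])
        if mat.shape[0] != node.mask.size:
            raise ValueError(
                f"node {node.label}: {mat.shape[0]} voxel rows but mask has "
                f"{node.mask.size} voxels"
            )
        flat[node.mask, :] = mat
    return nib.Nifti1Image(flat.reshape(*atlas.grid.shape, t), atlas.grid.affine)
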
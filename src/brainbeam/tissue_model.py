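"""Four-layer voxelized head model and its optical property table.

The study volume is a 14 x 14 x 14 mm cube sampled at 0.1 mm isotropic
voxels (140^3 grid).  Along +z the cube is a stack of four planar tissue
slabs: scalp (3 mm), skull (5 mm), cerebrospinal fluid (2 mm) and gray
matter (4 mm).  Each voxel carries an integer tissue label; label 0 is
reserved for the background medium outside the cube (air, refractive
index 1), which is treated as effectively transparent: photons entering
it are scored as escaped energy.

Coordinate convention (imported by every other module): voxels are
0-based and half-open, voxel (i, j, k) spans
``[i*d, (i+1)*d) x [j*d, (j+1)*d) x [k*d, (k+1)*d)`` in mm with
``d = voxel_size_mm`` and the origin at the physical corner of voxel
(0, 0, 0).  z increases with depth; the illuminated surface is z = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

LABEL_NAMES = {0: "background", 1: "scalp", 2: "skull", 3: "csf", 4: "gray_matter"}

#: Tissue optical properties at 800 nm: label -> (mu_a 1/mm, mu_s 1/mm, g, n).
#: Background (label 0) is non-absorbing, effectively non-scattering air.
PROPERTIES_800NM = {
    0: (0.0, 0.001, 1.0, 1.0),
    1: (0.018, 19.0, 0.9, 1.37),
    2: (0.016, 16.0, 0.9, 1.43),
    3: (0.004, 2.4, 0.9, 1.33),
    4: (0.036, 22.0, 0.9, 1.37),
}


@dataclass(frozen=True)
class LayeredBrainSpec:
    """Geometry of the planar layered head phantom.

    Parameters
    ----------
    layer_thicknesses_mm : tuple of float
        Slab thicknesses along +z, ordered from the surface inward.
    voxel_size_mm : float
        Isotropic voxel edge length.
    lateral_extent_mm : float
        Side length of the cube in x and y.
    """

    layer_thicknesses_mm: tuple = (3.0, 5.0, 2.0, 4.0)
    voxel_size_mm: float = 0.1
    lateral_extent_mm: float = 14.0

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.lateral_extent_mm <= 0:
            raise ValueError("lateral_extent_mm must be positive")
        if not self.layer_thicknesses_mm or any(
            t <= 0 for t in self.layer_thicknesses_mm
        ):
            raise ValueError("layer thicknesses must be positive")

    @property
    def axial_extent_mm(self) -> float:
        return float(sum(self.layer_thicknesses_mm))

    @property
    def shape(self) -> tuple:
        nxy = _exact_voxel_count(self.lateral_extent_mm, self.voxel_size_mm, "lateral extent")
        nz = _exact_voxel_count(self.axial_extent_mm, self.voxel_size_mm, "axial extent")
        return (nxy, nxy, nz)


@dataclass
class LabeledVolume:
    """3D integer tissue-label grid with the physical coordinate convention.

    ``labels`` is indexed ``[i, j, k]`` for (x, y, z); ``origin_mm`` is the
    physical position of the low corner of voxel (0, 0, 0).
    """

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def extent_mm(self) -> tuple:
        return tuple(n * self.voxel_size_mm for n in self.labels.shape)

    def voxel_index(self, xyz_mm) -> tuple:
        """Voxel index containing a physical point (half-open convention)."""
        rel = (np.asarray(xyz_mm, float) - np.asarray(self.origin_mm)) / self.voxel_size_mm
        return tuple(int(np.floor(c)) for c in rel)

    def label_at(self, xyz_mm) -> int:
        i, j, k = self.voxel_index(xyz_mm)
        return int(self.labels[i, j, k])

    def label_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class OpticalPropertyTable:
    """Per-label optical properties: absorption and scattering coefficients
    (1/mm), Henyey-Greenstein anisotropy g, and refractive index n.

    Row 0 is the background medium.
    """

    rows: dict = field(default_factory=lambda: dict(PROPERTIES_800NM))

    def __post_init__(self):
        for label, (mua, mus, g, n) in self.rows.items():
            if mua < 0 or mus < 0:
                raise ValueError(f"label {label}: mu_a and mu_s must be >= 0")
            if not -1.0 <= g <= 1.0:
                raise ValueError(f"label {label}: g must lie in [-1, 1]")
            if n < 1.0:
                raise ValueError(f"label {label}: refractive index must be >= 1")

    def __getitem__(self, label: int) -> tuple:
        return self.rows[label]

    @property
    def n_labels(self) -> int:
        return max(self.rows) + 1

    def as_arrays(self):
        """Dense (mua, mus, g, n) arrays indexed by label, for the transport kernel."""
        L = self.n_labels
        mua = np.zeros(L)
        mus = np.zeros(L)
        g = np.zeros(L)
        n = np.ones(L)
        for label, (a, s, gg, nn) in self.rows.items():
            mua[label], mus[label], g[label], n[label] = a, s, gg, nn
        return mua, mus, g, n

    def validate_against(self, volume: LabeledVolume) -> None:
        present = set(volume.label_counts())
        missing = present - set(self.rows)
        if missing:
            raise ValueError(f"property table missing rows for labels {sorted(missing)}")


def _exact_voxel_count(length_mm: float, voxel_mm: float, what: str) -> int:
    n = length_mm / voxel_mm
    if abs(n - round(n)) > 1e-9 * max(1.0, n):
        raise ValueError(
            f"{what} of {length_mm} mm is not an integer multiple of the "
            f"{voxel_mm} mm voxel size"
        )
    return int(round(n))


def build_layered_volume(spec: LayeredBrainSpec | None = None) -> LabeledVolume:
    """Construct the labeled voxel volume for a planar layered head spec.

    Layers are stacked along +z in the order given, labeled 1..L.  Every
    thickness must be commensurate with the voxel size; a non-commensurate
    layer is rejected by name.
    """
    spec = spec or LayeredBrainSpec()
    nxy, _, nz = spec.shape
    labels = np.zeros((nxy, nxy, nz), dtype=np.uint8)
    k = 0
    for idx, thickness in enumerate(spec.layer_thicknesses_mm, start=1):
        nk = _exact_voxel_count(
            thickness, spec.voxel_size_mm, f"layer {idx} thickness"
        )
        labels[:, :, k : k + nk] = idx
        k += nk
    assert k == nz
    return LabeledVolume(labels=labels, voxel_size_mm=spec.voxel_size_mm)


def default_property_table() -> OpticalPropertyTable:
    """The study's tissue optical properties at 800 nm plus the background row."""
    return OpticalPropertyTable()


def layer_masks(volume: LabeledVolume, n_layers: int = 4):
    """Boolean mask per tissue layer 1..n_layers."""
    return [volume.labels == i for i in range(1, n_layers + 1)]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def save_nifti(volume: LabeledVolume, path) -> None:
    """Write the label volume as NIfTI-1 (uint8, isotropic spacing in mm)."""
    import nibabel as nib

    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.labels, affine)
    nib.save(img, str(path))


def save_raw(volume: LabeledVolume, path) -> None:
    """Write the labels as raw bytes plus a JSON sidecar describing the grid."""
    path = Path(path)
    volume.labels.tofile(path)
    sidecar = {
        "dims": list(volume.shape),
        "dtype": str(volume.labels.dtype),
        "order": "C (x fastest-varying last axis z)",
        "voxel_size_mm": volume.voxel_size_mm,
        "origin_mm": list(volume.origin_mm),
        "labels": LABEL_NAMES,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
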
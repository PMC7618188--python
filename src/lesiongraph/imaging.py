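"""Volumetric containers, NIfTI I/O and grid geometry.

All analysis happens on a single rectangular voxel grid in a common
stereotaxic space.  A :class:`Volume` is a 3D scalar array plus the affine
mapping voxel indices to world (mm) coordinates; a :class:`BrainTemplate`
additionally carries the brain mask and a compartment labelling (left/right
frontal, left/right posterior, medial wall) used for cohort inclusion and
for anchoring regions of interest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage


class Compartment(enum.IntEnum):
    """Anatomical compartment labels on the template grid."""

    OTHER = 0
    LEFT_FRONTAL = 1
    RIGHT_FRONTAL = 2
    LEFT_POSTERIOR = 3
    RIGHT_POSTERIOR = 4
    MEDIAL_WALL = 5


#: Compartment families eligible for cohort inclusion (frontal/posterior, by side).
INCLUSION_COMPARTMENTS = (
    Compartment.LEFT_FRONTAL,
    Compartment.RIGHT_FRONTAL,
    Compartment.LEFT_POSTERIOR,
    Compartment.RIGHT_POSTERIOR,
)


@dataclass(frozen=True)
class Volume:
    """A 3D scalar field on a voxel grid.

    Parameters
    ----------
    data
        3D array.  For ``kind="mask"`` values must be exactly {0, 1}.
    affine
        4x4 invertible voxel-to-world affine.
    kind
        Value semantics: ``"mask"``, ``"zscore"``, ``"weight"`` or ``"labels"``.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str = "weight"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {data.shape}")
        if not np.isfinite(data).all():
            raise ValueError("volume contains non-finite values")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.kind == "mask":
            vals = np.unique(data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask volume must be binary, found values {vals[:10]}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass(frozen=True)
class BrainTemplate:
    """Grid geometry, brain mask and compartment labels.

    ``labels`` holds :class:`Compartment` codes and is zero (``OTHER``)
    outside the brain mask; compartments are disjoint by construction.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    brain_mask: np.ndarray
    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.brain_mask).astype(bool)
        labels = np.asarray(self.labels).astype(np.int16)
        if mask.shape != tuple(self.shape) or labels.shape != tuple(self.shape):
            raise ValueError("brain_mask/labels do not match template shape")
        if (labels[~mask] != Compartment.OTHER).any():
            raise ValueError("compartment labels defined outside the brain mask")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "brain_mask", mask)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def n_brain_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def compartment_mask(self, compartment: Compartment) -> np.ndarray:
        return self.labels == int(compartment)


@dataclass(frozen=True)
class ROI:
    """A connected set of voxels on the analysis grid.

    ``voxels`` is an (n, 3) integer index array; provenance records the
    threshold and connected-component id it was extracted with.
    """

    voxels: np.ndarray
    shape: tuple[int, int, int]
    threshold: float | None = None
    component_id: int | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if vox.shape[0] == 0:
            raise ValueError("ROI must be non-empty")
        object.__setattr__(self, "voxels", vox)

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=np.uint8)
        mask[tuple(self.voxels.T)] = 1
        return mask

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def read_volume(path, kind: str = "weight") -> Volume:
    """Read a NIfTI volume from ``path``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume(data=data, affine=np.asarray(img.affine), kind=kind)


def read_mask(path) -> Volume:
    """Read a binary NIfTI lesion mask; rejects non-binary data."""
    return read_volume(path, kind="mask")


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI, preserving array values and affine exactly."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    nib.save(img, str(path))


write_mask = write_volume


def resample_mask(mask: Volume, factor: int, min_fraction: float = 0.5) -> Volume:
    """Downsample a binary mask by an integer factor.

    A coarse voxel is lesioned iff the fraction of lesioned fine voxels
    inside it is at least ``min_fraction``.  Dimensions not divisible by
    ``factor`` are zero-padded at the high end; the affine scales with the
    factor so world coordinates stay aligned.
    """
    if mask.kind != "mask":
        raise ValueError("resample_mask requires a binary mask volume")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    if factor == 1:
        return mask

    data = mask.data.astype(np.float64)
    pad = [(0, (-s) % factor) for s in data.shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad)
    nx, ny, nz = (s // factor for s in data.shape)
    blocks = data.reshape(nx, factor, ny, factor, nz, factor)
    frac = blocks.mean(axis=(1, 3, 5))
    coarse = (frac >= min_fraction - 1e-12).astype(np.uint8)

    affine = mask.affine.copy()
    affine[:3, :3] *= factor
    # voxel centre (0,0,0) on the coarse grid sits at the mean of its children
    centre_shift = (factor - 1) / 2.0
    affine[:3, 3] = mask.affine[:3, :3] @ np.full(3, centre_shift) + mask.affine[:3, 3]
    return Volume(data=coarse, affine=affine, kind="mask")


def resample_template(template: BrainTemplate, factor: int) -> BrainTemplate:
    """Coarsen a template by an integer factor.

    The brain mask follows the majority rule (>= 50% brain children);
    compartment labels take the majority label among in-brain children.
    """
    if factor == 1:
        return template
    brain_vol = Volume(template.brain_mask.astype(np.uint8), template.affine, "mask")
    coarse_brain = resample_mask(brain_vol, factor, min_fraction=0.5)
    shape = coarse_brain.shape
    labels = np.zeros(shape, dtype=np.int16)
    pad = [(0, (-s) % factor) for s in template.shape]
    lab = np.pad(template.labels, pad)
    msk = np.pad(template.brain_mask, pad)
    blocks_lab = lab.reshape(shape[0], factor, shape[1], factor, shape[2], factor)
    blocks_msk = msk.reshape(shape[0], factor, shape[1], factor, shape[2], factor)
    for idx in np.argwhere(coarse_brain.data):
        i, j, k = idx
        child_lab = blocks_lab[i, :, j, :, k, :].ravel()
        child_in = blocks_msk[i, :, j, :, k, :].ravel()
        vals = child_lab[child_in]
        if len(vals):
            labels[i, j, k] = np.bincount(vals).argmax()
    return BrainTemplate(
        shape=shape,
        voxel_size_mm=template.voxel_size_mm * factor,
        brain_mask=coarse_brain.astype_bool(),
        labels=labels,
        affine=coarse_brain.affine,
    )


def compartment_fractions(
    mask: Volume, template: BrainTemplate, threshold: float = 0.70
) -> tuple[dict[Compartment, float], Compartment | None]:
    """Lesion volume fraction per compartment and the inclusion decision.

    A patient is assigned to the compartment holding at least ``threshold``
    (default 70%) of the total lesion volume; lesions split across
    compartments below that bound are excluded (assignment ``None``).
    """
    lesion = mask.astype_bool()
    if lesion.shape != template.shape:
        raise ValueError("mask grid does not match template grid")
    total = int(lesion.sum())
    if total == 0:
        raise ValueError("empty lesion mask")
    fractions: dict[Compartment, float] = {}
    for comp in Compartment:
        if comp == Compartment.OTHER:
            continue
        fractions[comp] = float((lesion & (template.labels == int(comp))).sum()) / total
    assignment = None
    for comp in INCLUSION_COMPARTMENTS:
        if fractions[comp] >= threshold:
            assignment = comp
            break
    return fractions, assignment


def connected_components(
    mask: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Label connected components of a binary array."""
    return ndimage.label(mask, structure=_connectivity_structure(connectivity))


def extract_roi(
    zmap: Volume,
    threshold: float = 3.1,
    connectivity: int = 26,
    within: np.ndarray | None = None,
) -> ROI:
    """Extract the dominant suprathreshold connected component.

    Voxels with ``z > threshold`` (strict) are labelled into connected
    components.  If ``within`` (a binary anatomical label mask, e.g. the
    medial wall) is given, the largest component whose voxel majority lies
    inside it is returned; otherwise simply the largest component.
    """
    supra = zmap.data > threshold
    if not supra.any():
        raise ValueError(f"no voxel exceeds z > {threshold}")
    labelled, n_comp = connected_components(supra, connectivity)
    sizes = ndimage.sum_labels(supra, labelled, index=np.arange(1, n_comp + 1))
    candidates = []
    for cid in range(1, n_comp + 1):
        comp_mask = labelled == cid
        if within is not None:
            inside = float((comp_mask & within.astype(bool)).sum())
            if inside / comp_mask.sum() <= 0.5:
                continue
        candidates.append((sizes[cid - 1], cid))
    if not candidates:
        raise ValueError("no suprathreshold component falls within the requested label")
    _, best = max(candidates)
    voxels = np.argwhere(labelled == best)
    return ROI(voxels=voxels, shape=zmap.shape, threshold=threshold, component_id=best)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * float((a & b).sum()) / float(denom)
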
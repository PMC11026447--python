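"""Turn a 3D volume into the ordered 2D slice sequence for one plane.

This is the step that converts volumetric classification into sequence
classification: a volume on the (x, y, z) = (LR, PA, IS) grid becomes

* axial    — one slice per z index, each of shape (x, y),
* coronal  — one slice per y index, each of shape (x, z),
* sagittal — one slice per x index, each of shape (y, z),

in ascending index order. On the 113x137x113 MNI grid this yields 113
axial slices of 113x137, 137 coronal slices of 113x113 and 113 sagittal
slices of 137x113. Slices are then stretched (anisotropically, no padding)
to 224x224 for the patch-based encoder and replicated to three identical
channels to match RGB-pretrained weights. All slices are kept, including
near-empty background ones, so sequence length always equals the grid
extent along the plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume_io import Volume3D

__all__ = ["SliceSequence", "PLANES", "extract_slices", "resize_slice",
           "resize_sequence", "to_encoder_input", "restack", "export_slices"]

#: plane name -> axis normal to the slicing plane
PLANES: dict[str, int] = {"sagittal": 0, "coronal": 1, "axial": 2}

ENCODER_SIDE = 224


@dataclass
class SliceSequence:
    """Ordered stack of 2D slices from one plane of one volume."""

    slices: list[np.ndarray]
    plane: str
    source_shape: tuple[int, int]
    label: str | None = None
    subject_id: str | None = None

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def is_resized(self) -> bool:
        return all(s.shape == (ENCODER_SIDE, ENCODER_SIDE) for s in self.slices)


def extract_slices(vol: Volume3D, plane: str) -> SliceSequence:
    """Full 2D sections along the plane's normal axis, ascending index order."""
    if plane not in PLANES:
        raise ValueError(f"invalid plane {plane!r}; choose from {sorted(PLANES)}")
    axis = PLANES[plane]
    data = vol.data
    slices = [np.take(data, i, axis=axis) for i in range(data.shape[axis])]
    return SliceSequence(slices=slices, plane=plane,
                         source_shape=slices[0].shape,
                         label=vol.label, subject_id=vol.subject_id)


def restack(seq: SliceSequence) -> np.ndarray:
    """Inverse of :func:`extract_slices` (pre-resize): rebuild the volume array."""
    return np.stack(seq.slices, axis=PLANES[seq.plane])


def resize_slice(slc: np.ndarray, target: int = ENCODER_SIDE) -> np.ndarray:
    """Bilinear resize to target x target, output clipped to [0, 1]."""
    slc = np.asarray(slc, dtype=np.float64)
    if slc.size == 0:
        raise ValueError("cannot resize an empty slice")
    if target < 1:
        raise ValueError("target side must be >= 1")
    if slc.shape == (target, target):
        return slc.copy()
    out = _sk_resize(slc, (target, target), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def resize_sequence(seq: SliceSequence, target: int = ENCODER_SIDE) -> SliceSequence:
    return SliceSequence(slices=[resize_slice(s, target) for s in seq.slices],
                         plane=seq.plane, source_shape=seq.source_shape,
                         label=seq.label, subject_id=seq.subject_id)


def to_encoder_input(seq: SliceSequence, standardize: str = "none") -> np.ndarray:
    """Channelize a resized sequence into an (n_slices, 3, S, S) batch.

    Each grayscale slice is replicated to three identical channels.
    ``standardize`` selects the per-slice statistic policy:

    * ``"none"``      — intensities kept as-is (already in [0, 1]),
    * ``"per_slice"`` — zero mean / unit variance per slice (constant slices
      are left at zero),
    """
    if not seq.is_resized:
        raise ValueError("sequence must be resized to 224x224 before channelizing "
                         "(call resize_sequence)")
    batch = np.stack(seq.slices).astype(np.float64)          # (n, S, S)
    if standardize == "per_slice":
        mu = batch.mean(axis=(1, 2), keepdims=True)
        sd = batch.std(axis=(1, 2), keepdims=True)
        sd[sd == 0] = 1.0
        batch = (batch - mu) / sd
    elif standardize != "none":
        raise ValueError(f"unknown standardization policy {standardize!r}")
    return np.repeat(batch[:, None, :, :], 3, axis=1)        # (n, 3, S, S)


def export_slices(seq: SliceSequence, out_dir) -> None:
    """Inspection export: one 8-bit PNG per slice plus a JSON index."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, slc in enumerate(seq.slices):
        name = f"{seq.plane}_{i:04d}.png"
        iio.imwrite(out_dir / name,
                    np.clip(slc * 255.0, 0, 255).astype(np.uint8))
        names.append(name)
    index = {"plane": seq.plane, "n_slices": seq.n_slices,
             "source_shape": list(seq.source_shape),
             "order": "ascending source index", "files": names,
             "label": seq.label, "subject_id": seq.subject_id}
    with open(out_dir / "index.json", "w") as fh:
        json.dump(index, fh, indent=2)
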
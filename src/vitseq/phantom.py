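"""Synthetic skull-stripped-brain phantoms with class-conditional morphology.

The generator emulates MNI-registered, skull-stripped T1 volumes just enough
to exercise the slice-sequence classification pipeline without clinical data:

* an ellipsoidal "brain" of mid-gray tissue centred in the grid,
* a central ellipsoidal near-zero cavity standing in for the ventricles,
  whose radius grows with disease severity (NC < MCI < AD) — a crude
  atrophy proxy,
* a bright peripheral "cortical" band whose intensity falls with severity,
* exact-zero background outside the brain, and
* additive Gaussian noise inside the brain, clipped to [0, 1].

A single ``separability`` knob scales all between-class differences: at 0
every class collapses onto the NC morphology, so any classifier can do no
better than chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import Volume3D, default_affine, write_manifest, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "save_dataset", "CLASS_ORDER"]

#: canonical severity order of the diagnostic classes
CLASS_ORDER: tuple[str, ...] = ("NC", "MCI", "AD")

# stream tags keeping morphology jitter class-independent while noise is
# class-specific (so separability=0 + noise_sd=0 gives identical volumes
# across classes at the same index)
_MORPH_TAG = 7919
_NOISE_TAG = 104729


@dataclass
class PhantomSpec:
    """Parameters of the synthetic volume generator.

    ``ventricle_radius_by_class`` / ``cortical_intensity_by_class`` give the
    full-separability values; the effective value for a class is the NC value
    plus ``separability`` times the class offset from NC.
    """

    grid_shape: tuple[int, int, int] = (113, 137, 113)
    n_per_class: int = 10
    classes: tuple[str, ...] = ("NC", "MCI", "AD")
    ventricle_radius_by_class: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.12, "MCI": 0.20, "AD": 0.30})
    cortical_intensity_by_class: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.90, "MCI": 0.82, "AD": 0.74})
    noise_sd: float = 0.05
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be a triple with entries >= 16")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        unknown = set(self.classes) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}; "
                             f"must be subset of {CLASS_ORDER}")
        for cls in self.classes:
            r = self.ventricle_radius_by_class[cls]
            if not 0.0 <= r < 1.0:
                raise ValueError(f"ventricle radius for {cls} must be in [0,1)")
            c = self.cortical_intensity_by_class[cls]
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"cortical intensity for {cls} must be in [0,1]")
        if self.separability > 0:
            sev = [c for c in CLASS_ORDER if c in self.classes]
            radii = [self.ventricle_radius_by_class[c] for c in sev]
            if any(b <= a for a, b in zip(radii, radii[1:])):
                raise ValueError(
                    "ventricle radii must strictly increase with severity "
                    "(NC < MCI < AD) when separability > 0")


def _effective(spec: PhantomSpec, table: dict[str, float], cls: str) -> float:
    base = table["NC"]
    return base + spec.separability * (table[cls] - base)


def generate_phantom(spec: PhantomSpec, class_label: str, index: int) -> Volume3D:
    """One labelled phantom volume, deterministic given (seed, class, index)."""
    if class_label not in spec.classes:
        raise ValueError(f"unknown class label {class_label!r}; "
                         f"spec declares {spec.classes}")
    if index < 0:
        raise ValueError("index must be >= 0")
    cls_idx = CLASS_ORDER.index(class_label)
    nx, ny, nz = spec.grid_shape

    r_vent = _effective(spec, spec.ventricle_radius_by_class, class_label)
    cortical = _effective(spec, spec.cortical_intensity_by_class, class_label)
    min_semi = 0.45 * min(spec.grid_shape)
    if r_vent > 0 and r_vent * min_semi < 1.0:
        # ventricle smaller than one voxel: the grid cannot carry the signal
        raise ValueError(f"grid {spec.grid_shape} too small for ventricle "
                         f"radius fraction {r_vent}")

    # morphology jitter is shared across classes at a given index
    morph_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _MORPH_TAG, index]))
    jitter = 1.0 + 0.03 * morph_rng.uniform(-1.0, 1.0, size=3)

    # normalized ellipsoidal radius rho: brain = {rho <= 1}
    semi = 0.45 * np.array([nx, ny, nz]) * jitter
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x = (np.arange(nx) - cx)[:, None, None] / semi[0]
    y = (np.arange(ny) - cy)[None, :, None] / semi[1]
    z = (np.arange(nz) - cz)[None, None, :] / semi[2]
    rho = np.sqrt(x ** 2 + y ** 2 + z ** 2)

    brain = rho <= 1.0
    ventricle = rho <= r_vent
    cortex = (rho >= 0.82) & brain

    data = np.zeros(spec.grid_shape, dtype=np.float64)
    data[brain] = 0.45            # parenchyma
    data[cortex] = cortical       # bright peripheral band
    data[ventricle] = 0.02        # CSF-like hypointensity

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, _NOISE_TAG, cls_idx, index]))
        data[brain] += noise_rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        np.clip(data, 0.0, 1.0, out=data)
        data[~brain] = 0.0

    return Volume3D(data=data, affine=default_affine(spec.grid_shape),
                    label=class_label,
                    subject_id=f"phantom-{class_label}-{index:04d}")


def generate_dataset(spec: PhantomSpec) -> list[Volume3D]:
    """``n_per_class`` phantoms per class, reproducible volume by volume."""
    return [generate_phantom(spec, cls, i)
            for cls in spec.classes
            for i in range(spec.n_per_class)]


def save_dataset(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write the dataset as .nii.gz files plus a labels CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in generate_dataset(spec):
        fname = f"{vol.subject_id}.nii.gz"
        write_volume(vol, out_dir / fname)
        rows.append({"filename": fname, "label": vol.label,
                     "subject_id": vol.subject_id})
    return write_manifest(rows, out_dir / "labels.csv")
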
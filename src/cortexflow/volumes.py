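"""Labelled-volume I/O, tissue/lobe mapping and regional volumetrics.

A :class:`LabelVolume` is a 3D integer segmentation with physical spacing,
read from and written to NIfTI-1.  A :class:`RegionScheme` maps each label
to a (tissue class, lobe) pair; regional volumes in ml follow by counting
voxels.  "Whole brain" is defined here as cGM + WM + deep grey matter +
cerebellum, excluding ventricles and extra-axial CSF (which are reported
as separate rows).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TISSUE_CLASSES",
    "LOBES",
    "LabelVolume",
    "RegionScheme",
    "read_label_volume",
    "write_label_volume",
    "tissue_volumes",
    "combine_regions",
    "UnmappedLabelError",
]

TISSUE_CLASSES = (
    "cGM",
    "WM",
    "deepGM",
    "cerebellum",
    "ventricle",
    "extra_axial_CSF",
    "background",
)
LOBES = ("frontal", "parietal", "temporal", "occipital", "none")

#: tissue classes summed into the "Whole brain" row (ventricles and
#: extra-axial CSF are listed separately, as in neonatal volumetric reports)
BRAIN_TISSUES = ("cGM", "WM", "deepGM", "cerebellum")


class UnmappedLabelError(KeyError):
    """A label present in the volume has no entry in the region scheme."""


@dataclass
class LabelVolume:
    """3D integer-labelled voxel grid with physical spacing (mm)."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must have an integer dtype")
        if np.any(self.voxels < 0):
            raise ValueError("labels must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 strictly positive reals")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def labels_present(self) -> np.ndarray:
        return np.unique(self.voxels)


@dataclass
class RegionScheme:
    """Total mapping label -> (tissue class, lobe)."""

    mapping: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, tuple[str, str]] = {}
        for label, (tissue, lobe) in self.mapping.items():
            if tissue not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {tissue!r} for label {label}")
            if lobe not in LOBES:
                raise ValueError(f"unknown lobe {lobe!r} for label {label}")
            clean[int(label)] = (tissue, lobe)
        self.mapping = clean

    def tissue(self, label: int) -> str:
        return self.mapping[label][0]

    def lobe(self, label: int) -> str:
        return self.mapping[label][1]

    def labels_for(self, tissues, lobes) -> set[int]:
        tissues, lobes = set(tissues), set(lobes)
        return {
            lab
            for lab, (t, lo) in self.mapping.items()
            if t in tissues and lo in lobes
        }

    def check_covers(self, lv: LabelVolume) -> None:
        missing = sorted(set(lv.labels_present().tolist()) - set(self.mapping))
        if missing:
            raise UnmappedLabelError(
                f"labels present in the volume but absent from the scheme: {missing}"
            )

    # -- serialisation ------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "RegionScheme":
        mapping = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[int(row["label"])] = (row["tissue"], row["lobe"])
        return cls(mapping)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "tissue", "lobe"])
            for lab in sorted(self.mapping):
                t, lo = self.mapping[lab]
                w.writerow([lab, t, lo])

    @classmethod
    def from_json(cls, path) -> "RegionScheme":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({int(k): (v["tissue"], v["lobe"]) for k, v in raw.items()})

    def to_json(self, path) -> None:
        raw = {str(k): {"tissue": t, "lobe": lo} for k, (t, lo) in self.mapping.items()}
        Path(path).write_text(json.dumps(raw, indent=1))


def read_label_volume(path) -> LabelVolume:
    """Load a NIfTI-1/2 segmentation.

    Rejects 4D inputs and non-integral data; float-typed files whose values
    are all integral are accepted with an integer cast.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: label volumes must be 3D (got {data.ndim}D); "
            "4D time series are not segmentations"
        )
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(
                f"{path.name}: data are not integer-valued; a label volume is required"
            )
        data = rounded.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(voxels=data, spacing_mm=spacing, affine=np.asarray(img.affine))


def write_label_volume(lv: LabelVolume, path) -> None:
    img = nib.Nifti1Image(lv.voxels.astype(np.int16), lv.affine)
    img.header.set_zooms(lv.spacing_mm)
    nib.save(img, str(path))


def tissue_volumes(lv: LabelVolume, scheme: RegionScheme) -> dict[str, float]:
    """Regional volumes in ml.

    Rows: whole brain, the six tissue classes (background excluded), and
    per-lobe cortical grey matter.  volume(region) = voxel count x voxel
    volume; whole brain = cGM + WM + deepGM + cerebellum.
    """
    scheme.check_covers(lv)
    counts = np.bincount(lv.voxels.ravel())
    vv = lv.voxel_volume_ml

    by_tissue = {t: 0.0 for t in TISSUE_CLASSES}
    by_lobe_cgm = {lo: 0.0 for lo in LOBES}
    for lab, (tissue, lobe) in scheme.mapping.items():
        n = int(counts[lab]) if lab < len(counts) else 0
        by_tissue[tissue] += n * vv
        if tissue == "cGM":
            by_lobe_cgm[lobe] += n * vv

    report = {"whole_brain": sum(by_tissue[t] for t in BRAIN_TISSUES)}
    report["cortical_grey_matter"] = by_tissue["cGM"]
    report["white_matter"] = by_tissue["WM"]
    report["deep_grey_matter"] = by_tissue["deepGM"]
    report["cerebellum"] = by_tissue["cerebellum"]
    report["ventricles"] = by_tissue["ventricle"]
    report["extra_axial_csf"] = by_tissue["extra_axial_CSF"]
    for lobe in LOBES[:4]:
        report[f"{lobe}_grey_matter"] = by_lobe_cgm[lobe]
    return report


def combine_regions(lv: LabelVolume, scheme: RegionScheme, tissues, lobes) -> np.ndarray:
    """Binary mask of voxels whose (tissue, lobe) pair matches the request."""
    tissues, lobes = list(tissues), list(lobes)
    if not tissues or not lobes:
        raise ValueError("empty tissue or lobe selection")
    unknown_t = set(tissues) - set(TISSUE_CLASSES)
    unknown_l = set(lobes) - set(LOBES)
    if unknown_t or unknown_l:
        raise ValueError(f"unknown selection: tissues {unknown_t}, lobes {unknown_l}")
    scheme.check_covers(lv)
    wanted = scheme.labels_for(tissues, lobes)
    return np.isin(lv.voxels, sorted(wanted))
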
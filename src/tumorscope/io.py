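"""Reading and writing phantom cases in plain interoperable formats.

Layout of a case directory::

    <case>/
      slices/slice_000.png ...   8-bit grayscale
      masks/mask_000.png ...     8-bit {0, 255}
      annotations.csv            case_id,slice_index,nodule_id,x_min,y_min,x_max,y_max
      tumor_volume.nii.gz        uint8 occupancy, spacing in the affine
      meta.yaml                  case_id, seed, slice count

Masks round-trip bit-identically; slice intensities round-trip within the
8-bit quantization bound of 1/255.  ``read_dicom_series`` maps one DICOM
series to a slice stack for users with clinical data.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .datatypes import (MaskImage, PhantomCase, SliceImage, TumorAnnotation,
                        VoxelVolume)
from .phantom import normalize_intensity

__all__ = ["write_case", "read_case", "read_dicom_series",
           "write_volume", "read_volume", "ANNOTATION_COLUMNS"]

ANNOTATION_COLUMNS = ["case_id", "slice_index", "nodule_id",
                      "x_min", "y_min", "x_max", "y_max"]


def write_volume(path: Path, volume: VoxelVolume) -> None:
    """Write a volume as NIfTI; the affine carries the voxel spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    nib.save(img, str(path))


def read_volume(path: Path) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(s) for s in np.abs(np.diag(img.affine)[:3]))
    return VoxelVolume(np.clip(data, 0.0, 1.0), spacing=spacing)


def write_case(path: str | Path, case: PhantomCase) -> None:
    root = Path(path)
    (root / "slices").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s, m in zip(case.slices, case.masks):
        arr8 = np.round(s.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(
            root / "slices" / f"slice_{s.slice_index:03d}.png")
        Image.fromarray(m.labels * np.uint8(255), mode="L").save(
            root / "masks" / f"mask_{s.slice_index:03d}.png")
    rows = [{"case_id": case.case_id, "slice_index": a.slice_index,
             "nodule_id": a.nodule_id, "x_min": a.box[0], "y_min": a.box[1],
             "x_max": a.box[2], "y_max": a.box[3]}
            for a in case.annotations]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        root / "annotations.csv", index=False)
    write_volume(root / "tumor_volume.nii.gz", case.tumor_volume)
    with open(root / "meta.yaml", "w") as fh:
        yaml.safe_dump({"case_id": case.case_id, "seed": int(case.seed),
                        "n_slices": len(case.slices)}, fh)


def read_case(path: str | Path) -> PhantomCase:
    root = Path(path)
    meta_path = root / "meta.yaml"
    try:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        case_id, seed = meta["case_id"], int(meta["seed"])
    except (OSError, KeyError, TypeError, yaml.YAMLError) as exc:
        raise ValueError(f"{meta_path}: malformed case metadata ({exc})") from exc

    slice_paths = sorted((root / "slices").glob("slice_*.png"))
    mask_paths = sorted((root / "masks").glob("mask_*.png"))
    if not slice_paths or len(slice_paths) != len(mask_paths):
        raise ValueError(f"{root}: slice/mask files missing or unpaired")
    slices, masks = [], []
    for i, (sp, mp) in enumerate(zip(slice_paths, mask_paths)):
        px = np.asarray(Image.open(sp), dtype=np.float64) / 255.0
        slices.append(SliceImage(px, case_id=case_id, slice_index=i))
        mk = np.asarray(Image.open(mp))
        masks.append(MaskImage((mk > 127).astype(np.uint8)))

    ann_path = root / "annotations.csv"
    try:
        df = pd.read_csv(ann_path)
    except Exception as exc:
        raise ValueError(f"{ann_path}: unreadable annotations ({exc})") from exc
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{ann_path}: missing column {col!r}")
    annotations = [
        TumorAnnotation(slice_index=int(r.slice_index),
                        box=(float(r.x_min), float(r.y_min),
                             float(r.x_max), float(r.y_max)),
                        nodule_id=str(r.nodule_id))
        for r in df.itertuples()
    ]
    volume = read_volume(root / "tumor_volume.nii.gz")
    return PhantomCase(slices=slices, masks=masks, annotations=annotations,
                       tumor_volume=volume, seed=seed)


def read_dicom_series(directory: str | Path) -> list[SliceImage]:
    """Read one DICOM series directory into a normalized slice stack.

    Slices are ordered by InstanceNumber (falling back to filename) and each
    is min-max normalized to [0, 1].
    """
    import pydicom

    paths = sorted(Path(directory).glob("*.dcm"))
    if not paths:
        raise ValueError(f"{directory}: no .dcm files found")
    entries = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
            order = int(getattr(ds, "InstanceNumber", len(entries)))
            entries.append((order, p.name, ds.pixel_array.astype(np.float64)))
        except Exception as exc:
            raise ValueError(f"{p}: unreadable DICOM file ({exc})") from exc
    entries.sort(key=lambda e: (e[0], e[1]))
    case_id = Path(directory).name
    return [SliceImage(normalize_intensity(arr), case_id=case_id, slice_index=i)
            for i, (_, _, arr) in enumerate(entries)]
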
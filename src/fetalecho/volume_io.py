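"""Read/write label and grey volumes (NRRD, NIfTI, MetaImage) via SimpleITK.

The in-memory convention is an (x, y, z)-indexed numpy array with
per-axis spacing and a world origin at the centre of voxel (0, 0, 0);
SimpleITK stores arrays (z, y, x), so axes are transposed on the way
through.  Label maps ride along in a YAML sidecar (``<stem>.labels.yaml``)
because none of the three formats carries one natively.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .synthetic_heart import LabelVolume

_SUFFIXES = (".nrrd", ".nii", ".nii.gz", ".mhd", ".mha")


def _sidecar(path: Path) -> Path:
    stem = path.name
    for suf in _SUFFIXES:
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.parent / f"{stem}.labels.yaml"


def save_label_volume(vol: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.array.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({int(k): v for k, v in vol.label_map.items()}, fh)


def load_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = sitk.ReadImage(str(path))
    array = sitk.GetArrayFromImage(img).T
    label_map: dict[int, str] = {}
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as fh:
            label_map = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    else:
        label_map = {int(l): f"label_{int(l)}"
                     for l in np.unique(array) if l != 0}
    return LabelVolume(
        array=np.asarray(array), spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()), label_map=label_map)


def save_grey_volume(grey: np.ndarray, spacing, origin,
                     path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grey.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def load_grey_volume(path: str | Path):
    """Returns (array, spacing, origin) with the (x, y, z) convention."""
    img = sitk.ReadImage(str(path))
    return (sitk.GetArrayFromImage(img).T.astype(np.float32),
            tuple(img.GetSpacing()), tuple(img.GetOrigin()))
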
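"""NIfTI / text readers and writers for the on-disk dataset layout."""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldSeries, EcMap, StatMap

__all__ = [
    "load_bold",
    "load_mask",
    "load_motion",
    "save_map",
    "save_ecmap",
    "save_statmap",
    "load_dataset_dir",
]


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


def load_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(str(path))
    motion = np.atleast_2d(motion)
    if motion.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    return motion


def load_bold(
    path: str | Path,
    brain_mask: np.ndarray,
    tr_s: float,
    subject_id: str = "",
) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return BoldSeries(
        data,
        tuple(float(z) for z in zooms),
        tr_s,
        brain_mask,
        affine=np.asarray(img.affine),
        subject_id=subject_id,
    )


def save_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_ecmap(ecmap: EcMap, affine: np.ndarray, path: str | Path) -> None:
    """EC map as NIfTI plus a JSON sidecar with its provenance fields."""
    import json

    save_map(ecmap.data, affine, path)
    sidecar = {
        "subject": ecmap.subject_id,
        "seed": ecmap.seed_label,
        "direction": ecmap.direction,
        "lag": 1,
        "n_degenerate_voxels": (
            int(ecmap.degenerate_mask.sum()) if ecmap.degenerate_mask is not None else 0
        ),
    }
    with open(str(Path(path).with_suffix("").with_suffix("")) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def save_statmap(stat: StatMap, path: str | Path) -> None:
    save_map(stat.t, stat.affine, path)


def load_dataset_dir(
    data_dir: str | Path, tr_s: float = 2.5
) -> tuple[list[BoldSeries], list[np.ndarray], pd.DataFrame, dict[str, np.ndarray]]:
    """Read a dataset written by :func:`seedgc.synth.write_dataset`.

    Returns (subjects, motion tables, subjects/scales table, masks dict).
    """
    data_dir = Path(data_dir)
    table = pd.read_csv(data_dir / "subjects.tsv", sep="\t")
    masks = {}
    for name in ("brain_mask", "csf_mask", "wm_mask", "seed_mask"):
        p = data_dir / f"{name}.nii.gz"
        if p.exists():
            masks[name] = load_mask(p)
    subjects, motion = [], []
    for sid in table["subject_id"]:
        bold_path = data_dir / f"{sid}_bold.nii.gz"
        if not bold_path.exists():
            raise FileNotFoundError(f"missing BOLD file: {bold_path}")
        subjects.append(load_bold(bold_path, masks["brain_mask"], tr_s, sid))
        motion.append(load_motion(data_dir / f"{sid}_motion.txt"))
    return subjects, motion, table, masks
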
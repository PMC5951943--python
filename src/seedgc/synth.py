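"""Synthetic multi-subject resting-state datasets with known directed influences.

The generator emulates the dimensions of a typical clinical resting-state
acquisition (240 volumes at TR 2.5 s, 3 mm isotropic voxels) on a small 3D
grid.  Three disjoint cubic regions are planted:

* a *seed* region whose voxels share a latent AR(1) signal,
* a *forward target* region whose voxels follow
  ``Y_t = a X_{t-1} + b Y_{t-1} + noise`` with the forward coefficient ``a``
  drawn per subject around a group-specific value,
* a *reverse source* region whose shared latent drives the seed the same way.

On top of the planted signals every voxel receives spatially smoothed
background noise, slow global/WM/CSF-like drifts, and six motion-like
random-walk components (also written to the motion tables).  A synthetic
insomnia-severity score (ISI) is linearly coupled to each subject's planted
forward coefficient; the remaining scales (PSQI, SAS, SDS) are noisy monotone
transforms of ISI.  Identical spec + seed gives bit-identical output.

The default group layout mirrors a patient/control contrast in which the
patient group has the *weaker* forward influence, so the expected
patient-minus-control difference in the target region is negative and the
ISI coupling (negative slope) makes higher scores go with lower planted
coefficients.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import smooth_gaussian
from .types import BoldSeries, GroupDesign, default_affine

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SyntheticDataset",
    "default_regions",
    "simulate_dataset",
    "simulate_null_maps",
    "write_dataset",
]


def _block(shape, lo, size) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : lo[0] + size, lo[1] : lo[1] + size, lo[2] : lo[2] + size] = True
    return m


def default_regions(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Disjoint 3x3x3 blocks for seed / forward target / reverse source,
    plus WM- and CSF-like corner blocks used for nuisance extraction."""
    if min(grid_shape) < 14:
        raise ValueError("default regions need a grid of at least 14 per axis")
    c = tuple(s // 2 - 1 for s in grid_shape)
    return {
        "seed": _block(grid_shape, (2, c[1], c[2]), 3),
        "forward_target": _block(grid_shape, (grid_shape[0] - 6, c[1], c[2]), 3),
        "reverse_source": _block(grid_shape, (c[0], 1, c[2]), 3),
        "wm": _block(grid_shape, (grid_shape[0] - 4, grid_shape[1] - 4, 1), 3),
        "csf": _block(grid_shape, (1, grid_shape[1] - 4, grid_shape[2] - 4), 3),
    }


@dataclass
class SimulationSpec:
    """Layout, effect sizes and noise model of one synthetic study.

    ``a_forward_by_group`` / ``a_reverse_by_group`` give the lag-1 directed
    coefficients for (group 1, group 2); per subject the planted value is the
    group value plus Normal(0, ``coef_jitter_sd``) jitter so the ROI stage has
    a continuous relationship to recover.  ``scale_coupling`` is the slope of
    the synthetic ISI on the subject's planted forward coefficient.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_timepoints: int = 240
    tr_s: float = 2.5
    n_per_group: tuple[int, int] = (12, 12)
    group_names: tuple[str, str] = ("patient", "control")
    seed_region: np.ndarray | None = None
    forward_target_region: np.ndarray | None = None
    reverse_source_region: np.ndarray | None = None
    wm_region: np.ndarray | None = None
    csf_region: np.ndarray | None = None
    a_forward_by_group: tuple[float, float] = (0.0, 0.4)
    a_reverse_by_group: tuple[float, float] = (0.0, 0.25)
    b_auto: float = 0.3
    coef_jitter_sd: float = 0.05
    noise_sd: float = 1.0
    background_sd: float = 0.35
    drift_amplitude: float = 0.3
    motion_step_mm: float = 0.01
    motion_step_rad: float = 0.0002
    smooth_fwhm_mm: float = 3.0
    isi_intercept: float = 19.5
    scale_coupling: float = -30.0
    scale_noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or self.n_timepoints <= 0:
            raise ValueError("grid dimensions and n_timepoints must be positive")
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("both groups need at least one subject")
        if self.tr_s <= 0 or self.noise_sd <= 0 or self.scale_noise_sd <= 0:
            raise ValueError("tr_s, noise_sd and scale_noise_sd must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.seed_region is None:
            regions = default_regions(self.grid_shape)
            self.seed_region = regions["seed"]
            self.forward_target_region = regions["forward_target"]
            self.reverse_source_region = regions["reverse_source"]
            self.wm_region = regions["wm"]
            self.csf_region = regions["csf"]
        for name in ("seed_region", "forward_target_region", "reverse_source_region"):
            m = getattr(self, name)
            if m is None or m.shape != tuple(self.grid_shape) or not m.any():
                raise ValueError(f"{name} must be a nonempty mask on the grid")
        overlap = (
            self.seed_region.astype(int)
            + self.forward_target_region.astype(int)
            + self.reverse_source_region.astype(int)
        )
        if overlap.max() > 1:
            raise ValueError("seed/forward/reverse regions must be pairwise disjoint")
        for a in (*self.a_forward_by_group, *self.a_reverse_by_group):
            if abs(a) + abs(self.b_auto) >= 1:
                raise ValueError(
                    "nonstationary pair: need |a| + |b_auto| < 1 for every "
                    "planted coefficient"
                )


@dataclass
class GroundTruth:
    """Planted coefficients and the qualitative signatures they imply."""

    subject_ids: list[str]
    a_forward: np.ndarray  # per subject
    a_reverse: np.ndarray
    region_masks: dict[str, np.ndarray]
    expected_sign: dict[str, int]  # group1-minus-group2 difference per region
    expected_isi_corr_sign: int

    def to_jsonable(self) -> dict:
        return {
            "subject_ids": self.subject_ids,
            "a_forward": self.a_forward.tolist(),
            "a_reverse": self.a_reverse.tolist(),
            "region_masks": {
                k: np.argwhere(v).tolist() for k, v in self.region_masks.items()
            },
            "expected_sign": self.expected_sign,
            "expected_isi_corr_sign": self.expected_isi_corr_sign,
        }


@dataclass
class SyntheticDataset:
    subjects: list[BoldSeries]
    motion: list[np.ndarray]  # (T, 6) per subject, translations mm / rotations rad
    design: GroupDesign
    scales: pd.DataFrame  # subject_id, group, age, sex, education, ISI, PSQI, SAS, SDS
    truth: GroundTruth
    brain_mask: np.ndarray
    csf_mask: np.ndarray
    wm_mask: np.ndarray
    spec: SimulationSpec = field(repr=False, default=None)


def _ar1(rng, T, b, innov_sd):
    e = rng.normal(0.0, innov_sd, T)
    out = np.empty(T)
    out[0] = e[0] / np.sqrt(max(1 - b * b, 1e-12))
    for t in range(1, T):
        out[t] = b * out[t - 1] + e[t]
    return out


def _slow_drift(rng, T, tr_s, amplitude):
    """Sum of two sub-0.01 Hz cosines with random phase and amplitude."""
    t = np.arange(T) * tr_s
    out = np.zeros(T)
    for period in (220.0, 390.0):
        amp = amplitude * (0.5 + rng.random())
        out += amp * np.cos(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    return out


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate the full multi-subject dataset described by ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    nx, ny, nz = spec.grid_shape
    T = spec.n_timepoints
    b = spec.b_auto
    innov = spec.noise_sd * np.sqrt(1 - b * b)  # unit-ish latent variance

    brain_mask = np.ones(spec.grid_shape, dtype=bool)
    n1, n2 = spec.n_per_group
    n = n1 + n2
    groups = np.array([spec.group_names[0]] * n1 + [spec.group_names[1]] * n2)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    a_fwd = np.concatenate(
        [
            spec.a_forward_by_group[0] + rng.normal(0, spec.coef_jitter_sd, n1),
            spec.a_forward_by_group[1] + rng.normal(0, spec.coef_jitter_sd, n2),
        ]
    )
    a_rev = np.concatenate(
        [
            spec.a_reverse_by_group[0] + rng.normal(0, spec.coef_jitter_sd, n1),
            spec.a_reverse_by_group[1] + rng.normal(0, spec.coef_jitter_sd, n2),
        ]
    )
    # stationarity guard on the jittered values
    cap = 0.999 - abs(b)
    a_fwd = np.clip(a_fwd, -cap, cap)
    a_rev = np.clip(a_rev, -cap, cap)

    seed_idx = spec.seed_region
    fwd_idx = spec.forward_target_region
    rev_idx = spec.reverse_source_region
    n_fwd = int(fwd_idx.sum())

    affine = default_affine(spec.voxel_mm)
    subjects: list[BoldSeries] = []
    motion_tables: list[np.ndarray] = []
    for s in range(n):
        # latent reverse-source signal and seed signal driven by it
        r = _ar1(rng, T, b, innov)
        e_x = rng.normal(0.0, innov, T)
        x = np.empty(T)
        x[0] = e_x[0] / np.sqrt(max(1 - b * b, 1e-12))
        for t in range(1, T):
            x[t] = b * x[t - 1] + a_rev[s] * r[t - 1] + e_x[t]
        # forward-target voxels: independent innovations, shared coefficient
        e_y = rng.normal(0.0, spec.noise_sd, (T, n_fwd))
        y = np.empty((T, n_fwd))
        y[0] = e_y[0]
        for t in range(1, T):
            y[t] = a_fwd[s] * x[t - 1] + b * y[t - 1] + e_y[t]

        data = np.zeros((nx, ny, nz, T))
        data[seed_idx] += x
        data[rev_idx] += r
        data[fwd_idx] += y.T

        # spatially smooth background noise (planted signals stay exact)
        if spec.background_sd > 0:
            bg = rng.standard_normal((nx, ny, nz, T))
            if spec.smooth_fwhm_mm > 0:
                bg = smooth_gaussian(bg, spec.smooth_fwhm_mm, spec.voxel_mm)
                sd = bg.std()
                if sd > 0:
                    bg *= spec.background_sd / sd
            else:
                bg *= spec.background_sd
            data += bg

        # slow global / WM-like / CSF-like drifts
        data[brain_mask] += _slow_drift(rng, T, spec.tr_s, spec.drift_amplitude)
        data[spec.wm_region] += _slow_drift(rng, T, spec.tr_s, 1.5 * spec.drift_amplitude)
        data[spec.csf_region] += _slow_drift(rng, T, spec.tr_s, 1.5 * spec.drift_amplitude)

        # motion-like random walks, written to the table and leaked into the data
        steps = rng.normal(
            0.0,
            [spec.motion_step_mm] * 3 + [spec.motion_step_rad] * 3,
            (T, 6),
        )
        motion = np.cumsum(steps, axis=0)
        motion -= motion.mean(axis=0)
        weights = rng.normal(0.0, 0.05, (6, nx, ny, nz))
        data += np.einsum("tj,jxyz->xyzt", motion, weights)

        subjects.append(
            BoldSeries(
                data,
                spec.voxel_mm,
                spec.tr_s,
                brain_mask,
                affine=affine,
                subject_id=subject_ids[s],
            )
        )
        motion_tables.append(motion)

    age = np.round(np.clip(rng.normal(40, 9, n), 22, 59), 1)
    sex = (rng.random(n) < 0.4).astype(int)  # 1 = male
    education = np.round(np.clip(rng.normal(8, 3.2, n), 1, 19), 1)
    isi = spec.isi_intercept + spec.scale_coupling * a_fwd + rng.normal(
        0, spec.scale_noise_sd, n
    )
    psqi = 1.0 + 0.55 * isi + rng.normal(0, 1.0, n)
    sas = 30.0 + 1.1 * isi + rng.normal(0, 2.0, n)
    sds = 30.0 + 1.3 * isi + rng.normal(0, 2.0, n)

    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "education": education}
    )
    design = GroupDesign(subject_ids, groups, covariates)
    scales = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "age": age,
            "sex": np.where(sex == 1, "M", "F"),
            "education": education,
            "ISI": np.round(isi, 2),
            "PSQI": np.round(psqi, 2),
            "SAS": np.round(sas, 2),
            "SDS": np.round(sds, 2),
        }
    )

    def _sign(d: float) -> int:
        return int(np.sign(d))

    truth = GroundTruth(
        subject_ids=subject_ids,
        a_forward=a_fwd,
        a_reverse=a_rev,
        region_masks={
            "seed": seed_idx,
            "forward_target": fwd_idx,
            "reverse_source": rev_idx,
        },
        expected_sign={
            "forward_target": _sign(
                spec.a_forward_by_group[0] - spec.a_forward_by_group[1]
            ),
            "reverse_source": _sign(
                spec.a_reverse_by_group[0] - spec.a_reverse_by_group[1]
            ),
        },
        expected_isi_corr_sign=_sign(spec.scale_coupling),
    )
    return SyntheticDataset(
        subjects=subjects,
        motion=motion_tables,
        design=design,
        scales=scales,
        truth=truth,
        brain_mask=brain_mask,
        csf_mask=spec.csf_region,
        wm_mask=spec.wm_region,
        spec=spec,
    )


def simulate_null_maps(
    n_subjects: int,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    smooth_fwhm_mm: float = 6.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-subject smooth noise maps with no group structure.

    A light-weight null model for calibrating the group-inference stages:
    each subject map is spatially smoothed unit-variance Gaussian noise, the
    spatial covariance EC maps inherit from the smoothed background field.
    Returns an (n_subjects, *grid_shape) stack.
    """
    rng = np.random.default_rng(rng)
    maps = rng.standard_normal((n_subjects, *grid_shape))
    if smooth_fwhm_mm > 0:
        for i in range(n_subjects):
            maps[i] = smooth_gaussian(maps[i], smooth_fwhm_mm, voxel_mm)
        maps /= maps.std()
    return maps


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset in on-disk exchange form.

    Per-subject 4D NIfTI (.nii.gz) and 6-column whitespace-delimited motion
    text; masks as 3D NIfTI; subjects + scales as TSV; ground truth as JSON.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = ds.subjects[0].affine
    for series, motion in zip(ds.subjects, ds.motion):
        nib.save(
            nib.Nifti1Image(series.data.astype(np.float32), aff),
            outdir / f"{series.subject_id}_bold.nii.gz",
        )
        np.savetxt(outdir / f"{series.subject_id}_motion.txt", motion, fmt="%.6f")
    for name, mask in (
        ("brain_mask", ds.brain_mask),
        ("csf_mask", ds.csf_mask),
        ("wm_mask", ds.wm_mask),
        ("seed_mask", ds.truth.region_masks["seed"]),
    ):
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), aff), outdir / f"{name}.nii.gz"
        )
    ds.scales.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ds.truth.to_jsonable(), fh, indent=1)
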
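"""Core containers shared across the pipeline stages.

Everything is a plain dataclass over numpy arrays / pandas frames; NIfTI
serialization lives in :mod:`seedgc.io`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoldSeries",
    "NuisanceSet",
    "PreprocessParams",
    "GcaFit",
    "EcMap",
    "GroupDesign",
    "StatMap",
    "SmoothnessEstimate",
    "AlphaSimParams",
    "TfceParams",
    "default_affine",
]


def default_affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned voxel-to-world transform with the origin at voxel (0,0,0)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


@dataclass
class BoldSeries:
    """One subject's 4D BOLD data, indexed ``(i, j, k, t)``.

    Parameters
    ----------
    data : 4D float array
    voxel_mm : voxel edge lengths in mm
    tr_s : repetition time in seconds
    brain_mask : 3D boolean array matching the spatial shape
    affine : 4x4 voxel-to-world transform (defaults to a scaled identity)
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    tr_s: float
    brain_mask: np.ndarray
    affine: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BoldSeries.data must be 4D (i, j, k, t)")
        if self.data.shape[3] < 2:
            raise ValueError("BoldSeries needs at least 2 timepoints")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"brain_mask shape {self.brain_mask.shape} does not match "
                f"data spatial shape {self.data.shape[:3]}"
            )
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm entries must be positive")
        if self.affine is None:
            self.affine = default_affine(self.voxel_mm)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def masked_matrix(self) -> np.ndarray:
        """Return the in-mask data as a (T, V) matrix (C-order voxel flattening)."""
        return self.data[self.brain_mask].T


@dataclass
class NuisanceSet:
    """T x q matrix of nuisance regressors with column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("number of labels must equal number of columns")


@dataclass
class PreprocessParams:
    """Knobs of the volume-to-residual preprocessing chain."""

    n_discard: int = 10
    smooth_fwhm_mm: float = 6.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    motion_limit_mm: float = 1.5
    motion_limit_deg: float = 1.5

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if not 0 <= self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 <= band_low_hz < band_high_hz")
        if self.motion_limit_mm <= 0 or self.motion_limit_deg <= 0:
            raise ValueError("motion limits must be positive")


@dataclass
class GcaFit:
    """Bivariate lag-1 signed path coefficients for one (seed, voxel) pair.

    ``a_xy`` is the coefficient on the lagged seed series in the regression of
    the target (seed -> voxel); ``a_yx`` the converse. ``b_y`` / ``b_x`` are
    the autoregressive coefficients, ``c_y`` / ``c_x`` the coefficients on any
    exogenous columns.
    """

    a_xy: float
    a_yx: float
    b_y: float
    b_x: float
    c_y: np.ndarray
    c_x: np.ndarray
    resid_sd_y: float
    resid_sd_x: float
    n_lags: int = 1
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_lags != 1:
            raise ValueError("only first-order (n_lags = 1) fits are supported")
        if self.resid_sd_y < 0 or self.resid_sd_x < 0:
            raise ValueError("residual SDs must be nonnegative")


@dataclass
class EcMap:
    """Per-subject whole-brain signed-path-coefficient map for one direction."""

    data: np.ndarray  # 3D float
    direction: str  # "x2y" (seed -> voxel) or "y2x" (voxel -> seed)
    seed_label: str
    subject_id: str
    brain_mask: np.ndarray | None = None
    degenerate_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("x2y", "y2x"):
            raise ValueError("direction must be 'x2y' or 'y2x'")
        self.data = np.asarray(self.data, dtype=float)


@dataclass
class GroupDesign:
    """Two-group design with continuous/binary covariates.

    ``group_labels`` holds exactly two level names; the two-sample contrast is
    mean(level 0) - mean(level 1) adjusted for covariates.
    """

    subject_ids: list[str]
    groups: np.ndarray  # array of str labels, one per subject
    covariates: pd.DataFrame | None = None  # age, sex (0/1), education ...

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        if len(self.groups) != len(self.subject_ids):
            raise ValueError("groups and subject_ids length mismatch")
        if self.covariates is not None:
            if len(self.covariates) != len(self.subject_ids):
                raise ValueError("covariate rows must match subjects")
            if self.covariates.isna().any().any():
                raise ValueError("missing covariate values")

    @property
    def group_levels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def subset(self, idx: np.ndarray) -> "GroupDesign":
        cov = None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True)
        return GroupDesign(
            [self.subject_ids[i] for i in idx], self.groups[idx], cov
        )


@dataclass
class StatMap:
    """3D t-statistic image with its degrees of freedom."""

    t: np.ndarray
    df: int
    brain_mask: np.ndarray
    affine: np.ndarray
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.t.shape != self.brain_mask.shape:
            raise ValueError("t and brain_mask shapes differ")
        if self.df <= 0:
            raise ValueError("df must be positive")


@dataclass
class SmoothnessEstimate:
    """Per-axis spatial FWHM of a statistic image's noise, in mm."""

    fwhm_mm: np.ndarray  # length 3

    def __post_init__(self) -> None:
        self.fwhm_mm = np.asarray(self.fwhm_mm, dtype=float)
        if self.fwhm_mm.shape != (3,):
            raise ValueError("fwhm_mm must have 3 entries")
        if np.any(self.fwhm_mm <= 0):
            raise ValueError("FWHM estimates must be positive")

    @property
    def geometric_mean(self) -> float:
        return float(np.exp(np.mean(np.log(self.fwhm_mm))))


@dataclass
class AlphaSimParams:
    """Monte-Carlo cluster-extent simulation settings."""

    voxel_p: float = 0.001  # two-sided voxel-forming p
    cluster_p: float = 0.01
    n_iterations: int = 1000
    connectivity: int = 26
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_p < 1):
            raise ValueError("voxel_p and cluster_p must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class TfceParams:
    """Threshold-free cluster enhancement and permutation-test settings."""

    H: float = 2.0
    E: float = 0.5
    n_steps: int = 100
    n_permutations: int = 5000
    fwe_p: float = 0.05
    connectivity: int = 26
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.H <= 0 or self.E <= 0:
            raise ValueError("H and E must be positive")
        if self.n_steps < 10:
            raise ValueError("n_steps must be >= 10")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
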
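"""Peak-sphere ROI extraction, clinical correlations and group scalar tests.

ROIs are small spheres centered on cluster peaks ("6-mm-diameter" is read
literally: radius 3 mm, inclusive boundary — on a 3 mm grid that is the
center voxel plus its six face neighbors; the diameter is a parameter for
users who follow the radius-6-mm convention instead).  Per-subject
effective-connectivity values are the arithmetic mean over the ROI, and are
related to the sleep/emotion scales with plain Pearson correlation.  No
multiple-testing correction is applied across the ROI-scale pairs; the
p-values are reported raw, as is conventional for this design (a caveat
worth keeping in mind when many ROIs are screened).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import EcMap

__all__ = [
    "CorrelationResult",
    "ScalarTestResult",
    "sphere_mask",
    "roi_mean_values",
    "pearson_with_p",
    "two_sample_t",
    "chi_square_2x2",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


@dataclass
class ScalarTestResult:
    statistic: float
    p: float
    df: float
    kind: str  # "t" or "chi2"


def sphere_mask(
    center_voxel: tuple[int, int, int],
    diameter_mm: float,
    voxel_mm: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxels whose center-to-center world distance from ``center_voxel`` is
    at most ``diameter_mm / 2``, clipped to the grid."""
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    if not all(0 <= c < s for c, s in zip(center_voxel, grid_shape)):
        raise ValueError("center voxel outside grid")
    radius = diameter_mm / 2.0
    reach = [int(np.floor(radius / v)) for v in voxel_mm]
    mask = np.zeros(grid_shape, dtype=bool)
    ci, cj, ck = center_voxel
    for di in range(-reach[0], reach[0] + 1):
        for dj in range(-reach[1], reach[1] + 1):
            for dk in range(-reach[2], reach[2] + 1):
                d = np.sqrt(
                    (di * voxel_mm[0]) ** 2
                    + (dj * voxel_mm[1]) ** 2
                    + (dk * voxel_mm[2]) ** 2
                )
                if d <= radius + 1e-9:
                    i, j, k = ci + di, cj + dj, ck + dk
                    if 0 <= i < grid_shape[0] and 0 <= j < grid_shape[1] and 0 <= k < grid_shape[2]:
                        mask[i, j, k] = True
    return mask


def roi_mean_values(maps: list[EcMap] | np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Per-subject arithmetic mean over the ROI voxels, subject order kept."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if isinstance(maps, list):
        data = np.stack([m.data for m in maps])
        bm = maps[0].brain_mask
        if bm is not None and not np.any(roi & bm):
            raise ValueError("ROI lies entirely outside the brain mask")
    else:
        data = np.asarray(maps, dtype=float)
    return data[:, roi].mean(axis=1)


def pearson_with_p(
    x: np.ndarray, y: np.ndarray, x_label: str = "x", y_label: str = "y"
) -> CorrelationResult:
    """Sample Pearson r with the two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n, x_label, y_label)


def two_sample_t(x: np.ndarray, y: np.ndarray) -> ScalarTestResult:
    """Pooled-variance two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return ScalarTestResult(float(t), float(p), float(x.size + y.size - 2), "t")


def chi_square_2x2(table: np.ndarray) -> ScalarTestResult:
    """Pearson chi-square on a 2x2 count table, without continuity correction.

    The uncorrected statistic equals N (ad - bc)^2 / (row and column margins);
    the Yates-corrected variant would report a noticeably larger p on
    moderately sized tables.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ScalarTestResult(float(chi2), float(p), float(df), "chi2")
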
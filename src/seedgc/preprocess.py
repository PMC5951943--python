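"""Volume-to-residual preprocessing of resting-state BOLD series.

The chain reduces each subject's 4D series to nuisance-cleaned residuals:

1. discard the initial volumes acquired before magnetization equilibrium,
2. spatial Gaussian smoothing,
3. per-voxel linear detrend,
4. ideal frequency-domain band-pass (0.01-0.08 Hz by default),
5. regression of nine nuisance covariates (CSF, WM, global mean, six motion
   parameters).

Subjects whose motion trace exceeds the translation/rotation limit are only
flagged, never silently dropped; exclusion policy belongs to the caller.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import BoldSeries, NuisanceSet, PreprocessParams

__all__ = [
    "smooth_gaussian",
    "detrend_linear",
    "bandpass_filter",
    "regress_nuisance",
    "motion_exceeds_limit",
    "build_nuisance_set",
    "preprocess_pipeline",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(
    vol4d: np.ndarray, fwhm_mm: float, voxel_mm: tuple[float, float, float]
) -> np.ndarray:
    """Separable Gaussian smoothing, volume-wise per timepoint.

    sigma = fwhm / (2 sqrt(2 ln 2)) on each axis.  Boundary handling is
    zero-padding outside the volume with no renormalization; ``fwhm_mm = 0``
    is the identity.  Accepts 3D input as a single volume.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    vol4d = np.asarray(vol4d, dtype=float)
    if fwhm_mm == 0:
        return vol4d.copy()
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / v for v in voxel_mm]
    if vol4d.ndim == 3:
        return ndimage.gaussian_filter(vol4d, sigma_vox, mode="constant", cval=0.0)
    out = np.empty_like(vol4d)
    for t in range(vol4d.shape[3]):
        ndimage.gaussian_filter(
            vol4d[..., t], sigma_vox, output=out[..., t], mode="constant", cval=0.0
        )
    return out


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove intercept + linear trend from each column of a (T, V) matrix."""
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[0]
    x = np.arange(T, dtype=float)
    x = (x - x.mean()) / x.std() if T > 1 else x
    design = np.column_stack([np.ones(T), x])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def bandpass_filter(
    ts: np.ndarray, tr_s: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """Ideal frequency-domain band-pass of each column of a (T, V) matrix.

    Discrete-Fourier bins with frequency in [low_hz, high_hz] (inclusive) are
    retained, all others zeroed.  Applying the filter twice is a no-op.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[0]
    if T < 4:
        raise ValueError("need at least 4 timepoints to band-pass")
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist:.4f} Hz")
    freqs = np.fft.rfftfreq(T, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(ts, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def regress_nuisance(
    ts: np.ndarray,
    nuisance: NuisanceSet | np.ndarray,
    drop_collinear: bool = False,
) -> np.ndarray:
    """OLS-remove an intercept plus every nuisance column from each voxel series.

    Residuals are orthogonal to [1, Z].  A rank-deficient design raises with
    the colliding columns named; with ``drop_collinear=True`` the redundant
    columns are dropped instead (they are exactly explained by the retained
    ones, so the residuals are unchanged).
    """
    ts = np.asarray(ts, dtype=float)
    if isinstance(nuisance, NuisanceSet):
        Z, labels = nuisance.matrix, nuisance.labels
    else:
        Z = np.atleast_2d(np.asarray(nuisance, dtype=float))
        labels = [f"z{i}" for i in range(Z.shape[1])]
    if Z.shape[0] != ts.shape[0]:
        raise ValueError("nuisance rows must match timepoints")
    # zero-variance columns carry no signal to remove; drop them silently
    keep = Z.std(axis=0) > 1e-12
    Z = Z[:, keep]
    labels = [l for l, k in zip(labels, keep) if k]
    design = np.column_stack([np.ones(ts.shape[0]), Z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, ["intercept"] + list(labels))
        if not drop_collinear:
            raise ValueError(
                f"rank-deficient nuisance design; colliding columns: {bad}"
            )
        cols = [j for j, l in enumerate(labels) if l not in bad]
        design = np.column_stack([np.ones(ts.shape[0]), Z[:, cols]])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def _collinear_columns(design: np.ndarray, labels: list[str]) -> list[str]:
    """Columns lying in the span of their predecessors (greedy sweep)."""
    bad = []
    for j in range(1, design.shape[1]):
        prev = design[:, :j]
        col = design[:, j]
        beta, *_ = np.linalg.lstsq(prev, col, rcond=None)
        resid = col - prev @ beta
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(col)):
            bad.append(labels[j])
    return bad


def motion_exceeds_limit(
    motion: np.ndarray, limit_mm: float = 1.5, limit_deg: float = 1.5
) -> bool:
    """True iff any motion parameter's maximum |excursion| meets the limit.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians
    (realignment-parameter dialect); rotations are converted to degrees before
    the comparison.  The threshold is inclusive (>=).
    """
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    max_trans = np.max(np.abs(motion[:, :3]))
    max_rot_deg = np.max(np.abs(np.degrees(motion[:, 3:])))
    return bool(max_trans >= limit_mm or max_rot_deg >= limit_deg)


def build_nuisance_set(
    data4d: np.ndarray,
    brain_mask: np.ndarray,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    motion: np.ndarray,
) -> NuisanceSet:
    """Assemble the nine-column nuisance matrix (csf, wm, global, motion1..6).

    Tissue signals are the mean over each (user-supplied, already eroded)
    mask at every timepoint; all columns are mean-centered.
    """
    for name, m in (("csf", csf_mask), ("wm", wm_mask), ("global", brain_mask)):
        if not np.any(m):
            raise ValueError(f"{name} mask is empty")
        if m.shape != data4d.shape[:3]:
            raise ValueError(f"{name} mask shape does not match data")
    csf = data4d[np.asarray(csf_mask, bool)].mean(axis=0)
    wm = data4d[np.asarray(wm_mask, bool)].mean(axis=0)
    glob = data4d[np.asarray(brain_mask, bool)].mean(axis=0)
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[0] != data4d.shape[3]:
        raise ValueError("motion rows must match retained timepoints")
    Z = np.column_stack([csf, wm, glob, motion])
    Z = Z - Z.mean(axis=0)
    labels = ["csf", "wm", "global"] + [f"motion{i + 1}" for i in range(6)]
    return NuisanceSet(Z, labels)


def preprocess_pipeline(
    series: BoldSeries,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    motion: np.ndarray,
    params: PreprocessParams | None = None,
) -> tuple[BoldSeries, NuisanceSet, bool]:
    """Full chain: discard, smooth, detrend, band-pass, nuisance regression.

    ``motion`` must have one row per *original* timepoint; the first
    ``n_discard`` rows are dropped together with the volumes.  Returns the
    residual series (zero outside the brain mask), the nuisance set actually
    regressed, and the motion-exclusion flag.
    """
    params = params or PreprocessParams()
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[0] != series.n_timepoints:
        raise ValueError(
            f"motion table has {motion.shape[0]} rows for "
            f"{series.n_timepoints} timepoints"
        )
    if not np.any(series.brain_mask):
        raise ValueError("empty brain mask")
    nyquist = 1.0 / (2.0 * series.tr_s)
    if params.band_high_hz >= nyquist:
        raise ValueError("band_high_hz outside Nyquist range")

    excluded = motion_exceeds_limit(
        motion, params.motion_limit_mm, params.motion_limit_deg
    )

    data = series.data[..., params.n_discard :]
    motion_kept = motion[params.n_discard :]
    data = smooth_gaussian(data, params.smooth_fwhm_mm, series.voxel_mm)

    mask = series.brain_mask
    ts = data[mask].T  # (T, V)
    ts = detrend_linear(ts)
    ts = bandpass_filter(ts, series.tr_s, params.band_low_hz, params.band_high_hz)

    filtered = np.zeros_like(data)
    filtered[mask] = ts.T
    nuisance = build_nuisance_set(filtered, mask, csf_mask, wm_mask, motion_kept)
    resid = regress_nuisance(ts, nuisance, drop_collinear=True)

    out = np.zeros_like(data)
    out[mask] = resid.T
    cleaned = BoldSeries(
        out,
        series.voxel_mm,
        series.tr_s,
        mask,
        affine=series.affine,
        subject_id=series.subject_id,
    )
    return cleaned, nuisance, excluded
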
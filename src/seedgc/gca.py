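"""Bivariate first-order signed-path-coefficient Granger causality.

For a seed mean series X and a voxel series Y the two regressions

    Y_t = A1 X_{t-1} + B1 Y_{t-1} + C  Z_t + e_t
    X_t = A1' Y_{t-1} + B1' X_{t-1} + C' Z_t + e'_t

are fit by OLS (with intercept, on mean-centered series) over t = 2..T.
``a_xy = A1`` measures the directed influence of the seed on the voxel,
``a_yx = A1'`` the reverse; a positive coefficient is read as excitatory,
a negative one as inhibitory influence.  Series are mean-centered but not
variance-standardized, so the coefficients keep regression (signed-path)
scale.

Exogenous covariates ``z`` default to empty: in the standard pipeline the
nine nuisance covariates were already regressed out during preprocessing,
and regressing them a second time here would be redundant.  The ``C Z_t``
term is nonetheless implemented for callers who skip nuisance cleanup.
"""
from __future__ import annotations

import numpy as np

from .types import BoldSeries, EcMap, GcaFit

__all__ = ["extract_roi_mean", "fit_signed_path", "gca_maps"]

_ZERO_VAR_TOL = 1e-12


def extract_roi_mean(series: BoldSeries, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the mask voxels at each timepoint."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError("seed mask shape does not match series")
    if not np.any(mask):
        raise ValueError("empty seed mask")
    return series.data[mask].mean(axis=0)


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=0)


def fit_signed_path(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
) -> GcaFit:
    """Fit both lag-1 regressions between a seed series x and a target y.

    ``z``, if given, is a (T, q) matrix of exogenous covariates entering at
    time t (not lagged).  A zero-variance x or y yields a flagged
    zero-coefficient fit rather than an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    T = x.size
    if y.size != T:
        raise ValueError("x and y must have the same length")
    if T < 10:
        raise ValueError("need at least 10 timepoints")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input series")
    q = 0
    if z is not None:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] != T:
            raise ValueError("z must have T rows")
        q = z.shape[1]

    if x.std() < _ZERO_VAR_TOL or y.std() < _ZERO_VAR_TOL:
        zc = np.zeros(q)
        return GcaFit(0.0, 0.0, 0.0, 0.0, zc, zc.copy(), 0.0, 0.0, degenerate=True)

    xc, yc = _center(x), _center(y)
    zc = _center(z) if z is not None else None
    x0, y0 = xc[:-1], yc[:-1]
    x1, y1 = xc[1:], yc[1:]
    cols = [x0, y0]
    if zc is not None:
        cols.append(zc[1:])
    cols.append(np.ones(T - 1))
    D = np.column_stack(cols)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("collinear design in signed-path regression")
    beta_y, res_y, *_ = np.linalg.lstsq(D, y1, rcond=None)
    beta_x, res_x, *_ = np.linalg.lstsq(D, x1, rcond=None)
    dof = (T - 1) - D.shape[1]
    rss_y = float(res_y[0]) if res_y.size else float(np.sum((y1 - D @ beta_y) ** 2))
    rss_x = float(res_x[0]) if res_x.size else float(np.sum((x1 - D @ beta_x) ** 2))
    sd_y = np.sqrt(rss_y / dof) if dof > 0 else 0.0
    sd_x = np.sqrt(rss_x / dof) if dof > 0 else 0.0
    c_y = beta_y[2 : 2 + q].copy()
    c_x = beta_x[2 : 2 + q].copy()
    return GcaFit(
        a_xy=float(beta_y[0]),
        a_yx=float(beta_x[1]),
        b_y=float(beta_y[1]),
        b_x=float(beta_x[0]),
        c_y=c_y,
        c_x=c_x,
        resid_sd_y=float(sd_y),
        resid_sd_x=float(sd_x),
    )


def gca_maps(
    series: BoldSeries,
    seed_mask: np.ndarray,
    z: np.ndarray | None = None,
    seed_label: str = "seed",
) -> tuple[EcMap, EcMap]:
    """Signed path coefficients between the seed mean and every brain voxel.

    Returns the seed-to-voxel ("x2y") and voxel-to-seed ("y2x") maps.  Seed
    voxels are treated like any other voxel.  Zero-variance voxels get a zero
    coefficient and are flagged in ``degenerate_mask``.

    The per-voxel design of both regressions shares the predictor set
    {x_{t-1}, y_{t-1}, Z_t, 1}; the Gram matrix is assembled once per voxel
    in batched form and solved for the two responses simultaneously.
    """
    mask = np.asarray(series.brain_mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty brain mask")
    x = extract_roi_mean(series, seed_mask)
    Y = series.data[mask].T  # (T, V)
    T, V = Y.shape

    xc = _center(x)
    Yc = _center(Y)
    zc = _center(np.atleast_2d(np.asarray(z, dtype=float))) if z is not None else None

    if x.std() < _ZERO_VAR_TOL:
        shape = series.spatial_shape
        zero = np.zeros(shape)
        flagged = mask.copy()
        return (
            EcMap(zero, "x2y", seed_label, series.subject_id, mask, flagged),
            EcMap(zero.copy(), "y2x", seed_label, series.subject_id, mask, flagged),
        )

    x0, x1 = xc[:-1], xc[1:]
    Y0, Y1 = Yc[:-1], Yc[1:]
    n = T - 1

    # common predictor columns: [x0, Z_t, 1]
    common = [x0[:, None]]
    if zc is not None:
        common.append(zc[1:])
    common.append(np.ones((n, 1)))
    C = np.concatenate(common, axis=1)  # (n, k)
    k = C.shape[1]
    if np.linalg.matrix_rank(C) < k:
        raise ValueError("collinear common design (seed lag / exogenous columns)")

    CtC = C.T @ C  # (k, k)
    CtW = C.T @ Y0  # (k, V); W = per-voxel y-lag column
    WtW = np.einsum("tv,tv->v", Y0, Y0)  # (V,)

    # degenerate: zero-variance voxels, and voxels whose lag column is
    # numerically collinear with the common design (e.g. a voxel identical to
    # the seed mean) — these cannot carry a separate path coefficient
    proj = np.linalg.solve(CtC, CtW)
    resid_w = WtW - np.einsum("kv,kv->v", CtW, proj)
    degenerate = (Y0.std(axis=0) < _ZERO_VAR_TOL) | (
        resid_w <= 1e-10 * np.maximum(WtW, 1e-300)
    )

    G = np.empty((V, k + 1, k + 1))
    G[:, 0, 0] = WtW
    G[:, 0, 1:] = CtW.T
    G[:, 1:, 0] = CtW.T
    G[:, 1:, 1:] = CtC[None]
    # keep flagged voxels solvable; their coefficients are zeroed afterwards
    G[degenerate] = np.eye(k + 1)

    R = np.empty((V, k + 1, 2))
    R[:, 0, 0] = np.einsum("tv,tv->v", Y0, Y1)  # W' y1_v
    R[:, 1:, 0] = (C.T @ Y1).T
    R[:, 0, 1] = Y0.T @ x1  # W' x1
    R[:, 1:, 1] = (C.T @ x1)[None]
    beta = np.linalg.solve(G, R)  # (V, k+1, 2)

    a_xy = beta[:, 1, 0]  # coeff on x0 in y-regression
    a_yx = beta[:, 0, 1]  # coeff on y0 in x-regression
    if np.any(degenerate):
        a_xy = np.where(degenerate, 0.0, a_xy)
        a_yx = np.where(degenerate, 0.0, a_yx)

    shape = series.spatial_shape
    deg3d = np.zeros(shape, dtype=bool)
    deg3d[mask] = degenerate
    out = []
    for vals, direction in ((a_xy, "x2y"), (a_yx, "y2x")):
        m = np.zeros(shape)
        m[mask] = vals
        out.append(
            EcMap(
                m,
                direction,
                seed_label,
                series.subject_id,
                brain_mask=mask,
                degenerate_mask=deg3d,
            )
        )
    return out[0], out[1]
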
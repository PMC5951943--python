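"""Group-level inference on effective-connectivity maps.

Covers the voxel-wise GLM t-maps (one-sample and two-sample with
covariates), residual-based spatial smoothness estimation, Monte-Carlo
cluster-extent thresholds, suprathreshold clusterization, and permutation
TFCE with family-wise error control via the max-statistic null.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import (
    AlphaSimParams,
    EcMap,
    GroupDesign,
    SmoothnessEstimate,
    StatMap,
    TfceParams,
    default_affine,
)

__all__ = [
    "build_design_matrix",
    "glm_tmap",
    "estimate_smoothness",
    "alphasim_threshold",
    "cluster_table",
    "tfce_transform",
    "tfce_permutation_test",
    "TfcePermResult",
]

_CONN_STRUCTURE = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# ---------------------------------------------------------------------------
# GLM t-maps


def build_design_matrix(design: GroupDesign | None, n: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix, contrast and column names for the group model.

    ``design=None`` gives the intercept-only (one-sample) model.  For a
    two-group design the group column is an indicator of the first group
    level, so the contrast estimates mean(level0) - mean(level1) adjusted for
    the mean-centered covariates.
    """
    if design is None:
        return np.ones((n, 1)), np.array([1.0]), ["intercept"]
    levels = design.group_levels
    if len(levels) != 2:
        raise ValueError(f"two-sample design needs exactly 2 groups, got {levels}")
    g = (design.groups == levels[0]).astype(float)
    cols = [np.ones(n), g]
    names = ["intercept", f"group[{levels[0]}]"]
    if design.covariates is not None:
        for c in design.covariates.columns:
            v = design.covariates[c].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(str(c))
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return X, contrast, names


def glm_tmap(
    maps: np.ndarray | list[EcMap],
    design: GroupDesign | None,
    brain_mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> tuple[StatMap, np.ndarray]:
    """Voxel-wise OLS t-map plus the residual stack for smoothness estimation.

    ``maps`` is an (n, i, j, k) stack or a list of :class:`EcMap`.  With
    ``design=None`` this is the one-sample t-test of the mean against zero;
    otherwise the two-sample contrast with covariates.  Voxels whose
    residual variance is zero get t = 0.
    """
    if isinstance(maps, list):
        if brain_mask is None:
            brain_mask = maps[0].brain_mask
        data = np.stack([m.data for m in maps])
    else:
        data = np.asarray(maps, dtype=float)
    n = data.shape[0]
    shape = data.shape[1:]
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    if affine is None:
        affine = default_affine(voxel_mm)
    if n < 3:
        raise ValueError("need at least 3 subjects")

    X, contrast, names = build_design_matrix(design, n)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from .preprocess import _collinear_columns

        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient group design; colliding columns: {bad}")
    if n <= X.shape[1]:
        raise ValueError("fewer subjects than design parameters")

    Y = data.reshape(n, -1)[:, brain_mask.ravel()]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - rank
    sigma2 = np.sum(resid**2, axis=0) / df
    num = contrast @ beta
    se = np.sqrt(sigma2 * float(contrast @ XtX_inv @ contrast))
    # voxels whose residual variance is zero to machine precision get t = 0
    floor = 1e-12 * np.sqrt(np.mean(Y**2, axis=0) + 1e-300)
    ok = se > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, num / np.where(ok, se, 1.0), 0.0)

    t3d = np.zeros(shape)
    t3d[brain_mask] = t
    resid4d = np.zeros((n, *shape))
    resid4d[:, brain_mask] = resid
    stat = StatMap(t3d, df, brain_mask, affine, voxel_mm)
    return stat, resid4d


# ---------------------------------------------------------------------------
# Spatial smoothness


def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_mm: tuple[float, float, float],
) -> SmoothnessEstimate:
    """First-difference variance-ratio FWHM per axis, averaged across maps.

    The neighbor correlation along axis ``a`` is estimated as
    ``rho_hat = 1 - Var(Delta_a) / (4 Var)`` (the increment normalized by
    sqrt(2), as in the resting-state toolbox lineage) and mapped to FWHM by
    the Gaussian autocorrelation model ``FWHM = d * sqrt(-2 ln 2 / ln rho)``.
    Under this convention unsmoothed iid noise has an intrinsic smoothness of
    sqrt(2) voxels (~1.41); smoothing can only increase the estimate.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 3:
        residuals = residuals[None]
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    # variance-standardize per voxel across maps: the cluster-forming statistic
    # is studentized voxel-wise, so the relevant autocorrelation is that of the
    # unit-variance residual field, not of the raw residuals (whose variance
    # can vary strongly across voxels and corrupt the difference-variance ratio)
    vox_sd = residuals.std(axis=0)
    if np.all(vox_sd[mask] < 1e-15):
        raise ValueError("constant residual maps: smoothness undefined")
    residuals = residuals / np.where(vox_sd > 1e-15, vox_sd, 1.0)
    fwhms = np.zeros((residuals.shape[0], 3))
    for i, r in enumerate(residuals):
        var = r[mask].var()
        if var < 1e-30:
            raise ValueError("constant residual map: smoothness undefined")
        for ax in range(3):
            pair = mask & np.roll(mask, -1, axis=ax)
            # drop wrap-around faces
            sl = [slice(None)] * 3
            sl[ax] = slice(-1, None)
            pair[tuple(sl)] = False
            d = (np.roll(r, -1, axis=ax) - r)[pair]
            if d.size < 2:
                raise ValueError("mask too thin to difference along an axis")
            rho = 1.0 - np.mean(d**2) / (4.0 * var)
            rho = float(np.clip(rho, 1e-4, 1 - 1e-9))
            fwhms[i, ax] = voxel_mm[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(rho))
    return SmoothnessEstimate(fwhms.mean(axis=0))


def _kernel_sigma_vox(
    fwhm_mm: np.ndarray | float, voxel_mm: tuple[float, float, float]
) -> list[float]:
    """Invert the smoothness estimator: Gaussian-kernel sigma (in voxels)
    that reproduces a requested estimated FWHM.  FWHM at or below the
    intrinsic sqrt(2)-voxel floor maps to no smoothing."""
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    sigmas = []
    for f, d in zip(fwhm, voxel_mm):
        if f <= 0:
            sigmas.append(0.0)
            continue
        rho_hat = np.exp(-2.0 * np.log(2.0) * d * d / (f * f))
        rho = 2.0 * rho_hat - 1.0
        if rho <= 0:
            sigmas.append(0.0)
        else:
            sigmas.append(float(np.sqrt(-d * d / (4.0 * np.log(rho))) / d))
    return sigmas


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent threshold (AlphaSim)


def _max_cluster_size(field: np.ndarray, zthr: float, structure: np.ndarray) -> int:
    mx = 0
    for sgn in (1.0, -1.0):
        lab, nlab = ndimage.label(sgn * field >= zthr, structure=structure)
        if nlab:
            mx = max(mx, int(np.bincount(lab.ravel())[1:].max()))
    return mx


def alphasim_threshold(
    mask: np.ndarray,
    smoothness: SmoothnessEstimate | float,
    params: AlphaSimParams,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    return_distribution: bool = False,
):
    """Minimum cluster extent controlling the cluster-level alpha.

    Each iteration draws white noise on the mask's grid, smooths it so the
    smoothness estimator would report the requested FWHM, standardizes it
    in-mask, thresholds at the two-sided ``voxel_p`` Gaussian quantile, and
    records the largest suprathreshold cluster (positive and negative parts
    clustered separately).  The returned extent is the smallest k with
    ``(1 + #{max >= k}) / (1 + n_iterations) <= cluster_p``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    floor = 1.0 / (1.0 + params.n_iterations)
    if params.cluster_p < floor:
        raise ValueError(
            f"cluster_p {params.cluster_p} unattainable with "
            f"{params.n_iterations} iterations; attainable floor is {floor:.5f}"
        )
    fwhm = (
        smoothness.fwhm_mm
        if isinstance(smoothness, SmoothnessEstimate)
        else float(smoothness)
    )
    sigma = _kernel_sigma_vox(fwhm, voxel_mm)
    do_smooth = any(s > 0 for s in sigma)
    zthr = stats.norm.ppf(1.0 - params.voxel_p / 2.0)
    structure = _CONN_STRUCTURE[params.connectivity]
    rng = np.random.default_rng(params.rng_seed)
    max_sizes = np.zeros(params.n_iterations, dtype=int)
    for i in range(params.n_iterations):
        field = rng.standard_normal(mask.shape)
        if do_smooth:
            field = ndimage.gaussian_filter(field, sigma, mode="constant", cval=0.0)
        inm = field[mask]
        field = (field - inm.mean()) / inm.std()
        field[~mask] = 0.0
        max_sizes[i] = _max_cluster_size(field, zthr, structure)
    for k in range(1, int(max_sizes.max()) + 2):
        p = (1.0 + np.sum(max_sizes >= k)) / (1.0 + params.n_iterations)
        if p <= params.cluster_p:
            if return_distribution:
                return k, max_sizes
            return k
    raise RuntimeError("unreachable: extent search exhausted")  # pragma: no cover


# ---------------------------------------------------------------------------
# Clusterization


def cluster_table(
    stat: StatMap,
    voxel_p: float = 0.001,
    min_extent: int = 1,
    connectivity: int = 26,
    return_members: bool = False,
):
    """Suprathreshold clusters of a two-sided thresholded t-map.

    Voxels with ``|t| >= t_{1-voxel_p/2, df}`` are labeled; positive and
    negative voxels are clustered separately; components smaller than
    ``min_extent`` are dropped.  The peak is the member voxel with the
    largest |t| (ties broken by smallest C-order linear index).  With
    ``return_members=True`` also returns the boolean member mask of each
    cluster, row-aligned with the table.
    """
    thr = stats.t.ppf(1.0 - voxel_p / 2.0, stat.df)
    structure = _CONN_STRUCTURE[connectivity]
    rows = []
    member_masks = []
    t = np.where(stat.brain_mask, stat.t, 0.0)
    for sgn in (1, -1):
        lab, nlab = ndimage.label(sgn * t >= thr, structure=structure)
        for li in range(1, nlab + 1):
            members = lab == li
            size = int(members.sum())
            if size < min_extent:
                continue
            tv = np.where(members, np.abs(t), -np.inf)
            flat_peak = int(np.argmax(tv))
            pi, pj, pk = np.unravel_index(flat_peak, t.shape)
            mm = stat.affine @ np.array([pi, pj, pk, 1.0])
            rows.append(
                {
                    "size_voxels": size,
                    "sign": sgn,
                    "peak_i": pi,
                    "peak_j": pj,
                    "peak_k": pk,
                    "peak_x_mm": mm[0],
                    "peak_y_mm": mm[1],
                    "peak_z_mm": mm[2],
                    "peak_t": float(t[pi, pj, pk]),
                    "_members": members,
                }
            )
    rows.sort(key=lambda r: -r["size_voxels"])
    member_masks = [r.pop("_members") for r in rows]
    df = pd.DataFrame(
        rows,
        columns=[
            "label",
            "size_voxels",
            "sign",
            "peak_i",
            "peak_j",
            "peak_k",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            "peak_t",
        ],
    )
    df["label"] = [f"cluster_{i + 1}" for i in range(len(df))]
    if return_members:
        return df, member_masks
    return df


# ---------------------------------------------------------------------------
# TFCE


def tfce_transform(
    map3d: np.ndarray, mask: np.ndarray, params: TfceParams | None = None
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    TFCE(v) = sum_h extent(v, h)^E * h^H * dh over heights 0 < h <= map(v),
    with extent(v, h) the size of v's connected suprathreshold component at
    height h.  Positive and negative parts are enhanced separately (negatives
    negated, transformed, re-negated).  dh = max|map| / n_steps with heights
    at step midpoints.
    """
    params = params or TfceParams()
    if params.n_steps <= 0:
        raise ValueError("n_steps must be positive")
    mask = np.asarray(mask, dtype=bool)
    m = np.where(mask, np.asarray(map3d, dtype=float), 0.0)
    vmax = np.abs(m).max()
    out = np.zeros_like(m)
    if vmax == 0:
        return out
    dh = vmax / params.n_steps
    structure = _CONN_STRUCTURE[params.connectivity]
    lab = np.empty(m.shape, dtype=np.int32)
    for sgn in (1.0, -1.0):
        part = sgn * m
        pmax = part.max()
        if pmax <= 0:
            continue
        for s in range(params.n_steps):
            h = (s + 0.5) * dh
            if h > pmax:
                break
            sup = part >= h
            nlab = ndimage.label(sup, structure=structure, output=lab)
            if not nlab:
                break
            sizes = np.bincount(lab[sup])
            out[sup] += sgn * (sizes[lab[sup]] ** params.E) * (h**params.H) * dh
    return out


@dataclass
class TfcePermResult:
    """Outcome of the max-statistic TFCE permutation test."""

    p: np.ndarray  # 3D FWE-corrected p-values (1 outside the mask)
    observed_tfce: np.ndarray
    observed_t: StatMap
    null_max: np.ndarray
    n_permutations: int
    exhaustive: bool


def _tmap_flat(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Vectorized OLS contrast t over the columns of Y (n, V)."""
    n = Y.shape[0]
    XtX_inv = np.linalg.inv(X.T @ X)
    P = XtX_inv @ X.T
    beta = P @ Y
    resid = Y - X @ beta
    df = n - X.shape[1]
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    se = np.sqrt(sigma2 * float(contrast @ XtX_inv @ contrast))
    floor = 1e-12 * np.sqrt(np.mean(Y**2, axis=0) + 1e-300)
    ok = se > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, (contrast @ beta) / np.where(ok, se, 1.0), 0.0)


def tfce_permutation_test(
    maps: np.ndarray | list[EcMap],
    design: GroupDesign | None,
    params: TfceParams,
    brain_mask: np.ndarray | None = None,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    affine: np.ndarray | None = None,
) -> TfcePermResult:
    """Voxel-wise FWE-corrected p-map from the max-|TFCE| permutation null.

    Two-sample designs permute the group labels; one-sample designs flip
    per-subject signs.  The corrected p at voxel v is
    ``(1 + #{perm max >= observed(v)}) / (1 + n_permutations)``; ties count
    against rejection.  When fewer distinct relabelings exist than requested
    permutations the test enumerates them all and reports ``exhaustive``.
    """
    if isinstance(maps, list):
        if brain_mask is None:
            brain_mask = maps[0].brain_mask
        data = np.stack([m.data for m in maps])
    else:
        data = np.asarray(maps, dtype=float)
    n = data.shape[0]
    shape = data.shape[1:]
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    if affine is None:
        affine = default_affine(voxel_mm)
    X, contrast, _ = build_design_matrix(design, n)
    Y = data.reshape(n, -1)[:, brain_mask.ravel()]
    df = n - np.linalg.matrix_rank(X)

    def t_stat_3d(Xp: np.ndarray, Yp: np.ndarray) -> np.ndarray:
        t3 = np.zeros(shape)
        t3[brain_mask] = _tmap_flat(Yp, Xp, contrast)
        return t3

    obs_t3 = t_stat_3d(X, Y)
    obs_tfce = tfce_transform(obs_t3, brain_mask, params)

    rng = np.random.default_rng(params.rng_seed)
    exhaustive = False
    if design is None:
        n_distinct = 2**n
        if params.n_permutations >= n_distinct:
            exhaustive = True
            flips = [
                np.array([1.0 if (i >> b) & 1 else -1.0 for b in range(n)])
                for i in range(n_distinct)
            ]
        else:
            flips = [
                rng.choice([-1.0, 1.0], size=n) for _ in range(params.n_permutations)
            ]
        perms = [("flip", f) for f in flips]
    else:
        levels = design.group_levels
        n1 = int(np.sum(design.groups == levels[0]))
        n_distinct = comb(n, n1)
        if params.n_permutations >= n_distinct:
            exhaustive = True
            assignments = combinations(range(n), n1)
            gcols = []
            for idx in assignments:
                g = np.zeros(n)
                g[list(idx)] = 1.0
                gcols.append(g)
        else:
            gcols = [rng.permutation(X[:, 1]) for _ in range(params.n_permutations)]
        perms = [("relabel", g) for g in gcols]

    null_max = np.empty(len(perms))
    for i, (kind, p) in enumerate(perms):
        if kind == "flip":
            tp = t_stat_3d(X, p[:, None] * Y)
        else:
            Xp = X.copy()
            Xp[:, 1] = p
            tp = t_stat_3d(Xp, Y)
        null_max[i] = np.abs(tfce_transform(tp, brain_mask, params)).max()

    obs_abs = np.abs(obs_tfce)
    if exhaustive:
        # the observed labeling is one of the enumerated relabelings
        counts = (null_max[None, :] >= obs_abs[brain_mask][:, None]).sum(axis=1)
        pvals = counts / len(perms)
    else:
        counts = (null_max[None, :] >= obs_abs[brain_mask][:, None]).sum(axis=1)
        pvals = (1.0 + counts) / (1.0 + len(perms))
    p3 = np.ones(shape)
    p3[brain_mask] = pvals
    stat = StatMap(obs_t3, max(df, 1), brain_mask, affine, voxel_mm)
    return TfcePermResult(
        p=p3,
        observed_tfce=obs_tfce,
        observed_t=stat,
        null_max=null_max,
        n_permutations=len(perms),
        exhaustive=exhaustive,
    )
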
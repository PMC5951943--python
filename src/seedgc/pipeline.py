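"""End-to-end orchestration: simulate/load -> preprocess -> GCA -> group stats
-> ROI correlations, from a single config with one global seed.

The global seed deterministically derives per-stage seeds (simulation,
cluster-extent Monte Carlo, permutation test), so one knob reproduces a full
run bit-for-bit.  Outputs are written to a fresh directory; re-running into a
non-empty directory is refused unless ``force`` is set.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gca, io, mapstats, preprocess, roistats, synth
from .types import (
    AlphaSimParams,
    BoldSeries,
    EcMap,
    GroupDesign,
    PreprocessParams,
    TfceParams,
)

__all__ = ["Config", "DirectionReport", "ReportBundle", "run_full_analysis"]

log = logging.getLogger("seedgc")

_SCALE_COLS = ["ISI", "PSQI", "SAS", "SDS"]


@dataclass
class Config:
    """Everything one analysis run needs.

    Exactly one input source must be given: a :class:`SimulationSpec` or a
    ``data_dir`` holding the on-disk layout of :func:`seedgc.synth.write_dataset`.
    """

    simulation: synth.SimulationSpec | None = None
    data_dir: str | None = None
    tr_s: float = 2.5
    seed_masks: dict[str, str] | None = None  # label -> NIfTI path; default: shipped seed mask
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    alphasim: AlphaSimParams = field(default_factory=AlphaSimParams)
    tfce: TfceParams = field(default_factory=TfceParams)
    correction_mode: str = "alphasim"  # "alphasim" | "tfce" | "both"
    one_sample_voxel_p: float = 0.001
    one_sample_min_extent: int = 50
    two_sample_voxel_p: float = 0.001
    roi_diameter_mm: float = 6.0
    correlate_group: str | None = None  # default: first group level (patients)
    out_dir: str | None = None
    rng_seed: int = 0
    force: bool = False
    save_intermediates: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.data_dir is None):
            raise ValueError(
                "exactly one input source required: simulation spec OR data_dir"
            )
        if self.correction_mode not in ("alphasim", "tfce", "both"):
            raise ValueError("correction_mode must be alphasim, tfce or both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            sim = dict(kwargs["simulation"])
            for key in ("grid_shape", "voxel_mm", "n_per_group", "group_names",
                        "a_forward_by_group", "a_reverse_by_group"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulation"] = synth.SimulationSpec(**sim)
        for key, klass in (
            ("preprocess", PreprocessParams),
            ("alphasim", AlphaSimParams),
            ("tfce", TfceParams),
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


@dataclass
class DirectionReport:
    seed_label: str
    direction: str
    one_sample_clusters: pd.DataFrame
    two_sample_clusters: pd.DataFrame | None
    smoothness_fwhm_mm: list[float]
    alphasim_extent: int | None
    tfce_n_significant: int | None
    tfce_clusters: pd.DataFrame | None
    roi_table: pd.DataFrame
    roi_correlations: pd.DataFrame
    # boolean member masks, row-aligned with two_sample_clusters (not serialized)
    two_sample_cluster_masks: list[np.ndarray] | None = None


@dataclass
class ReportBundle:
    directions: list[DirectionReport]
    demographics: pd.DataFrame
    excluded_subjects: list[dict]
    n_analyzed: int
    rng_seed: int

    def to_jsonable(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "n_analyzed": self.n_analyzed,
            "excluded_subjects": self.excluded_subjects,
            "demographics": self.demographics.to_dict(orient="records"),
            "directions": [
                {
                    "seed": d.seed_label,
                    "direction": d.direction,
                    "smoothness_fwhm_mm": d.smoothness_fwhm_mm,
                    "alphasim_extent": d.alphasim_extent,
                    "tfce_n_significant": d.tfce_n_significant,
                    "one_sample_clusters": d.one_sample_clusters.to_dict(orient="records"),
                    "two_sample_clusters": (
                        None
                        if d.two_sample_clusters is None
                        else d.two_sample_clusters.to_dict(orient="records")
                    ),
                    "roi_correlations": d.roi_correlations.to_dict(orient="records"),
                }
                for d in self.directions
            ],
        }


def _derive_seeds(global_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(global_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _validate_paths(config: Config) -> None:
    problems = []
    if config.data_dir is not None:
        d = Path(config.data_dir)
        if not d.is_dir():
            problems.append(f"data_dir does not exist: {d}")
        elif not (d / "subjects.tsv").exists():
            problems.append(f"missing subjects table: {d / 'subjects.tsv'}")
    if config.seed_masks:
        for label, p in config.seed_masks.items():
            if isinstance(p, (str, Path)) and not Path(p).exists():
                problems.append(f"seed mask '{label}' not found: {p}")
    if problems:
        raise FileNotFoundError(
            "configuration validation failed:\n  - " + "\n  - ".join(problems)
        )


def _prepare_outdir(config: Config) -> Path | None:
    if config.out_dir is None:
        return None
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_full_analysis(config: Config) -> ReportBundle:
    """Execute every stage for every seed mask and both directions."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    _validate_paths(config)
    out = _prepare_outdir(config)
    sim_seed, alphasim_seed, tfce_seed = _derive_seeds(config.rng_seed, 3)

    # ------------------------------------------------------------------ input
    if config.simulation is not None:
        spec = dataclasses.replace(config.simulation, rng_seed=sim_seed)
        log.info("simulating dataset: grid=%s subjects=%s", spec.grid_shape, spec.n_per_group)
        ds = synth.simulate_dataset(spec)
        subjects, motion, table = ds.subjects, ds.motion, ds.scales
        masks = {
            "brain_mask": ds.brain_mask,
            "csf_mask": ds.csf_mask,
            "wm_mask": ds.wm_mask,
            "seed_mask": ds.truth.region_masks["seed"],
        }
        if out is not None and config.save_intermediates:
            synth.write_dataset(ds, out / "dataset")
    else:
        subjects, motion, table, masks = io.load_dataset_dir(config.data_dir, config.tr_s)

    seed_masks: dict[str, np.ndarray] = {}
    if config.seed_masks:
        for label, p in config.seed_masks.items():
            seed_masks[label] = io.load_mask(p) if isinstance(p, (str, Path)) else np.asarray(p, bool)
    else:
        seed_masks["seed"] = masks["seed_mask"]

    # ------------------------------------------------------------- preprocess
    cleaned: list[BoldSeries] = []
    kept_idx: list[int] = []
    excluded: list[dict] = []
    for i, (series, mot) in enumerate(zip(subjects, motion)):
        resid, _, flag = preprocess.preprocess_pipeline(
            series, masks["csf_mask"], masks["wm_mask"], mot, config.preprocess
        )
        if flag:
            excluded.append(
                {
                    "subject_id": series.subject_id,
                    "reason": (
                        f"head motion >= {config.preprocess.motion_limit_mm} mm "
                        f"or {config.preprocess.motion_limit_deg} deg"
                    ),
                }
            )
            continue
        cleaned.append(resid)
        kept_idx.append(i)
    log.info("preprocessed %d subjects, excluded %d", len(cleaned), len(excluded))

    table = table.iloc[kept_idx].reset_index(drop=True)
    groups = table["group"].to_numpy()
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2 or min((groups == lv).sum() for lv in levels) < 3:
        raise ValueError("need two groups with at least 3 subjects each after exclusions")
    covariates = pd.DataFrame(
        {
            "age": table["age"].to_numpy(float),
            "sex": (table["sex"].astype(str) == "M").astype(float)
            if table["sex"].dtype == object
            else table["sex"].to_numpy(float),
            "education": table["education"].to_numpy(float),
        }
    )
    design = GroupDesign(list(table["subject_id"]), groups, covariates)
    corr_group = config.correlate_group or levels[0]

    voxel_mm = cleaned[0].voxel_mm
    affine = cleaned[0].affine
    brain_mask = cleaned[0].brain_mask

    # ------------------------------------------------------------ per seed/dir
    reports: list[DirectionReport] = []
    for label, smask in seed_masks.items():
        log.info("computing EC maps for seed '%s'", label)
        per_subject = [gca.gca_maps(s, smask, seed_label=label) for s in cleaned]
        for di, direction in enumerate(("x2y", "y2x")):
            ecmaps: list[EcMap] = [pair[di] for pair in per_subject]
            stack = np.stack([m.data for m in ecmaps])

            one_stat, _ = mapstats.glm_tmap(
                stack, None, brain_mask, affine, voxel_mm
            )
            one_clusters = mapstats.cluster_table(
                one_stat,
                config.one_sample_voxel_p,
                config.one_sample_min_extent,
                config.alphasim.connectivity,
            )

            two_stat, resid = mapstats.glm_tmap(
                stack, design, brain_mask, affine, voxel_mm
            )
            smoothness = mapstats.estimate_smoothness(resid, brain_mask, voxel_mm)

            two_clusters = None
            cluster_masks = None
            extent = None
            if config.correction_mode in ("alphasim", "both"):
                asim = dataclasses.replace(config.alphasim, rng_seed=alphasim_seed)
                extent = mapstats.alphasim_threshold(
                    brain_mask, smoothness, asim, voxel_mm
                )
                two_clusters, cluster_masks = mapstats.cluster_table(
                    two_stat,
                    config.two_sample_voxel_p,
                    extent,
                    config.alphasim.connectivity,
                    return_members=True,
                )

            tfce_n_sig = None
            tfce_clusters = None
            if config.correction_mode in ("tfce", "both"):
                tparams = dataclasses.replace(config.tfce, rng_seed=tfce_seed)
                perm = mapstats.tfce_permutation_test(
                    stack, design, tparams, brain_mask, voxel_mm, affine
                )
                sig = perm.p <= tparams.fwe_p
                tfce_n_sig = int(sig.sum())
                tfce_clusters = _clusters_from_mask(
                    sig, two_stat, config.alphasim.connectivity, affine
                )

            cluster_source = (
                two_clusters if two_clusters is not None else tfce_clusters
            )
            roi_rows, corr_rows = _roi_stage(
                cluster_source, stack, table, corr_group,
                config.roi_diameter_mm, voxel_mm, brain_mask.shape,
            )
            reports.append(
                DirectionReport(
                    seed_label=label,
                    direction=direction,
                    one_sample_clusters=one_clusters,
                    two_sample_clusters=two_clusters,
                    smoothness_fwhm_mm=[float(f) for f in smoothness.fwhm_mm],
                    alphasim_extent=extent,
                    tfce_n_significant=tfce_n_sig,
                    tfce_clusters=tfce_clusters,
                    roi_table=roi_rows,
                    roi_correlations=corr_rows,
                    two_sample_cluster_masks=cluster_masks,
                )
            )
            if out is not None:
                prefix = out / f"{label}_{direction}"
                io.save_statmap(two_stat, f"{prefix}_two_sample_t.nii.gz")
                io.save_statmap(one_stat, f"{prefix}_one_sample_t.nii.gz")
                if two_clusters is not None:
                    two_clusters.to_csv(f"{prefix}_clusters.tsv", sep="\t", index=False)
                if config.save_intermediates:
                    for m in ecmaps:
                        io.save_ecmap(
                            m, affine, out / "ecmaps" / f"{m.subject_id}_{label}_{direction}.nii.gz"
                        )

    demographics = _demographics_table(table, levels)
    bundle = ReportBundle(
        directions=reports,
        demographics=demographics,
        excluded_subjects=excluded,
        n_analyzed=len(cleaned),
        rng_seed=config.rng_seed,
    )
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(bundle.to_jsonable(), fh, indent=1)
        demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
    return bundle


def _clusters_from_mask(sig, stat, connectivity, affine) -> pd.DataFrame:
    """Cluster table of significant-voxel components (TFCE route)."""
    from scipy import ndimage

    structure = mapstats._CONN_STRUCTURE[connectivity]
    rows = []
    t = stat.t
    lab, nlab = ndimage.label(sig, structure=structure)
    for li in range(1, nlab + 1):
        members = lab == li
        tv = np.where(members, np.abs(t), -np.inf)
        flat_peak = int(np.argmax(tv))
        pi, pj, pk = np.unravel_index(flat_peak, t.shape)
        mm = affine @ np.array([pi, pj, pk, 1.0])
        rows.append(
            {
                "label": f"cluster_{li}",
                "size_voxels": int(members.sum()),
                "sign": int(np.sign(t[pi, pj, pk])) or 1,
                "peak_i": pi,
                "peak_j": pj,
                "peak_k": pk,
                "peak_x_mm": mm[0],
                "peak_y_mm": mm[1],
                "peak_z_mm": mm[2],
                "peak_t": float(t[pi, pj, pk]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "size_voxels", "sign", "peak_i", "peak_j", "peak_k",
                 "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t"],
    )


def _roi_stage(
    clusters: pd.DataFrame | None,
    stack: np.ndarray,
    table: pd.DataFrame,
    corr_group: str,
    diameter_mm: float,
    voxel_mm,
    grid_shape,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    roi_rows, corr_rows = [], []
    in_group = (table["group"] == corr_group).to_numpy()
    if clusters is not None:
        for _, cl in clusters.iterrows():
            center = (int(cl["peak_i"]), int(cl["peak_j"]), int(cl["peak_k"]))
            roi = roistats.sphere_mask(center, diameter_mm, voxel_mm, grid_shape)
            values = roistats.roi_mean_values(stack, roi)
            roi_rows.append(
                {
                    "cluster": cl["label"],
                    "n_voxels": int(roi.sum()),
                    "center_i": center[0],
                    "center_j": center[1],
                    "center_k": center[2],
                    **{
                        f"mean_ec_{g}": float(values[(table["group"] == g).to_numpy()].mean())
                        for g in dict.fromkeys(table["group"])
                    },
                }
            )
            for scale in _SCALE_COLS:
                if scale not in table.columns:
                    continue
                res = roistats.pearson_with_p(
                    values[in_group],
                    table.loc[in_group, scale].to_numpy(float),
                    x_label=f"EC[{cl['label']}]",
                    y_label=scale,
                )
                corr_rows.append(
                    {
                        "cluster": cl["label"],
                        "scale": scale,
                        "group": corr_group,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    return (
        pd.DataFrame(roi_rows),
        pd.DataFrame(corr_rows, columns=["cluster", "scale", "group", "r", "p", "n"]),
    )


def _demographics_table(table: pd.DataFrame, levels: list[str]) -> pd.DataFrame:
    g1 = table[table["group"] == levels[0]]
    g2 = table[table["group"] == levels[1]]
    rows = []
    sex_counts = np.array(
        [
            [(g1["sex"].astype(str) == "M").sum(), (g1["sex"].astype(str) != "M").sum()],
            [(g2["sex"].astype(str) == "M").sum(), (g2["sex"].astype(str) != "M").sum()],
        ]
    )
    try:
        chi = roistats.chi_square_2x2(sex_counts)
        rows.append(
            {"variable": "sex", "test": "chi2", "statistic": chi.statistic, "p": chi.p}
        )
    except ValueError:
        rows.append({"variable": "sex", "test": "chi2", "statistic": np.nan, "p": np.nan})
    for col in ("age", "education", *_SCALE_COLS):
        if col not in table.columns:
            continue
        res = roistats.two_sample_t(g1[col].to_numpy(float), g2[col].to_numpy(float))
        rows.append(
            {"variable": col, "test": "t", "statistic": res.statistic, "p": res.p}
        )
    return pd.DataFrame(rows)
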
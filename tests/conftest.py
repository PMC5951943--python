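import numpy as np
import pytest

from seedgc import gca, preprocess, synth
from seedgc.types import BoldSeries


def light_preprocess(series: BoldSeries, ds: synth.SyntheticDataset, motion) -> BoldSeries:
    """Discard + detrend + nuisance regression only (no smoothing, no band-pass).

    Used for coefficient-recovery checks, where temporal filtering would bias
    the lag-1 estimates away from the generating values.
    """
    data = series.data[..., 10:]
    mask = series.brain_mask
    ts = preprocess.detrend_linear(data[mask].T)
    nz = preprocess.build_nuisance_set(data, mask, ds.csf_mask, ds.wm_mask, motion[10:])
    ts = preprocess.regress_nuisance(ts, nz)
    out = np.zeros_like(data)
    out[mask] = ts.T
    return BoldSeries(
        out, series.voxel_mm, series.tr_s, mask,
        affine=series.affine, subject_id=series.subject_id,
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    """Default-spec dataset plus lightly preprocessed EC map pairs per subject."""
    ds = synth.simulate_dataset(synth.SimulationSpec(rng_seed=11))
    pairs = []
    for series, motion in zip(ds.subjects, ds.motion):
        cleaned = light_preprocess(series, ds, motion)
        pairs.append(gca.gca_maps(cleaned, ds.truth.region_masks["seed"]))
    return ds, pairs


def tiny_spec(**kw) -> synth.SimulationSpec:
    """Small, fast simulation spec for structural tests."""
    defaults = dict(
        grid_shape=(14, 14, 14),
        n_timepoints=60,
        n_per_group=(3, 3),
        rng_seed=0,
    )
    defaults.update(kw)
    return synth.SimulationSpec(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
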
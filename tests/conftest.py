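import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import corespec as cs

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def tiny_cube(values, wavelengths=None, **kw):
    """Helper: SpectralCube from a (rows, cols, bands) array."""
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = np.linspace(400, 990, values.shape[2])
    kw.setdefault("pixel_size_um", 2000.0)
    return cs.SpectralCube(values=values, wavelengths=wavelengths, **kw)


def truth_map(core):
    """SOCMap wrapping a core's ground-truth SOC field."""
    return cs.SOCMap(
        values=core.soc_field,
        mask=np.ones_like(core.soc_field, dtype=bool),
        pixel_size_um=core.config.pixel_size_um,
    )


def preprocess_core(core):
    """raw cube -> (normalized+masked, snv) cubes."""
    nr = cs.mask_non_soil(cs.normalize_to_target(core.raw_cube, core.target))
    return nr, cs.snv_transform(nr)


@pytest.fixture(scope="session")
def study():
    """One default five-core study set, preprocessed, with ROIs and an SNV
    calibration set (seed 1).  Shared by read-only tests."""
    cores = cs.default_core_set(seed=1)
    nr, snv = {}, {}
    for c in cores:
        nr[c.core_id], snv[c.core_id] = preprocess_core(c)
    truths = {c.core_id: c.soc_field for c in cores}
    rois = cs.select_roi_set(snv, truths, n_total=71, seed=1)
    cal = cs.build_calibration_set(rois, snv, seed=1)
    return {
        "cores": cores,
        "nr": nr,
        "snv": snv,
        "rois": rois,
        "cal": cal,
        "bulk": [b for c in cores for b in c.bulk_truth],
    }


@pytest.fixture(scope="session")
def rf_model(study):
    return cs.fit_rf(study["cal"], cs.ModelConfig(algorithm="rf", seed=1))
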
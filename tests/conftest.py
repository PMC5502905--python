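import numpy as np
import pandas as pd
import pytest

import plaquemap as pm
from plaquemap.calibration import CalibrationSlice, grid_search
from plaquemap.pipeline import fit_cohort

from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def echo_times():
    return np.linspace(9.0, 127.0, 14)


@pytest.fixture(scope="session")
def noiseless_config():
    return pm.PhantomConfig(noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def default_config():
    return pm.PhantomConfig(seed=0)


@pytest.fixture(scope="session")
def recovery_cohorts():
    """100 seeded synthetic cohorts run through fit + threshold calibration.

    For each cohort: the calibrated threshold pair, and the per-plaque
    measured lipid area (at the calibrated pair) with symptom labels.
    Shared between the threshold-recovery check and the group-discrimination
    power check so the expensive simulation runs once.
    """
    out = []
    cfg = pm.PhantomConfig(seed=0)
    for seed in range(100):
        plaques, _ = pm.make_cohort(pm.CohortSpec(seed=seed), cfg)
        maps = fit_cohort(plaques)
        slices, owners, sym = [], [], []
        for p in plaques:
            for s in p.slices:
                slices.append(CalibrationSlice.from_t2map(
                    maps[(p.plaque_id, s.slice_index)], s.roi,
                    s.histology_lipid_pct, iph_core_share=s.iph_core_share))
                owners.append(p.plaque_id)
                sym.append(p.symptomatic)
        res = grid_search(slices)
        lipid = np.array([
            100.0 * (np.searchsorted(s.t2_values, res.best_pair.t2l, "left")
                     + s.t2_values.size
                     - np.searchsorted(s.t2_values, res.best_pair.t2h, "right"))
            / s.n_wall
            for s in slices
        ])
        df = pd.DataFrame({"plaque_id": owners, "symptomatic": sym, "lipid": lipid})
        plq = df.groupby("plaque_id").agg(
            lipid=("lipid", "mean"), symptomatic=("symptomatic", "first"))
        out.append({
            "t2l": res.best_pair.t2l,
            "t2h": res.best_pair.t2h,
            "best_r": res.best_r,
            "plaque_lipid": plq["lipid"].to_numpy(),
            "plaque_sym": plq["symptomatic"].to_numpy(dtype=bool),
        })
    return out
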
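import numpy as np
import pytest

import halfsib as hs


@pytest.fixture(scope="session")
def study_sim():
    """One study-scale simulated dataset (default design, fixed seed)."""
    cfg = hs.SimulationConfig(seed=11)
    pedigree, records, manifest = hs.simulate_dataset(cfg)
    data = hs.analysis_frame(hs.derive_traits(hs.filter_analysis_subset(records)))
    return {
        "config": cfg,
        "pedigree": pedigree,
        "records": records,
        "manifest": manifest,
        "data": data,
    }


@pytest.fixture(scope="session")
def balanced_nested():
    """Balanced 40-sire x 3-dam x 4-daughter Gaussian data with interior components."""
    rng = np.random.default_rng(42)
    s, d, k = 40, 3, 4
    vs, vd, ve = 2.0, 1.0, 4.0
    sire_eff = rng.normal(0, np.sqrt(vs), s)
    dam_eff = rng.normal(0, np.sqrt(vd), s * d)
    y = (
        10.0
        + np.repeat(sire_eff, d * k)
        + np.repeat(dam_eff, k)
        + rng.normal(0, np.sqrt(ve), s * d * k)
    )
    sire_ids = np.repeat([f"s{i}" for i in range(s)], d * k)
    dam_ids = np.repeat([f"d{i}" for i in range(s * d)], k)
    return y, sire_ids, dam_ids, (vs, vd, ve)
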
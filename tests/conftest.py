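import numpy as np
import pandas as pd
import pytest

import landgen


@pytest.fixture(scope="session")
def island():
    """Default synthetic island (seed 3): rasters, genotypes, truth, samples."""
    cfg = landgen.SimConfig(seed=3)
    rasters, mask = landgen.make_env_rasters(cfg)
    gm, truth, table = landgen.simulate_genotypes(cfg, rasters=rasters, mask=mask)
    return {
        "cfg": cfg,
        "rasters": rasters,
        "mask": mask,
        "gm": gm,
        "truth": truth,
        "table": table,
    }


@pytest.fixture(scope="session")
def island_predictors(island):
    """Environmental values at samples joined with retained PCNM scores."""
    coords = island["table"].coords(island["gm"].sample_ids)
    basis = landgen.pcnm(coords, sample_ids=island["gm"].sample_ids)
    return island["truth"].env_at_samples.join(landgen.retain_half(basis))


@pytest.fixture(scope="session")
def gf_signal_model(island, island_predictors):
    """Gradient-forest fit on the planted-cline island (shared across tests)."""
    return landgen.fit_gf(
        island["gm"], island_predictors, landgen.ForestConfig(n_trees=50, seed=3)
    )


@pytest.fixture(scope="session")
def gdm_island_model(island):
    spt = landgen.build_site_pairs(
        island["gm"], island["table"], island["truth"].env_at_samples
    )
    return landgen.fit_gdm(spt), spt


def make_sample_table(sample_ids, groups=None, coords=None):
    n = len(sample_ids)
    rng = np.random.default_rng(0)
    if coords is None:
        coords = rng.uniform(0, 10, (n, 2))
    return landgen.SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups if groups is not None else ["g"] * n,
                "x": coords[:, 0],
                "y": coords[:, 1],
            }
        )
    )
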
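from dataclasses import replace

import pandas as pd
import pytest

from coralfate.simulate import SimConfig, default_taxa, simulate_community


def small_sim_config(seed: int = 42) -> SimConfig:
    """A three-site community small enough for fast end-to-end tests."""
    scale = {"Montipora capitata": 20, "Montipora patula": 18,
             "Pocillopora spp": 12, "Porites lobata": 30}
    taxa = tuple(replace(t, n_genets=scale[t.name]) for t in default_taxa())
    return SimConfig(sites=("Kahekili", "Olowalu", "Molokini"), taxa=taxa, seed=seed)


@pytest.fixture(scope="session")
def small_community():
    patches, links, truth = simulate_community(small_sim_config())
    return patches, links, truth


def make_patches(rows) -> pd.DataFrame:
    """Patch table from (patch_id, site, year, taxon, area, extent, sev[, x, y])."""
    out = []
    for r in rows:
        r = list(r) + [float("nan")] * (9 - len(r))
        out.append(
            dict(zip(
                ["patch_id", "site", "survey_year", "taxon", "area_cm2",
                 "extent_pct", "severity", "x_m", "y_m"], r))
        )
    return pd.DataFrame(out)


def make_links(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(zip(["site", "from_year", "from_patch", "to_year", "to_patch"], r))
         for r in rows],
        columns=["site", "from_year", "from_patch", "to_year", "to_patch"],
    )
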
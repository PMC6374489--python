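import numpy as np
import pandas as pd
import pytest

import drugpath as dp
from drugpath.core_types import PROCESSES


def make_wells(records):
    """Build a wells table from compact per-well dicts (baseline-filled)."""
    defaults = {
        "survival": 1.0,
        "apoptosis_fraction": 0.05,
        "g1_fraction": 0.4,
        "s_fraction": 0.3,
        "g2m_fraction": 0.2,
        "size_all": 100.0,
        "size_g1": 90.0,
        "size_s": 100.0,
        "size_g2m": 110.0,
        "size_apoptotic": 60.0,
    }
    rows = []
    for rec in records:
        row = {
            "plate_id": "P1",
            "well": "A01",
            "cell_line": "ESC_L1",
            "group": "ESC",
            "replicate": 1,
            **defaults,
            **rec,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def tiny_dataset(records, conditions=None, groups=None):
    wells = make_wells(records)
    if conditions is None:
        conditions = [
            c
            for c in wells["condition"].drop_duplicates()
            if c not in ("untreated", "vehicle")
        ]
    if groups is None:
        groups = list(wells["group"].drop_duplicates())
    return dp.ScreenDataset(wells=wells, conditions=conditions, groups=groups)


def make_zmatrix(process_data, samples):
    """ZScoreMatrix from {process: DataFrame(conditions x samples)}."""
    stab = pd.DataFrame(samples).set_index("sample")
    return dp.ZScoreMatrix(data=dict(process_data), samples=stab)


def simple_samples(groups={"ESC": 2, "AFSC": 2}):
    rows = []
    for g, n in groups.items():
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample": f"{g}_L1|r{r}",
                    "cell_line": f"{g}_L1",
                    "replicate": r,
                    "group": g,
                }
            )
    return rows


@pytest.fixture(scope="session")
def small_screen():
    """A deterministic small screen with one planted AFSC survival effect."""
    cfg = dp.ScreenSimConfig(
        n_inhibitors=20,
        seed=123,
        noise_sd=0.3,
        planted_effects=[dp.PlantedEffect("inh_02", "survival", ("AFSC",), 4.0)],
    )
    ds, truth = dp.generate_screen(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_zscores(small_screen):
    ds, _ = small_screen
    norm = dp.normalize_to_controls(ds)
    z = dp.zscore(norm)
    dz = dp.delta_z(z)
    return ds, z, dz


@pytest.fixture(scope="session")
def signal_screen():
    """A screen where most inhibitors carry real (group-shared) effects.

    Replicates then share condition-level structure, as in a real screen,
    which is what replicate-concordance QC measures.
    """
    effects = []
    for i in range(1, 31):
        size = (4 + (i * 37) % 5) * (1 if i % 2 else -1)
        for proc in ALL_PROCESSES:
            effects.append(
                dp.PlantedEffect(
                    f"inh_{i:02d}", proc, ("ESC", "IPSC", "AFSC"), float(size)
                )
            )
    cfg = dp.ScreenSimConfig(
        n_inhibitors=81, seed=7, noise_sd=0.3, planted_effects=effects,
        controls_per_kind=4,
    )
    ds, _ = dp.generate_screen(cfg)
    return ds


@pytest.fixture(scope="session")
def structured_screen():
    """A screen with group-differential structure: ESC/IPSC vs AFSC profiles.

    Ten of 81 inhibitors carry large group-restricted effects (five on the
    ESC/IPSC side, five on AFSC).  Sparse planting keeps the z-scoring
    sigma close to the noise level, so the planted responses survive the
    noise cutoff the way real hits do.
    """
    effects = []
    for i in range(1, 11):
        size = float(5 + (i * 29) % 4)
        groups = ("ESC", "IPSC") if i <= 5 else ("AFSC",)
        effects.append(dp.PlantedEffect(f"inh_{i:02d}", "survival", groups, size))
    cfg = dp.ScreenSimConfig(
        n_inhibitors=81, seed=31, noise_sd=0.3, planted_effects=effects
    )
    ds, truth = dp.generate_screen(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def ranked_list_50():
    """A 50-gene ranked list with distinct metrics from +3 down to -3."""
    genes = [f"G{i:04d}" for i in range(1, 51)]
    return dp.RankedGeneList(
        table=pd.DataFrame({"gene": genes, "metric": np.linspace(3.0, -3.0, 50)})
    )


ALL_PROCESSES = PROCESSES


def analyze(ds, consolidate=False):
    """normalize -> z -> delta-z (+ optional ESC/IPSC consolidation)."""
    norm = dp.normalize_to_controls(ds)
    z = dp.zscore(norm)
    dz = dp.delta_z(z)
    samples = dp.consolidate_groups(z.samples) if consolidate else z.samples
    return norm, z, dz, samples
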
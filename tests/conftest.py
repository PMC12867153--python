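import numpy as np
import pandas as pd
import pytest

from proxpress.synth import SimConfig, generate_cohort, generate_tissue


def random_cell_table(
    rng: np.random.Generator,
    n_cells: int,
    n_markers: int = 3,
    field: float = 400.0,
    sample_id: str = "S",
    with_area: bool = True,
) -> pd.DataFrame:
    """Unstructured random table: uniform coordinates, lognormal markers."""
    table = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "x": rng.uniform(0, field, n_cells),
            "y": rng.uniform(0, field, n_cells),
        }
    )
    if with_area:
        table["area"] = rng.uniform(20, 150, n_cells)
    for j in range(n_markers):
        table[f"M{j}"] = rng.lognormal(0.5, 1.0, n_cells)
    return table


def brute_force_pressure(table, markers, radius, cancer_mask, percentile=90.0):
    """Independent O(n^2) reference for proximal pressures (no spatial index)."""
    xy = table[["x", "y"]].to_numpy(dtype=float)
    vals = {m: table[m].to_numpy(dtype=float) for m in markers}
    ids = table["cell_id"].to_numpy()
    out = {m: {} for m in markers}
    cancer = np.flatnonzero(np.asarray(cancer_mask, dtype=bool))
    for i in cancer:
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        nb = np.flatnonzero((d <= radius) & (np.arange(len(table)) != i))
        for m in markers:
            out[m][ids[i]] = (
                float(np.percentile(vals[m][nb], percentile)) if len(nb) else np.nan
            )
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 3v3 synthetic cohort for cohort-level tests."""
    cfg = SimConfig(n_samples_per_group=3, seed=42)
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def one_sample():
    cfg = SimConfig(seed=7)
    return generate_tissue(cfg, "S01", "sensitive", 0), cfg
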
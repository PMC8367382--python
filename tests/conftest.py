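import numpy as np
import pandas as pd
import pytest

from coreshell.pipeline import RunConfig, run_all


def match_planted_phenotypes(result) -> pd.Series:
    """Planted phenotype of each analyzed cell, by nearest planted centroid."""
    gt = result.ground_truth
    det = result.pac_gated.cells[["x_um", "y_um"]].to_numpy()
    tru = gt.cells[["x_um", "y_um"]].to_numpy()
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    return pd.Series(gt.cells["phenotype"].to_numpy()[nearest],
                     index=result.pac_gated.cells.index)


def match_planted_cells(result) -> pd.DataFrame:
    """Planted cell row for every segmented cell (nearest centroid)."""
    gt = result.ground_truth
    det = result.pac_raw.cells[["x_um", "y_um"]].to_numpy()
    tru = gt.cells[["x_um", "y_um"]].to_numpy()
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    out = gt.cells.iloc[d.argmin(axis=1)].copy()
    out.index = result.pac_raw.cells.index
    return out


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at default study conditions (seed 7)."""
    return run_all(RunConfig(seed=7, include_umap=False))
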
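import numpy as np
import pandas as pd
import pytest

from isletquant.synthetic import (
    CohortConfig,
    CompositionSpec,
    IntensityModelParams,
    gen_intensity_table,
    gen_islet_image,
)


@pytest.fixture(scope="session")
def default_params() -> IntensityModelParams:
    return IntensityModelParams()


@pytest.fixture(scope="session")
def control_table(default_params) -> pd.DataFrame:
    """Three control mice, 50 islets each."""
    cohort = CohortConfig(
        n_mice_per_group=3, islets_per_mouse=50, groups=(("WT", "44w"),), seed=11
    )
    return gen_intensity_table(cohort, {("WT", "44w"): default_params})


@pytest.fixture(scope="session")
def small_bundle():
    """Four rendered islets with ~25 cells each on a 256x256 canvas."""
    return gen_islet_image(
        CompositionSpec(cells_per_islet=25.0), n_islets=4, canvas=(256, 256), seed=3
    )


@pytest.fixture(scope="session")
def five_point_pool() -> pd.DataFrame:
    """The 5-point regression pool (x, y) with a closed-form least-squares fit."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 3.0, 5.0, 4.0, 6.0])
    return pd.DataFrame(
        {
            "mouse_id": "m1",
            "roi_id": [f"r{i}" for i in range(5)],
            "tomm20_log": x,
            "ndufb8_log": y,
            "mtco1_log": y,
            "insulin_log": y,
        }
    )


def brute_force_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Explicit-summation least squares: (slope, intercept, SEE with n-2 df)."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(xi * xi for xi in x)
    sxy = sum(xi * yi for xi, yi in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    rss = sum((yi - intercept - slope * xi) ** 2 for xi, yi in zip(x, y))
    return slope, intercept, (rss / (n - 2)) ** 0.5
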
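"""Packaged reference tables.

The package ships two small reference tables from the soybean RIL study it
models: the additive-genetic correlation matrix among the 14 physiological
and phenological traits (with narrow-sense heritabilities on the printed
diagonal), and the per-environment descriptive statistics of those traits.

The correlation table is printed with heritabilities on its diagonal, so a
naive read would silently treat an h² as a self-correlation. The loader
separates the two: correlations come back with a unit diagonal, and the
heritabilities come back as their own series.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

TRAITS = [
    "Ei", "HI", "GY", "RUE", "AGR40", "R8", "R1",
    "R5", "RL", "SFL", "LAI", "K", "A", "iWUE",
]


def _data_path(name: str):
    return resources.files("yieldpath.data").joinpath(name)


def read_table2_fixture() -> tuple[pd.DataFrame, pd.Series]:
    """Load the additive-genetic correlation matrix and heritabilities.

    Returns
    -------
    corr : DataFrame
        14 x 14 symmetric correlation matrix with unit diagonal, indexed
        by trait name in the published order.
    h2 : Series
        Narrow-sense heritability per trait (the printed diagonal).
    """
    with resources.as_file(_data_path("table2_gcorr.csv")) as path:
        raw = pd.read_csv(path, index_col=0)
    raw = raw.loc[TRAITS, TRAITS]
    values = raw.to_numpy(dtype=float)
    h2 = pd.Series(np.diag(values), index=TRAITS, name="h2")
    corr = np.where(np.isnan(values), 0.0, values)
    np.fill_diagonal(corr, 0.0)
    corr = corr + corr.T  # lower triangle is the data; mirror it
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=TRAITS, columns=TRAITS), h2


def read_table3_fixture() -> pd.DataFrame:
    """Per-environment trait means and observed ranges (mean, min, max)."""
    with resources.as_file(_data_path("table3_traits.csv")) as path:
        return pd.read_csv(path)
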
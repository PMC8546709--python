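"""Built-in example datasets.

Four small mock datasets used throughout the documentation and tests:

* ``table1`` — two mock communities with near-identical Shannon indices
  (1.609 vs 1.608) but very different composition: the textbook case the
  evenness-richness decomposition is designed to resolve.
* ``table2`` — four mock communities spanning even/uneven and species-poor/
  species-rich combinations.  Community 4's proportions are kept exactly as
  published (0.95, 0.095, 0.005 — they sum to 1.05); the evenness statistics
  for it are conventionally computed on these raw values.
* ``table3`` — ten fictional biomes (A-J) in two groups (Alpha, Omega) and
  two regions (Urban, Rural), with sample metadata; the worked dataset for
  ER distance matrices, PERMANOVA and dispersion examples.  Biome B's fourth
  proportion is stored as 0.045: the alternative reading 0.0045 makes the
  row sum 0.9595, while 0.045 is the unique value consistent with the row
  summing to 1 and with Shannon = 0.725 and NME = 0.651 for that biome.
* ``table4`` — a 2 x 3 contingency table of sample counts across two
  richness clusters and three gut enterotypes, for the chi-square test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["table1", "table2", "table3", "table4", "fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table2", "table3", "table4")

_SPECIES8 = [f"sp{i}" for i in range(1, 9)]


def table1() -> pd.DataFrame:
    """Two communities x eight species; zeros mark absent species."""
    data = {
        "community1": [0.2, 0.2, 0.2, 0.2, 0.2, 0.0, 0.0, 0.0],
        "community2": [0.500, 0.100, 0.100, 0.100, 0.095, 0.050, 0.030, 0.025],
    }
    return pd.DataFrame(data, index=_SPECIES8).T.rename_axis("sample")


def table2() -> pd.DataFrame:
    """Four communities x eight species.

    Community 4 is stored with its raw published proportions, which sum to
    1.05; see the module docstring.
    """
    data = {
        "community1": [0.2, 0.2, 0.2, 0.2, 0.2, 0.0, 0.0, 0.0],
        "community2": [0.5, 0.1, 0.1, 0.1, 0.095, 0.05, 0.03, 0.025],
        "community3": [0.333, 0.333, 0.333, 0.0, 0.0, 0.0, 0.0, 0.0],
        "community4": [0.95, 0.095, 0.005, 0.0, 0.0, 0.0, 0.0, 0.0],
    }
    return pd.DataFrame(data, index=_SPECIES8).T.rename_axis("sample")


def table3() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ten biomes x five taxa, plus Group/Region metadata."""
    rows = {
        "A": [0.7, 0.2, 0.05, 0.05, 0.0],
        "B": [0.8, 0.1, 0.05, 0.045, 0.005],
        "C": [0.8, 0.1, 0.05, 0.05, 0.0],
        "D": [0.6, 0.3, 0.05, 0.05, 0.0],
        "E": [0.8, 0.1, 0.05, 0.04, 0.01],
        "F": [0.4, 0.3, 0.3, 0.0, 0.0],
        "G": [0.6, 0.4, 0.0, 0.0, 0.0],
        "H": [0.4, 0.35, 0.25, 0.0, 0.0],
        "I": [0.6, 0.25, 0.15, 0.0, 0.0],
        "J": [0.5, 0.5, 0.0, 0.0, 0.0],
    }
    abundance = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{i}" for i in range(1, 6)]
    ).rename_axis("sample")
    metadata = pd.DataFrame(
        {
            "Group": ["Alpha"] * 5 + ["Omega"] * 5,
            "Region": ["Urban", "Rural"] * 5,
        },
        index=abundance.index,
    )
    for col in metadata:
        metadata[col] = pd.Categorical(metadata[col], categories=pd.unique(metadata[col]))
    return abundance, metadata


def table4() -> pd.DataFrame:
    """Sample counts across two richness clusters and three enterotypes."""
    return pd.DataFrame(
        np.array([[105, 26, 55], [63, 9, 13]]),
        index=pd.Index(["cluster1", "cluster2"], name="cluster"),
        columns=["enterotype1", "enterotype2", "enterotype3"],
    )


def fixture(name: str):
    """Fetch a built-in dataset by name.

    Returns a DataFrame for ``table1``/``table2``/``table4`` and an
    ``(abundance, metadata)`` pair for ``table3``.
    """
    try:
        return {"table1": table1, "table2": table2,
                "table3": table3, "table4": table4}[name]()
    except KeyError:
        raise InvalidInputError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
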
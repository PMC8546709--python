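"""Per-sample evenness-richness (ER) coordinate tables and their distances.

``er_table`` turns a samples x taxa abundance matrix into one row per sample
of (richness, NME, Shannon, Pielou, Hill-1).  ``er_distances`` builds the
pairwise Euclidean distance matrix on a chosen subset of those columns —
by default the raw (richness, NME) pair — which is the input for PERMANOVA
and dispersion diagnostics.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import diversity
from .exceptions import InvalidInputError, UndefinedResultError

__all__ = ["er_table", "er_distances", "ER_COLUMNS"]

log = logging.getLogger(__name__)

#: Columns of an ER coordinate table, in output order.
ER_COLUMNS = ("richness", "nme", "shannon", "pielou", "hill1")


def er_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Compute ER coordinates for every sample (row) of an abundance matrix.

    Each row is normalized to proportions before the per-community statistics
    are applied.  Samples with a single observed taxon get NaN for NME and
    Pielou (both undefined there) and a logged warning; all other columns are
    always defined.

    Parameters
    ----------
    matrix:
        Samples x taxa table of nonnegative counts or proportions, indexed
        by sample id.

    Returns
    -------
    DataFrame indexed like ``matrix`` with columns
    ``richness, nme, shannon, pielou, hill1``.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(matrix)
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InvalidInputError("abundance matrix is empty")
    rows = {}
    for sample, row in matrix.iterrows():
        p = diversity.relative_abundances(row.to_numpy())
        s = diversity.richness(p)
        h = diversity.shannon(p)
        if s >= 2:
            e, j = diversity.nme(p), diversity.pielou(p)
        else:
            e = j = np.nan
            log.warning(
                "sample %r has a single observed taxon; NME and Pielou are undefined",
                sample,
            )
        rows[sample] = (s, e, h, j, float(np.exp(h)))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(ER_COLUMNS))
    out.index.name = matrix.index.name or "sample"
    return out


def er_distances(
    coords: pd.DataFrame,
    features: Sequence[str] = ("richness", "nme"),
    standardize: bool = False,
) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples in ER coordinate space.

    Parameters
    ----------
    coords:
        An ER coordinate table as produced by :func:`er_table`.
    features:
        Columns to include; defaults to the raw ``(richness, nme)`` pair.
    standardize:
        If true, center each feature and scale it to unit (sample, ddof=1)
        variance before computing distances.

    Returns
    -------
    Square symmetric DataFrame indexed by sample id on both axes.
    """
    if coords.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples for a distance matrix")
    missing = [f for f in features if f not in coords.columns]
    if missing:
        raise InvalidInputError(f"unknown ER feature(s): {missing}")
    x = coords.loc[:, list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = coords.index[np.isnan(x).any(axis=1)].tolist()
        raise UndefinedResultError(
            f"samples {bad} have undefined values in {tuple(features)}; "
            "exclude single-species samples before computing distances"
        )
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise InvalidInputError("cannot standardize a constant feature")
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)
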
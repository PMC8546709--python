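"""Multivariate testing machinery for ER coordinates.

From-scratch implementations of:

* PERMANOVA with sequential (Type-I) sums of squares on a distance matrix,
  permutation p-values, and an exact-enumeration variant for small designs;
* multivariate dispersion diagnostics (PCoA embedding + per-sample distance
  to the group centroid, with a permutation homogeneity test);
* Pearson's chi-square test of independence for contingency tables;
* normal-theory bivariate confidence ellipses;
* t-based confidence intervals for a mean.

The distance-based sums of squares follow the standard construction: with
``G`` the Gower-centered matrix of squared distances, the SS attributable to
a model term is ``tr(H G)`` where ``H`` is the incremental projection onto
that term's design columns, and the residual SS is ``tr((I - H_full) G)``.
Terms enter sequentially in the order given, so each term is adjusted only
for the terms before it (the convention of vegan's ``adonis``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sympy.utilities.iterables import multiset_permutations

from .exceptions import InvalidInputError, UndefinedResultError

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "EllipseSpec",
    "gower_center",
    "permanova",
    "permanova_exact",
    "dispersion",
    "chi_square_independence",
    "confidence_ellipse",
    "mean_ci",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """ANOVA-style table for a distance-based model fit.

    ``terms`` holds one entry per model term with keys
    ``name, df, ss, f, r2, p``; the residual and total rows are separate
    attributes.  ``p`` entries are None when no permutations were run.
    """

    terms: list[dict] = field(default_factory=list)
    residual_df: int = 0
    residual_ss: float = 0.0
    total_ss: float = 0.0
    n_permutations: int = 0
    seed: int | None = None
    method: str = "monte-carlo"

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss if self.total_ss else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t["name"], "df": t["df"], "SS": t["ss"],
             "F": t["f"], "R2": t["r2"], "p": t["p"]}
            for t in self.terms
        ]
        rows.append({"term": "Residual", "df": self.residual_df,
                     "SS": self.residual_ss, "F": np.nan,
                     "R2": self.residual_r2, "p": np.nan})
        rows.append({"term": "Total", "df": self.residual_df + sum(t["df"] for t in self.terms),
                     "SS": self.total_ss, "F": np.nan, "R2": 1.0, "p": np.nan})
        return pd.DataFrame(rows)

    def format(self) -> str:
        """Human-readable table: F to 1 d.p., R2 to 2 d.p."""
        lines = [f"{'term':<16}{'df':>4}{'SS':>10}{'F':>8}{'R2':>7}{'p':>8}"]
        for t in self.terms:
            p = f"{t['p']:.4f}" if t["p"] is not None else "-"
            lines.append(
                f"{t['name']:<16}{t['df']:>4}{t['ss']:>10.4f}{t['f']:>8.1f}{t['r2']:>7.2f}{p:>8}"
            )
        lines.append(
            f"{'Residual':<16}{self.residual_df:>4}{self.residual_ss:>10.4f}"
            f"{'':>8}{self.residual_r2:>7.2f}{'':>8}"
        )
        lines.append(
            f"{'Total':<16}{self.residual_df + sum(t['df'] for t in self.terms):>4}"
            f"{self.total_ss:>10.4f}{'':>8}{1.0:>7.2f}{'':>8}"
        )
        return "\n".join(lines)


@dataclass
class DispersionResult:
    """PCoA embedding plus per-sample distances to the own-group centroid."""

    coordinates: pd.DataFrame        # samples x retained PCoA axes
    eigenvalues: np.ndarray          # descending, positive axes only
    centroids: pd.DataFrame          # groups x retained PCoA axes
    distances: pd.Series             # per-sample distance to own centroid
    groups: pd.Series                # group label per sample
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class EllipseSpec:
    """A bivariate confidence ellipse: center, semi-axes, orientation."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]   # major, minor
    angle: float                     # radians, major axis vs. x-axis
    level: float

    def polygon(self, n_vertices: int = 200) -> np.ndarray:
        """Polygonize the ellipse boundary as an (n, 2) vertex array."""
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        a, b = self.semi_axes
        xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T + np.asarray(self.center)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])    # inverse rotation
        uv = pts @ rot.T
        a, b = self.semi_axes
        return (uv[:, 0] / a) ** 2 + (uv[:, 1] / b) ** 2 <= 1.0 + _EPS


# ---------------------------------------------------------------------------
# distance-matrix plumbing
# ---------------------------------------------------------------------------

def _as_distance_array(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        a = d.to_numpy(dtype=float)
    else:
        a = np.asarray(d, dtype=float)
        ids = list(range(a.shape[0]))
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidInputError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise InvalidInputError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(a)) > 1e-8):
        raise InvalidInputError("distance matrix must have a zero diagonal")
    if np.any(a < -1e-12):
        raise InvalidInputError("distance matrix must be nonnegative")
    return a, ids


def gower_center(d) -> np.ndarray:
    """Gower double-centering of a distance matrix.

    Returns ``G = -1/2 * J A J`` with ``A = D**2`` and ``J = I - 11'/n``.
    Row and column sums of G are zero and ``tr(G)`` equals the total sum of
    squares ``sum_{i<j} d_ij^2 / n``.
    """
    a, _ = _as_distance_array(d)
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (a ** 2) @ j


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _parse_formula(formula) -> list[str]:
    if isinstance(formula, str):
        terms = [t.strip() for t in formula.split("+")]
    else:
        terms = [str(t).strip() for t in formula]
    if not terms or any(not t for t in terms):
        raise InvalidInputError(f"malformed formula: {formula!r}")
    return terms


def _term_columns(term: str, metadata: pd.DataFrame) -> np.ndarray:
    """Indicator-coding design columns for a main effect or an interaction."""
    parts = [p.strip() for p in term.split(":")]
    for p in parts:
        if p not in metadata.columns:
            raise InvalidInputError(
                f"unknown factor {p!r}; available: {list(metadata.columns)}"
            )
    blocks = []
    for p in parts:
        f = metadata[p].astype(str).to_numpy()
        levels = pd.unique(f)
        if len(levels) < 2:
            raise InvalidInputError(f"factor {p!r} has fewer than 2 levels")
        blocks.append(np.column_stack([(f == lv).astype(float) for lv in levels]))
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.einsum("ij,ik->ijk", cols, b).reshape(cols.shape[0], -1)
    return cols


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _model_projectors(metadata: pd.DataFrame, terms: list[str]):
    """Incremental projection matrices and dfs for sequential terms."""
    n = len(metadata)
    designs = [np.ones((n, 1))]
    for t in terms:
        designs.append(np.column_stack([designs[-1], _term_columns(t, metadata)]))
    hats = [_hat(x) for x in designs]
    ranks = [np.linalg.matrix_rank(x) for x in designs]
    dfs = []
    for k, t in enumerate(terms, start=1):
        df = ranks[k] - ranks[k - 1]
        if df == 0:
            raise InvalidInputError(
                f"term {t!r} is aliased with earlier terms (rank-deficient design)"
            )
        dfs.append(df)
    increments = [hats[k] - hats[k - 1] for k in range(1, len(hats))]
    resid = np.eye(n) - hats[-1]
    df_res = n - ranks[-1]
    return increments, dfs, resid, df_res


def _ss_f(g: np.ndarray, increments, dfs, resid, df_res):
    ss = np.array([np.trace(h @ g) for h in increments])
    ss_res = float(np.trace(resid @ g))
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = ss_res / df_res if df_res > 0 else np.nan
        f = np.where(
            ms_res > _EPS,
            (ss / np.asarray(dfs)) / ms_res,
            np.where(ss > _EPS, np.inf, 0.0),
        )
    return ss, ss_res, f


def permanova(
    d,
    metadata: pd.DataFrame,
    formula,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Sums of squares are sequential (Type-I) in the order the terms appear in
    ``formula`` (a string like ``"Group + Region + Group:Region"`` or a list
    of term names; ``A:B`` denotes an interaction).  The permutation null is
    generated by re-randomizing sample labels ``n_perm`` times and
    recomputing every term's pseudo-F; p-values use the add-one convention
    ``p = (1 + #{F* >= F}) / (1 + n_perm)``.

    Parameters
    ----------
    d : square DataFrame or array
        Distance matrix; if a DataFrame, its index must match
        ``metadata.index`` as a set.
    metadata : DataFrame
        One row per sample, categorical factor columns.
    n_perm : int
        Number of label permutations (>= 1).
    seed : int, optional
        Seed for the permutation stream; recorded in the result.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    a, ids = _as_distance_array(d)
    if isinstance(d, pd.DataFrame):
        missing = set(ids) - set(metadata.index)
        if missing:
            raise InvalidInputError(f"metadata missing samples: {sorted(missing)}")
        metadata = metadata.loc[ids]
    elif len(metadata) != a.shape[0]:
        raise InvalidInputError("metadata length does not match distance matrix")
    terms = _parse_formula(formula)

    increments, dfs, resid, df_res = _model_projectors(metadata, terms)
    g = gower_center(a)
    total_ss = float(np.trace(g))
    ss, ss_res, f_obs = _ss_f(g, increments, dfs, resid, df_res)

    rng = np.random.default_rng(seed)
    n = a.shape[0]
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, _, f_star = _ss_f(gp, increments, dfs, resid, df_res)
        exceed += f_star >= f_obs - 1e-10
    p = (1.0 + exceed) / (1.0 + n_perm)

    result = PermanovaResult(
        residual_df=df_res, residual_ss=ss_res, total_ss=total_ss,
        n_permutations=n_perm, seed=seed, method="monte-carlo",
    )
    for i, t in enumerate(terms):
        result.terms.append({
            "name": t, "df": int(dfs[i]), "ss": float(ss[i]),
            "f": float(f_obs[i]), "r2": float(ss[i] / total_ss), "p": float(p[i]),
        })
    return result


def permanova_exact(
    d,
    metadata: pd.DataFrame,
    factor: str,
    max_permutations: int = 50_000,
) -> PermanovaResult:
    """One-factor PERMANOVA with the exact permutation null.

    Enumerates every distinct assignment of the observed group labels to the
    samples and computes the exact p-value as the fraction of assignments
    whose pseudo-F is >= the observed one (the identity assignment counts,
    so p >= 1/K).  F and SS agree with :func:`permanova` to machine
    precision.  Intended for small designs; raises if the number of distinct
    label permutations exceeds ``max_permutations``.
    """
    a, ids = _as_distance_array(d)
    if isinstance(d, pd.DataFrame):
        metadata = metadata.loc[ids]
    labels = metadata[factor].astype(str).to_numpy()
    counts = pd.Series(labels).value_counts()
    n = len(labels)
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(c)
    if n_distinct > max_permutations:
        raise InvalidInputError(
            f"{n_distinct} distinct permutations exceed the limit "
            f"({max_permutations}); use permanova() in Monte-Carlo mode"
        )

    increments, dfs, resid, df_res = _model_projectors(metadata, [factor])
    g = gower_center(a)
    total_ss = float(np.trace(g))
    ss, ss_res, f_obs = _ss_f(g, increments, dfs, resid, df_res)

    n_geq = 0
    n_total = 0
    base = pd.DataFrame(index=metadata.index)
    for perm_labels in multiset_permutations(list(labels)):
        md = base.copy()
        md[factor] = perm_labels
        inc_p, dfs_p, resid_p, df_res_p = _model_projectors(md, [factor])
        _, _, f_star = _ss_f(g, inc_p, dfs_p, resid_p, df_res_p)
        n_total += 1
        if f_star[0] >= f_obs[0] - 1e-10:
            n_geq += 1
    p = n_geq / n_total

    result = PermanovaResult(
        residual_df=df_res, residual_ss=ss_res, total_ss=total_ss,
        n_permutations=n_total, seed=None, method="exact",
    )
    result.terms.append({
        "name": factor, "df": int(dfs[0]), "ss": float(ss[0]),
        "f": float(f_obs[0]), "r2": float(ss[0] / total_ss), "p": float(p),
    })
    return result


# ---------------------------------------------------------------------------
# multivariate dispersion (betadisper-style, centroid version)
# ---------------------------------------------------------------------------

def pcoa(d, tol: float = 1e-9) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix; axes with eigenvalues
    <= ``tol * max(eigenvalue)`` are dropped.  Sample scores are the
    eigenvectors scaled by the square root of their eigenvalue, so Euclidean
    distances among scores reproduce the input distances when the input is
    Euclidean-embeddable.
    """
    a, ids = _as_distance_array(d)
    g = gower_center(a)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(vals.max(), 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    scores = vecs * np.sqrt(vals)
    cols = [f"PCoA{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=ids, columns=cols), vals


def dispersion(
    d,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Multivariate dispersion diagnostics for PERMANOVA's homogeneity assumption.

    Embeds the distance matrix by PCoA, computes each group's centroid in
    the retained-axis space and every sample's Euclidean distance to its own
    group centroid, then tests homogeneity of those distances across groups
    with a one-way ANOVA F whose null distribution is obtained by permuting
    group labels.  (Group centroids are used rather than spatial medians.)
    """
    scores, vals = pcoa(d)
    if isinstance(groups, pd.Series):
        groups = groups.loc[scores.index].astype(object)
        groups.name = "group"
    else:
        groups = pd.Series(np.asarray(groups, dtype=object), index=scores.index, name="group")
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise InvalidInputError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise InvalidInputError(f"groups with a single sample: {small}")

    centroids = scores.groupby(groups).mean()
    diffs = scores.to_numpy() - centroids.loc[groups].to_numpy()
    dist = pd.Series(np.linalg.norm(diffs, axis=1), index=scores.index, name="distance")

    f_obs = _anova_f(dist.to_numpy(), groups.to_numpy())
    rng = np.random.default_rng(seed)
    x = dist.to_numpy()
    lab = groups.to_numpy()
    exceed = 0
    for _ in range(n_perm):
        f_star = _anova_f(x, rng.permutation(lab))
        if f_star >= f_obs - 1e-10:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)

    return DispersionResult(
        coordinates=scores, eigenvalues=vals, centroids=centroids,
        distances=dist, groups=groups, f_statistic=float(f_obs),
        p_value=float(p), n_permutations=n_perm, seed=seed,
    )


def _anova_f(x: np.ndarray, labels: np.ndarray) -> float:
    """Classical one-way ANOVA F statistic."""
    grand = x.mean()
    ss_b = ss_w = 0.0
    k = 0
    for lv in pd.unique(labels):
        xi = x[labels == lv]
        ss_b += len(xi) * (xi.mean() - grand) ** 2
        ss_w += ((xi - xi.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(x) - k
    if ss_w <= _EPS:
        return np.inf if ss_b > _EPS else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


# ---------------------------------------------------------------------------
# chi-square, ellipses, mean CIs
# ---------------------------------------------------------------------------

def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson's chi-square test of independence for an r x c count table.

    ``chi2 = sum (O - E)^2 / E`` with expected counts from the row/column
    margins; df = (r-1)(c-1); asymptotic p-value, no continuity correction.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise InvalidInputError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise InvalidInputError("contingency table must hold nonnegative counts")
    total = t.sum()
    if total <= 0:
        raise InvalidInputError("contingency table is all zero")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if np.any(expected == 0):
        raise InvalidInputError("expected count of 0 (empty row or column margin)")
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def confidence_ellipse(points, level: float = 0.95) -> EllipseSpec:
    """Normal-theory confidence ellipse for a bivariate point cloud.

    Center at the column means; axes from the eigendecomposition of the
    sample covariance; radius scaling ``r = sqrt(2 * F_q)`` with ``F_q`` the
    F(2, n-1) quantile at ``level`` (the normal-type ellipse of common
    plotting libraries).  Semi-axes are ``r * sqrt(eigenvalue)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 points for an ellipse")
    if not 0.0 < level < 1.0:
        raise InvalidInputError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] <= _EPS * max(vals[-1], 1.0):
        raise UndefinedResultError("singular covariance: points are collinear")
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    r = np.sqrt(2.0 * sps.f.ppf(level, 2, n - 1))
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(r * np.sqrt(vals[0])), float(r * np.sqrt(vals[1]))),
        angle=angle,
        level=level,
    )


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-distribution confidence interval.

    Returns ``(mean, lower, upper)`` with half-width
    ``t_{(1+level)/2, n-1} * sd / sqrt(n)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("need at least 2 values for a confidence interval")
    if not 0.0 < level < 1.0:
        raise InvalidInputError("level must be in (0, 1)")
    m = float(x.mean())
    half = float(sps.t.ppf(0.5 + level / 2.0, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size))
    return m, m - half, m + half
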
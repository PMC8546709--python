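"""Tests for the multivariate machinery: Gower centering, PERMANOVA,
dispersion/PCoA, chi-square, confidence ellipses and mean CIs."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

import erdiv
from erdiv import (
    InvalidInputError,
    UndefinedResultError,
    chi_square_independence,
    confidence_ellipse,
    dispersion,
    er_distances,
    gower_center,
    mean_ci,
    pcoa,
    permanova,
    permanova_exact,
)
from conftest import random_er_dataset


def euclid(x):
    return squareform(pdist(np.asarray(x, float)))


# ---------------------------------------------------------------------------
# Gower centering
# ---------------------------------------------------------------------------

def test_gower_zero_matrix():
    np.testing.assert_allclose(gower_center(np.zeros((4, 4))), 0.0)


def test_gower_two_points():
    d = np.array([[0.0, 2.0], [2.0, 0.0]])
    assert np.trace(gower_center(d)) == pytest.approx(2.0, abs=1e-12)


def test_gower_trace_is_total_ss(rng):
    x = rng.normal(size=(6, 3))
    d = euclid(x)
    g = gower_center(d)
    n = 6
    expected = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    assert np.trace(g) == pytest.approx(expected, abs=1e-9)
    np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(g.sum(axis=1), 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_permanova_matches_adonis_reference(dist3, table3):
    """Sequential-SS table agrees with vegan adonis2 on the ten-biome data
    (reference values frozen from an adonis2 run on the same matrix)."""
    res = permanova(dist3, table3[1], "Group + Region + Group:Region",
                    n_perm=99, seed=0)
    by = {t["name"]: t for t in res.terms}
    assert by["Group"]["ss"] == pytest.approx(8.3309, abs=1e-4)
    assert by["Group"]["f"] == pytest.approx(21.3735, abs=1e-4)
    assert by["Group"]["r2"] == pytest.approx(0.77518, abs=1e-5)
    assert by["Region"]["f"] == pytest.approx(0.1792, abs=1e-4)
    assert by["Group:Region"]["f"] == pytest.approx(0.0198, abs=1e-4)
    assert res.residual_ss == pytest.approx(2.3386, abs=1e-4)
    assert res.total_ss == pytest.approx(10.7471, abs=1e-4)


def test_permanova_partition_and_r2(rng):
    """Term SS + residual SS = total SS = sum d^2/n; R2 sums to 1."""
    for _ in range(5):
        coords, metadata = random_er_dataset(rng, n_per_group=4, n_groups=3)
        metadata["B"] = list(np.tile(["u", "v"], 6))
        d = er_distances(coords)
        res = permanova(d, metadata, "Group + B", n_perm=9, seed=1)
        ss_terms = sum(t["ss"] for t in res.terms)
        n = len(coords)
        total = (d.to_numpy() ** 2).sum() / (2 * n)
        assert ss_terms + res.residual_ss == pytest.approx(res.total_ss, abs=1e-9)
        assert res.total_ss == pytest.approx(total, abs=1e-9)
        assert sum(t["r2"] for t in res.terms) + res.residual_r2 == pytest.approx(1.0, abs=1e-9)
        for t in res.terms:
            assert 1 / (9 + 1) <= t["p"] <= 1.0


def test_permanova_sample_reordering_invariance(dist3, table3, rng):
    res1 = permanova(dist3, table3[1], "Group + Region", n_perm=9, seed=3)
    order = list(rng.permutation(dist3.index))
    res2 = permanova(dist3.loc[order, order], table3[1].loc[order],
                     "Group + Region", n_perm=9, seed=3)
    for t1, t2 in zip(res1.terms, res2.terms):
        assert t1["f"] == pytest.approx(t2["f"], abs=1e-9)
        assert t1["ss"] == pytest.approx(t2["ss"], abs=1e-9)


def test_permanova_equals_classical_anova_on_univariate_data(rng):
    """One-factor PERMANOVA on Euclidean distances of univariate data is the
    classical one-way ANOVA F."""
    y = rng.normal(size=12)
    groups = np.repeat(["a", "b", "c"], 4)
    d = euclid(y[:, None])
    metadata = pd.DataFrame({"g": groups})
    res = permanova(d, metadata, "g", n_perm=9, seed=0)
    f_ref = scipy.stats.f_oneway(*(y[groups == lv] for lv in "abc")).statistic
    assert res.terms[0]["f"] == pytest.approx(f_ref, abs=1e-9)


def test_permanova_matches_skbio_one_factor(dist3, table3):
    """Pseudo-F agrees with scikit-bio's independent PERMANOVA implementation."""
    import skbio.stats.distance as skbio_stats

    dm = skbio_stats.DistanceMatrix(dist3.to_numpy(), ids=list(dist3.index))
    ref = skbio_stats.permanova(dm, list(table3[1]["Group"]), permutations=9)
    res = permanova(dist3, table3[1], "Group", n_perm=9, seed=0)
    assert res.terms[0]["f"] == pytest.approx(ref["test statistic"], abs=1e-9)


def test_permanova_identical_groups_give_zero_f():
    coords = pd.DataFrame(
        {"richness": [3.0, 5.0, 7.0] * 2, "nme": [0.2, 0.5, 0.9] * 2},
        index=list("abcdef"),
    )
    metadata = pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3}, index=coords.index)
    res = permanova(er_distances(coords), metadata, "g", n_perm=19, seed=0)
    assert res.terms[0]["ss"] == pytest.approx(0.0, abs=1e-9)
    assert res.terms[0]["f"] == pytest.approx(0.0, abs=1e-9)


def test_permanova_determinism_and_validation(dist3, table3):
    r1 = permanova(dist3, table3[1], "Group", n_perm=49, seed=7)
    r2 = permanova(dist3, table3[1], "Group", n_perm=49, seed=7)
    assert r1.terms[0]["p"] == r2.terms[0]["p"]
    with pytest.raises(InvalidInputError):
        permanova(dist3, table3[1], "Group", n_perm=0, seed=1)
    with pytest.raises(InvalidInputError, match="aliased"):
        permanova(dist3, table3[1], "Group + Group", n_perm=9, seed=1)
    with pytest.raises(InvalidInputError):
        permanova(dist3, table3[1], "Enterotype", n_perm=9, seed=1)


def test_permanova_exact_enumeration(rng):
    """n=6, two groups of 3: exact p over all C(6,3)=20 assignments, and the
    Monte-Carlo p converges to it within 3 binomial standard errors."""
    coords, metadata = random_er_dataset(rng, n_per_group=3, n_groups=2)
    d = er_distances(coords)
    exact = permanova_exact(d, metadata, "Group")
    assert exact.n_permutations == 20
    n_perm = 10_000
    mc = permanova(d, metadata, "Group", n_perm=n_perm, seed=11)
    assert mc.terms[0]["f"] == pytest.approx(exact.terms[0]["f"], abs=1e-9)
    p_ex = exact.terms[0]["p"]
    se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
    assert abs(mc.terms[0]["p"] - p_ex) <= 3 * se + 2 / n_perm


def test_permanova_exact_degenerate_p_is_one():
    coords = pd.DataFrame(
        {"richness": [3.0, 5.0, 7.0] * 2, "nme": [0.2, 0.5, 0.9] * 2},
        index=list("abcdef"),
    )
    metadata = pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3}, index=coords.index)
    res = permanova_exact(er_distances(coords), metadata, "g")
    assert res.terms[0]["p"] == 1.0


def test_permanova_exact_rejects_large_designs():
    n = 20  # C(20, 10) = 184,756 distinct assignments
    coords = pd.DataFrame(
        {"richness": np.arange(n, dtype=float), "nme": np.linspace(0.1, 1, n)},
        index=[f"s{i}" for i in range(n)],
    )
    metadata = pd.DataFrame({"g": ["x", "y"] * (n // 2)}, index=coords.index)
    with pytest.raises(InvalidInputError, match="Monte-Carlo"):
        permanova_exact(er_distances(coords), metadata, "g")


# ---------------------------------------------------------------------------
# dispersion / PCoA
# ---------------------------------------------------------------------------

def test_pcoa_recovers_centered_coordinates(rng):
    """PCoA of Euclidean distances reproduces the centered input coordinates
    up to an orthogonal transformation (Procrustes residual < 1e-9)."""
    x = rng.normal(size=(9, 2))
    scores, vals = pcoa(euclid(x))
    xc = x - x.mean(axis=0)
    r, _ = orthogonal_procrustes(scores.to_numpy(), xc)
    assert np.abs(scores.to_numpy() @ r - xc).max() < 1e-9


def test_pcoa_rank_two_for_er_input(dist3):
    _, vals = pcoa(dist3)
    assert len(vals) == 2 and (vals > 0).all()


def test_dispersion_mirror_groups_equal_spread():
    pts = np.array([[1.0, 0.3], [2.0, 0.9], [3.0, 0.1], [4.0, 0.5]])
    mirrored = pts + np.array([10.0, 0.0])
    x = np.vstack([pts, mirrored])
    groups = ["a"] * 4 + ["b"] * 4
    res = dispersion(euclid(x), groups, n_perm=99, seed=5)
    mean_a = res.distances[np.asarray(res.groups) == "a"].mean()
    mean_b = res.distances[np.asarray(res.groups) == "b"].mean()
    assert mean_a == pytest.approx(mean_b, abs=1e-9)
    assert res.p_value > 0.5


def test_dispersion_f_matches_scipy_anova(dist3, table3):
    res = dispersion(dist3, table3[1]["Group"], n_perm=9, seed=0)
    d = res.distances
    g = np.asarray(res.groups)
    ref = scipy.stats.f_oneway(d[g == "Alpha"], d[g == "Omega"]).statistic
    assert res.f_statistic == pytest.approx(ref, abs=1e-9)
    assert (res.distances >= 0).all()
    assert list(res.eigenvalues) == sorted(res.eigenvalues, reverse=True)


def test_dispersion_validation(dist3):
    with pytest.raises(InvalidInputError):
        dispersion(dist3, ["a"] * 10, n_perm=9)
    with pytest.raises(InvalidInputError):
        dispersion(dist3, ["a"] + ["b"] * 9, n_perm=9)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi_square_enterotype_clusters(table4):
    stat, df, p = chi_square_independence(table4)
    assert round(stat, 4) == 8.1945
    assert df == 2
    assert p < 0.02


def test_chi_square_proportional_rows_give_zero():
    stat, _, p = chi_square_independence([[10, 20, 30], [20, 40, 60]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_chi_square_matches_scipy_oracle(rng):
    for _ in range(20):
        t = rng.integers(1, 50, size=(3, 3))
        stat, df, p = chi_square_independence(t)
        ref = scipy.stats.chi2_contingency(t, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_chi_square_permutation_invariance(table4, rng):
    t = table4.to_numpy()
    stat, _, _ = chi_square_independence(t)
    rp, cp = rng.permutation(2), rng.permutation(3)
    stat2, _, _ = chi_square_independence(t[np.ix_(rp, cp)])
    assert stat2 == pytest.approx(stat, abs=1e-9)


def test_chi_square_validation():
    with pytest.raises(InvalidInputError):
        chi_square_independence([[1, 2]])
    with pytest.raises(InvalidInputError):
        chi_square_independence([[0, 0], [0, 0]])
    with pytest.raises(InvalidInputError):
        chi_square_independence([[0, 0], [1, 2]])


# ---------------------------------------------------------------------------
# confidence ellipse
# ---------------------------------------------------------------------------

def test_ellipse_on_circle_is_isotropic():
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    pts = np.column_stack([np.cos(t), np.sin(t)])
    spec = confidence_ellipse(pts, level=0.95)
    assert spec.center[0] == pytest.approx(0.0, abs=1e-9)
    assert spec.center[1] == pytest.approx(0.0, abs=1e-9)
    assert spec.semi_axes[0] == pytest.approx(spec.semi_axes[1], rel=1e-6)


def test_ellipse_level_nesting(rng):
    pts = rng.normal(size=(30, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
    lo = confidence_ellipse(pts, level=0.95)
    hi = confidence_ellipse(pts, level=0.99)
    assert hi.contains(lo.polygon(100)).all()
    assert not lo.contains(hi.polygon(100)).all()


def test_ellipse_validation(rng):
    with pytest.raises(InvalidInputError):
        confidence_ellipse(rng.normal(size=(2, 2)))
    line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(UndefinedResultError):
        confidence_ellipse(line)
    with pytest.raises(InvalidInputError):
        confidence_ellipse(rng.normal(size=(10, 2)), level=1.5)


def test_ellipse_polygon_lies_on_boundary(rng):
    pts = rng.normal(size=(40, 2)) @ np.array([[2.0, 0.3], [0.0, 0.5]]) + [1, -2]
    spec = confidence_ellipse(pts)
    poly = spec.polygon(200)
    # boundary points satisfy the quadratic form at exactly 1
    c, s = np.cos(spec.angle), np.sin(spec.angle)
    rot = np.array([[c, s], [-s, c]])
    uv = (poly - np.asarray(spec.center)) @ rot.T
    q = (uv[:, 0] / spec.semi_axes[0]) ** 2 + (uv[:, 1] / spec.semi_axes[1]) ** 2
    np.testing.assert_allclose(q, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# mean CI
# ---------------------------------------------------------------------------

def test_mean_ci_constant_vector():
    m, lo, hi = mean_ci([0.4, 0.4, 0.4, 0.4])
    assert (m, lo, hi) == (0.4, 0.4, 0.4)


def test_mean_ci_alpha_group_shannon(er3, table3):
    values = er3.loc[np.asarray(table3[1]["Group"] == "Alpha"), "shannon"]
    m, lo, hi = mean_ci(values.to_numpy())
    assert m == pytest.approx(0.8008, abs=5e-4)
    assert lo < m < hi


def test_mean_ci_asymptotic_width(rng):
    x = rng.standard_normal(40_000)
    _, lo, hi = mean_ci(x, level=0.95)
    expected = 2 * 1.96 * x.std(ddof=1) / np.sqrt(len(x))
    assert (hi - lo) == pytest.approx(expected, rel=1e-3)


def test_mean_ci_validation():
    with pytest.raises(InvalidInputError):
        mean_ci([1.0])
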
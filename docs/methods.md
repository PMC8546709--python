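# Methods

## The evenness–richness decomposition

For a community with taxon proportions `p₁ … p_S` (present taxa only),
Shannon's entropy `H' = −Σ pᵢ ln pᵢ` is the sum of per-taxon *surprisal*
terms `−pᵢ ln pᵢ`. `erdiv` decomposes H' into:

* **richness** `S` — the count of taxa with nonzero abundance. Observed
  richness only; estimators that extrapolate unseen taxa (Chao1, ACE) are
  out of scope.
* **normalized-median evenness (NME)** — `median(−pᵢ ln pᵢ) / max(−pᵢ ln pᵢ)`.
  The median is a dominance-robust location summary of the surprisal terms;
  dividing by the maximum rescales it so a perfectly even community scores
  exactly 1 (every term equals the median equals the maximum) and a strongly
  dominated community scores near 0.

Pielou's `J' = H'/ln S` and the first-order Hill number `¹D = exp(H')` are
computed alongside for comparison, but the ER coordinate pair used for
plotting and testing is (richness, NME).

### Numerical conventions

* Natural logarithms throughout; no log₂/log₁₀ option.
* Absent taxa (pᵢ = 0) are excluded before anything is computed: they
  contribute no surprisal term and do not enter the NME median. Including
  `0·ln 0 := 0` terms would deflate the median of sparse communities.
* The median of an even-length surprisal list is the arithmetic mean of the
  two central order statistics.
* Ties in `max(−pᵢ ln pᵢ)` need no tie-breaking — only the value matters.
* Single-taxon communities: H' = 0 and ¹D = 1 are well defined, but NME and
  Pielou are 0/0 forms. Both raise `UndefinedResultError` rather than return
  a conventional value; `er_table` records NaN for such samples and warns,
  and `er_distances` refuses to build a distance matrix over them.
* The core functions treat their input as proportions *as given* and do not
  silently renormalize; `relative_abundances` is the explicit normalization
  step (applied row-wise by `er_table`, so count matrices are accepted
  there). This matters because evenness statistics are occasionally quoted
  in the literature for proportion vectors that do not sum exactly to 1
  (the bundled `table2` community 4, whose published proportions sum to
  1.05, is kept raw for exactly this reason).
* `table3` biome B stores its fourth proportion as 0.045: the alternative
  reading 0.0045 leaves the row summing to 0.9595, whereas 0.045 is the
  unique value consistent with the row summing to 1 and with that biome's
  established Shannon (0.725) and NME (0.651) values. NME is 0.651 under
  either reading.

## ER distances and PERMANOVA

`er_distances` computes pairwise Euclidean distances on the **raw**
(richness, NME) pairs. Richness (integer scale) then dominates the distance
relative to NME (unit interval); this is deliberate — it preserves the
interpretability of the ER plane, where axis units are the diversity metrics
themselves — and standardization to unit variance is available as an opt-in
flag. Other ER columns (shannon, pielou, hill1) may be selected via
`features=` when a different coordinate pair is wanted.

PERMANOVA partitions the total sum of squares of the distance matrix,
`SS_total = Σ_{i<j} d²ᵢⱼ / n`, via the Gower-centered matrix
`G = −½ J D² J` (`J = I − 11ᵀ/n`): the SS of each model term is `tr(H G)`
for the incremental projection `H` onto that term's indicator columns, terms
entering **sequentially (Type-I)** in the order written in the formula
(`"Group + Region + Group:Region"`). The pseudo-F for a term is
`(SS_term/df_term) / (SS_res/df_res)` and `R² = SS_term/SS_total`. The
permutation null re-randomizes sample labels (rows and columns of G
jointly), recomputes every term's F, and reports
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`. The default `n_perm` is 999 (99 gives
a p-resolution of only 0.01). For a single factor on a small design,
`permanova_exact` enumerates all distinct label assignments (≤ 50,000) and
returns the exact permutation p; it is the oracle against which the
Monte-Carlo p is tested. On Euclidean distances of univariate data the
one-factor pseudo-F reduces to the classical one-way ANOVA F, which the test
suite checks to 1e−9, and the multi-factor table is checked against vegan's
`adonis2` output for the bundled ten-biome dataset.

Degenerate designs: a term whose indicator columns add no rank beyond the
preceding terms is reported as aliased (error); a zero residual SS yields
F = ∞ for terms with positive SS and F = 0 otherwise.

## Dispersion diagnostics

`dispersion` embeds the distance matrix by principal-coordinate analysis
(eigendecomposition of G; axes with eigenvalues ≤ 1e−9 × the largest are
dropped; scores are eigenvectors scaled by √eigenvalue), computes each
group's **centroid** in the retained-axis space and each sample's Euclidean
distance to its own centroid, and tests homogeneity of those distances with
a one-way ANOVA F whose null distribution comes from permuting group labels.
Group centroids are used rather than the spatial medians that vegan's
`betadisper` defaults to: centroids are deterministic and closed-form, and
the diagnostic is used qualitatively (similar per-group spreads support the
homoscedasticity assumption behind PERMANOVA). Results will therefore differ
slightly from `betadisper(..., type = "median")`.

## Confidence ellipses and intervals

The group ellipse in ER scatter plots is the normal-theory ellipse: center
at the bivariate mean, axes from the eigendecomposition of the sample
covariance, and radius scaling `r = √(2 · F_{level}(2, n−1))`, i.e. semi-axis
lengths `r·√λₖ`. This matches the "normal"-type ellipse of common plotting
libraries; the multivariate-t variant is not implemented. Ellipses need
n ≥ 3 and a nonsingular covariance; smaller or collinear groups are drawn as
points with a warning. Ellipses are polygonized at 200 vertices.

Univariate group summaries use the t-interval
`mean ± t_{(1+level)/2, n−1} · sd/√n`. Pearson's chi-square test uses the
textbook `Σ (O−E)²/E` with margin-derived expected counts, `(r−1)(c−1)`
degrees of freedom and the asymptotic p-value; no Yates correction (the
intended use is tables larger than 2×2) and no Monte-Carlo option.

## Synthetic communities

`simulate` draws each sample's proportions from a symmetric Dirichlet: the
dimension fixes the sample's richness exactly and the concentration
parameter controls evenness (concentration → ∞ gives uniform proportions,
NME → 1; concentration ≪ 1 gives strong dominance and low NME; group-mean
NME is monotone in concentration, which the suite verifies at three
concentrations with 200 samples each). The default specification mirrors
the bundled ten-biome dataset's structure: five samples of a species-richer
uneven group (richness 5, concentration 0.8) and five of a species-poorer
even group (richness 3, concentration 15).

What the generator does *not* emulate: sequencing-depth effects on observed
richness, zero inflation / undersampling, taxon–taxon correlations, and
compositional count noise. Tests passing on these mock communities
demonstrate the correctness of the statistics, not robustness to those
real-data artifacts — in real data, richness in particular is sensitive to
sampling effort and technology, and the ER plane will expose (not remove)
such batch effects.

## Problem sizes

The bundled analyses are intentionally desk-scale: 2–10 samples, ≤ 8 taxa,
99–999 permutations. Property tests use up to 200 simulated samples, 10,000
Monte-Carlo permutations (against a 20-assignment exact enumeration) and
10,000 bivariate-normal draws for ellipse coverage.

## Known limitations

* NME is undefined at S = 1 and, like all evenness indices, compresses
  information for very small S (at S = 2 the median and maximum coincide
  unless the two surprisals differ, making NME either 1 or a simple ratio).
* Sequential SS makes term order part of the model specification; reordering
  correlated factors changes their SS. Only `A + B + A:B`-style formulas
  (main effects and pairwise interactions) are supported — no nesting,
  strata or Type-II/III SS.
* The permutation scheme is unrestricted label re-randomization; blocked or
  restricted permutations are not implemented.
* Distances other than Euclidean on ER coordinates (Bray–Curtis, UniFrac)
  are out of scope: the method is defined by the ER embedding.
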
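# Methods

## The model and its assumptions

The analysis treats a continuous trait measured across species as the
outcome of evolution along a rooted phylogeny with branch lengths. Under
Brownian motion, tip values are multivariate normal with covariance
σ²V, where `V[i, j]` is the branch length shared by tips i and j (root to
their most recent common ancestor) and `V[i, i]` is the root-to-tip depth.
Everything downstream conditions on V:

* **Blomberg's K** standardizes the ratio of the ordinary mean squared
  deviation from the GLS root estimate â (MSE0) to the V⁻¹-weighted one
  (MSE) by the ratio's expectation under Brownian motion, so K has a fixed
  benchmark of 1 on *any* tree shape, including non-ultrametric ML trees.
  K is invariant to affine trait transforms and to rescaling all branch
  lengths; the trees are therefore used exactly as inferred, with no
  dating or rate smoothing.
* **Significance** is a one-tailed permutation test: trait values are
  shuffled uniformly across tips, the phylogenetically weighted MSE is
  recomputed with â re-estimated per shuffle, and
  p = (1 + #{null MSE ≤ observed}) / (n_perm + 1). The add-one rule bounds
  p below by 1/(n_perm + 1) (0.001 at the default 999 shuffles). A config
  switch permits permuting on K itself instead; for a fixed tree the two
  orderings differ only through the per-shuffle variation of MSE0 and give
  closely similar p-values.
* **GLS/PGLS** fits abundance ~ trait with residual covariance σ²V (PGLS)
  or σ²I (GLS ≡ OLS), via Cholesky whitening. The slope t has n − 2
  degrees of freedom; the proportionality constant of V cancels, so
  branch-length units never matter. Contrasting the two fits per cell
  separates ecological trait–abundance relationships from resemblance
  inherited with the phylogeny.

One point worth recording because it is commonly mis-stated: with a single
predictor the slope t-statistic is a partial correlation in the whitened
coordinates and is therefore symmetric in which variable plays the
response — for PGLS just as for OLS. The `response` switch
(`abundance` | `trait`, default `abundance`) changes the slope's value and
units but not t, p, or the significance calls.

## Grouping rules

Urbanization levels follow the impervious-surface bands low = [0, 20),
moderate = [20, 50], high = (50, 100] — the boundary percentages 20 and 50
belong to the moderate band, reading the printed ranges literally. Species
groups are a pure function of the species × level presence pattern:
urban = present at high and not low, rural = low and not high, general =
both, middle = moderate only. Presence at moderate levels never moves a
species between urban/rural/general. The four groups provably partition
the species list, and the partition is invariant to which patch within a
level hosts a presence (both are tested properties). Groups are assigned
from the pooled species list; statistics are then run separately per habit
(tree vs shrub), since habits respond differently but occupancy is defined
by patches, not habits.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_perm` | 999 | tip shuffles per signal test; p-floor 1/(n_perm+1) |
| `alpha_signal` | .05 | significance flag for the K tables |
| `alpha_model` | .01 | significance flag for the GLS/PGLS tables |
| `min_n_signal` | 4 | below this a cell is flagged `insufficient_n` (K with n ≤ 3 is numerically meaningless) |
| `min_n_model` | 5 | regression needs df = n − 2 ≥ 3 |
| `abundance_aggregation` | `total` | per-species summed counts; `patch_mean` divides by occupied patches |
| `log10_abundance`, `log10_traits` | off | optional transforms; off because the report tables are defined on raw scales |
| `on_mismatch` | `error` | species-name reconciliation policy (`drop` warns and intersects) |

No multiple-testing correction is applied; the report conventions are
per-cell flags at the stated alphas.

Species names are matched exactly and case-sensitively after trimming
whitespace and converting internal spaces to underscores (the newick
convention). Zero-length terminal branches are clamped to 1e-8 × tree
depth with a warning, because sister tips at zero distance make V exactly
singular; internal zero branches (soft polytomies) are left untouched, as
V remains positive definite. Missing branch lengths are an error unless a
substitute is requested. All linear algebra uses symmetric
positive-definite factorizations, never explicit inversion; a Cholesky
failure surfaces as a sanitation error, not a numeric result.

## Random numbers and reproducibility

One root seed enters the configuration. Each trait × group × habit cell
derives its own seed from a SHA-256 hash of (root seed, habit, group,
trait), so any cell can be recomputed in isolation, in any order, with
identical results; rerunning a full analysis with the same config yields
byte-identical report files. K itself is deterministic and never depends
on the seed.

## What the synthetic generator emulates — and what it does not

`simulate_dataset` mirrors the survey's data shapes: a ~100-tip Yule
phylogeny (birth rate 1); nine traits evolved as
`w·BM + (1 − w)·white noise` with matched per-tip marginal variance
(default w = 0.7, moderate signal) and affine-mapped onto realistic
scales for subtropical woody plants (e.g. leaf N ≈ 20 ± 5 g/kg, maximum
height ≈ 12 ± 6 m), clipped at physical bounds; nine patches, three per
urbanization level, with per-patch occupancy probability 0.2 per level —
populating all four groups at realistic sizes (roughly 25/25/24/13 per
100 species); and per-species totals that are negative-binomial
(dispersion 1, strongly overdispersed, Poisson available as a limit)
around a log-mean with intercept 3 (≈ 20 individuals), slope 0.5 on the
standardized focal trait (maximum height), and a Brownian random effect
(SD 0.5, V scaled to unit mean diagonal) giving phylogenetically
correlated abundance residuals.

What it does not emulate: spatial patch geometry and edge/interior
structure, trait–trait correlations (traits are simulated independently; a
correlation hook exists but is off), measurement error in traits, and the
count nature of real abundances interacts with the Gaussian PGLS
assumption only approximately — the exact-calibration checks therefore
simulate Gaussian Brownian residuals directly, which is the model PGLS
assumes. Passing tests consequently demonstrate correctness of the
statistics under their own assumptions and sane behaviour on survey-shaped
data; they do not certify distributional fit to any particular field
dataset.

## Numerical and design choices

* **Pruning** collapses emptied internal nodes with branch-length
  summation but retains the root even at out-degree one, so root-to-MRCA
  depths — hence covariance entries — of the kept tips are exactly
  preserved, not just pairwise distances.
* **Degenerate cells**: constant traits yield a `degenerate_trait` flag
  (not K = 0); perfect regression fits report t = ±∞, p = 0 with a
  `degenerate_fit` note; empty or single-species summary cells are flagged
  rather than raised, so a full report table always materializes.
* **Problem sizes** in the calibration suite (50–100 tips, 500–1000
  replicates, 199 shuffles where the test needs many replicates) were
  chosen as the smallest sizes at which the Monte-Carlo error is
  comfortably below the tolerance being checked; the add-one p-value floor
  and binomial 99% acceptance intervals are computed exactly rather than
  approximated.
* **Ties** in the permutation null count against significance (`≤` in the
  add-one rule), the conservative direction.

## Known limitations

Only Brownian-motion covariance is implemented — no Pagel's λ estimation,
no Ornstein–Uhlenbeck correlation, no measurement-error models, no
phylogenetically independent contrasts. Trees are consumed as given; no
inference, dating or support handling beyond ignoring internal labels.
Impervious-surface percentages are inputs, never computed from GIS. The
middle group is structurally the smallest under any realistic occupancy
regime, so its cells are the most often flagged `insufficient_n`; that is
a property of the design, not a bug.
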
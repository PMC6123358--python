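# Methods

This note documents the statistical methods, the simulator's generative
model, every default parameter with its rationale, and the known limits of
what the simulator does and does not emulate.

## 1. Input model

One experiment is an integer OTU table (samples × OTUs) plus per-sample
metadata with four fields:

| field | values | meaning |
|---|---|---|
| `source` | `rumen` / `plate` / `cohort` | original community + its dilutions; plate washes; independent microbiomes |
| `medium` | `defined` / `undefined` / `none` | plate medium (`none` for non-plates) |
| `dilution_exponent` | 0, 1, 2, … | decimal dilution; 0 = undiluted; plates require ≥ 1 |
| `replicate` | 1, 2, … | duplicate plate index |

Counts are validated on read (non-negative integers, unique ids); errors name
the offending cell.

## 2. Preprocessing

* **Low-count filter.** An OTU is dropped when its total count pooled over
  *all* samples is ≤ `max_total` (default 2), i.e. pooled singletons and
  doubletons are removed. Filtering precedes everything else.
* **Rarefaction.** Sampling without replacement to a common depth, via
  `numpy`'s multivariate hypergeometric generator. The default depth is the
  smallest non-zero sample total among rumen + plate samples; shallower
  samples are excluded (and reported) rather than silently kept. Rarefied
  tables feed only ordination and richness statistics — set-level accounting
  always uses the non-rarefied filtered table, since presence/absence should
  not be degraded by subsampling.

## 3. Cultivability accounting

Presence of an OTU in a group (rumen = original + dilutions; defined plates;
undefined plates) means count ≥ 1 in at least one sample of the group. The
three groups induce a seven-region Venn partition; all derived quantities are
set cardinalities on it:

* **cultivable fraction** = |rumen ∩ plates| / |rumen|,
* **medium gain** = |OTUs exclusive to the added medium| / |other medium's
  full set|,
* **shared per dilution** = per (dilution, medium), the fraction of OTUs of
  *that* diluted aliquot's sequence library recovered on its plates,
* **rare biosphere** = plate-detected OTUs absent from rumen + dilutions,
  surveyed across the cohort samples for detection frequency.

Reported summaries truncate percentages to whole percents (686/2881 → 23%);
`results.json` always carries the raw fractions.

## 4. Phylogenetic cohesion test

Statistic: mean pairwise distance (MPD) over the cultured (focal) set,
compared against B (default 100) random subsets of the community pool drawn
uniformly without replacement, size-matched to the focal set. P-values use
the add-one estimator (k+1)/(B+1), so the smallest reachable value is
1/(B+1). Distance backends:

* **patristic** — path lengths on a Newick tree (vectorized bottom-up merge,
  O(n²); cross-checked against dendropy's distance matrix in the tests),
* **p-distance** — mismatches / comparable columns on an aligned FASTA,
  where a column is comparable when both sequences have an unambiguous base,
* **precomputed** — a square TSV matrix.

Family-level tests repeat the procedure inside each family with at least
`min_otus` (default 10) members on both sides, with the null drawn from that
family's pool only. Underpopulated families are skipped and listed, never an
error.

**Degenerate regime.** When the focal set is nearly as large as the pool
(high cultivable fraction), the size-matched null draws are nearly the whole
pool and the null variance collapses; the test then has no power and reports
percentile ≈ 0 or 100 with p ≈ 1. This is a property of the design, not a
bug; it is conservative, and it is the expected outcome on default-parameter
simulations, where ~80 % of the community is cultivable (see §7).

## 5. Community statistics

* **Distances/ordination.** Euclidean distances on relative abundances of
  the rarefied table; PCoA by classical scaling (Gower double-centering +
  symmetric eigendecomposition). Negative eigenvalues are floored at zero
  for coordinates; variance proportions are over positive eigenvalues. Axis
  signs are fixed deterministically (largest-|loading| sample positive).
* **PERMANOVA.** Two-factor additive model (medium × dilution, no
  interaction) with *sequential* (Type I) sums of squares computed from
  traces of hat-matrix products with the Gower-centered matrix. P-values by
  free permutation of samples, the same B (default 1000) permutations reused
  for both factors; both factor orders are reported. The one-way special
  case is verified against scikit-bio's PERMANOVA in the tests. Factors
  whose levels are aliased raise an error.
* **Exact rank tests.** The paired signed-rank test drops zero differences,
  uses doubled midranks (exact integer arithmetic under ties) and enumerates
  the full sign-assignment distribution by convolution for n ≤ 25; the
  rank-sum test enumerates all assignments for n+m ≤ 12. Both double the
  smaller tail, capped at 1; larger samples fall back to tie-corrected
  normal approximations. Six same-sign pairs give exactly 2/64 = 0.03125.
* **Multiple testing.** Holm–Bonferroni step-down (statsmodels), applied
  within each family of comparisons.
* **Abundance–cultivability correlation.** Within one dilution's rumen
  sequence library, detected OTUs are ranked by relative abundance and split
  into `n_bins` (default 100, lowered explicitly when fewer OTUs are
  detected) equal-count bins by stable sort; for each cultured subset
  (total / defined-only / undefined-only / both media) the per-bin member
  count is correlated (Pearson) with the bin's mean relative abundance.
  Holm adjustment runs across all (dilution × subset) cells; a cell is
  flagged significant when |r| > 0.3 *and* adjusted P < 0.05. Subset
  members undetected in that library (e.g. plate-only OTUs) are ignored
  with a warning and counted in `n_ignored`.

## 6. Simulator: generative model

All randomness flows from one seed through named `SeedSequence` substreams
(`tree`, `truth`, `rumen`, `plates`, `cohort`), so adding samples of one kind
never perturbs another.

1. **Phylogeny.** Pure-birth (Yule, rate 1) tree over `n_taxa` tips,
   extended by one expected waiting time past the last split, scaled to unit
   height below the first split.
2. **Community.** Relative abundances ∝ log-normal(0, σ = `abundance_sigma`)
   draws — the classic heavy-tailed "few dominants, long rare tail" shape.
3. **Cultivability.** A liability trait evolves by Brownian motion along the
   tree (variance `phylo_signal_variance` per unit height) plus independent
   Gaussian noise (`independent_noise_variance`); per-medium colony-founding
   probability is `expit(logit(base) + liability [+ boost])`, with the boost
   applied on the undefined medium. Cultivability is therefore heritable on
   the tree but not deterministic.
4. **Sequencing a liquid sample** (rumen, dilutions): cells entering the
   aliquot are Poisson with mean `inoculum_cells · 10^-d · abundance`; reads
   are a multinomial of size `read_depth` over the realized cell pool.
5. **Plates**: founder colonies are Poisson with mean `inoculum_cells ·
   10^-d · abundance · cultivability`; the plate wash is sequenced as a
   multinomial over founders weighted by a per-taxon log-normal growth
   factor (σ = `growth_dispersion`). A plate (or dilution) with zero
   cells/founders yields an all-zero row and is flagged.
6. **Cohort**: each of `n_cohort_samples` animals re-draws log-abundances as
   the focal community's log-abundance plus N(0, `cohort_log_abundance_sigma`)
   noise, renormalized — related microbiomes, not identical and not
   independent.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `n_taxa` | 3000 | community richness of the same order as deep 16S surveys of rumen |
| `abundance_sigma` | 2.5 | gives ~4–5 orders of magnitude between dominant and rare taxa |
| `inoculum_cells` | 1e7 | plated aliquot large enough that d=1 saturates and d=6 is founder-limited |
| `dilution_exponents` | 1–6 | decimal series to extinction |
| `media`, `replicates` | 2 media × 2 | defined + undefined, duplicate plates → 24 plates |
| `read_depth` | 8078 | even sequencing depth after rarefaction |
| `cultivability_base` | 0.05 | median colony-founding probability of a few percent |
| `undefined_medium_log_odds_boost` | 1.2 | ≈ factor-2 richness gain of the undefined medium in the extinction regime (calibrated property, tested over 20 seeds) |
| `phylo_signal_variance` / `independent_noise_variance` | 1.0 / 0.25 | strong but not deterministic phylogenetic signal in cultivability |
| `growth_dispersion` | 0.8 | unequal colony growth distorts plate composition |
| `n_cohort_samples` | 38 | cohort survey size |
| `cohort_log_abundance_sigma` | 1.0 | cohort microbiomes correlated with the focal one (Spearman ≈ 0.9 at the detection level) but individually distinct |
| `seed` | 0 | reproducibility |

The default design yields 1 + 6 + 24 + 38 = 69 sequenced samples.

## 7. What the simulator does and does not emulate

* **Read-depth saturation.** With `inoculum_cells` = 1e7 and `read_depth` =
  8078, low-dilution plates carry far more founders than reads, so their
  *sequenced* richness is read-limited and nearly medium-independent. The
  undefined medium's richness advantage is therefore a property of the
  extinction regime (d ≥ 4), which is where the calibration is asserted.
  Averaged over all plates the sequenced richness ratio is ≈ 1.2, even
  though the founder-level ratio is ≈ 1.4 everywhere.
* **Rare-biosphere visibility.** Plate-only OTUs arise from founder sampling
  of taxa below the sequencing detection limit — the effect is emergent, not
  planted. However, the simulator's dynamic range is compressed relative to
  a real rumen (~1e7 simulated cells vs ~1e9–1e10 real cells per aliquot):
  most simulated plate-only taxa sit just below the focal sample's detection
  limit, so a 38-animal cohort at depth 8078 *does* detect the large
  majority of them at least once (fraction never detected ≈ 0.01–0.06 at
  defaults). In a real community, plate-only taxa can be orders of magnitude
  rarer and stay invisible. Code and tests treat "fraction of the rare
  biosphere never detected in the cohort" as a reported quantity, not a
  constant of nature.
* **Dispersion vs location.** Higher dilutions diverge from the community by
  *stochastic founder sampling*, which is a dispersion effect around the
  same centroid, not a systematic location shift. PERMANOVA on default
  simulations therefore often shows substantial dilution variance without a
  small P — unlike real plates, where medium selectivity and growth biology
  add true location effects. The medium factor does shift composition (via
  the cultivability boost) and behaves accordingly.
* **Cohesion-test degeneracy at defaults** (§4): simulated cultivable
  fractions (~0.8) are far higher than typical real ones, because the
  liability model plus 1e7 cells make most abundant taxa cultivable. The
  cohesion test is most informative on data where the cultured set is a
  small minority of the pool.

## 8. Numerical choices

* Exact rank-test enumeration uses doubled midranks so tied data stay in
  integer arithmetic; no floating-point rank comparisons.
* Truncated percents are computed with `decimal` floor rounding, never via
  binary-float `int()` casts; one-decimal percents use `ROUND_HALF_EVEN`.
* Permutation P-values are always add-one, `(k+1)/(B+1)`.
* `results.json` floats are rounded to 12 significant digits; non-finite
  values serialize as `null`.
* PCoA sign convention: within each axis, the coordinate with the largest
  magnitude is made positive, so results are machine-independent.

## 9. Validation

The test suite checks every statistic against an independent oracle where
one exists: scikit-bio (PCoA, one-way PERMANOVA), scipy (signed-rank,
rank-sum, Kruskal–Wallis, Pearson), dendropy (patristic distances), plus
brute-force enumerations (Venn membership, rank tests for all n ≤ 10, 2⁶
sign assignments) and Monte-Carlo calibration of permutation type-I error
(500 null replicates within 3 binomial SE of nominal). Simulator tests pin
closed-form special cases (zero variances, zero boost, saturating inoculum,
Poisson inclusion counts) and distributional properties rather than golden
outputs.
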
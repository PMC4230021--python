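# Methods

## Model

At a single cytosine site observed in samples $i = 1, \dots, s$, the data
are read pairs $(m_i, n_i)$: $n_i$ reads cover the site in sample $i$ and
$m_i$ of them indicate methylation. Replicate methylation levels vary
biologically, so the counts are modelled beta-binomially,

$$M_i \sim \mathrm{BetaBinomial}(n_i, \pi_i, \gamma),$$

parameterized by the mean level $\pi \in (0,1)$ and the dispersion
$\gamma \in [0,1)$; in shape parameters, $\alpha = \pi(1/\gamma - 1)$ and
$\beta = (1-\pi)(1/\gamma - 1)$. Then $E(M) = n\pi$ and
$\mathrm{Var}(M) = n\pi(1-\pi)(1 + (n-1)\gamma)$: $\gamma = 0$ recovers
the binomial, and $\gamma$ near 1 means the level itself is essentially
random between replicates. Sample-level binary factors enter through a
logit link,

$$\operatorname{logit}(\pi_i) = x_i^\top \eta,$$

with $X$ an $s \times t$ binary model matrix (intercept first) and
$\eta$ the regression coefficients on the log-odds scale; $\gamma$ is a
single free parameter shared by all samples at the site, fitted per site
with no shrinkage across sites. Differential methylation with respect to
one factor is the likelihood-ratio test of the full model against the
reduced model with that factor's column(s) removed, referred to a
$\chi^2$ distribution with one degree of freedom per dropped column.

Samples with $n_i = 0$ carry no likelihood contribution and are dropped.
A site is *untestable* — reported as NA and excluded from every later
stage — when the covered-sample design loses full column rank or one
level of the test factor has no coverage at all; the LRT is undefined
there and NA is the honest answer.

## Neighborhood combination

Methylation is locally correlated, so evidence at nearby CpGs is pooled.
Raw p-values become Z-scores $z_i = \Phi^{-1}(1 - p_i)$ (p clipped to
$[10^{-15}, 1-10^{-15}]$ to keep z finite). For each testable site, all
testable same-chromosome sites within ±`window_bp`/2 (default
`window_bp` = 200) are combined by the weighted-Z (Stouffer–Liptak)
statistic

$$p_z = 1 - \Phi\!\left(\frac{\sum_i z_i}
{\sqrt{n + 2\sum_{i<j} \rho_{|p_i - p_j|}}}\right),$$

which reduces to the classic Stouffer combination $1-\Phi(\sum z/\sqrt n)$
under independence — the form of the denominator is forced by that limit.
$\rho_d$ is the Pearson correlation of Z-scores pooled genome-wide over
all pairs of testable sites exactly $d$ bp apart ($d \le$ `max_dist`,
default 200); bins with fewer than 50 pairs inherit the nearest
populated bin, and 0 is used when nothing is populated or a pair exceeds
`max_dist`. Because noisy negative correlation estimates could drive the
variance term to zero or below, the denominator is floored at
$\sqrt{0.1\,n}$. The half-window convention keeps every in-window pair
within `max_dist` of each other, so every needed $\rho_d$ is actually
estimated. Combined p-values are then Benjamini–Hochberg adjusted
(NA sites excluded from the ranking), and sites with adjusted p strictly
below the cutoff (default 0.01) are called differentially methylated.

## Regions

Consecutive DM sites on a chromosome with at most `max_gap` bp (default
200, mirroring the simulated region layout) between neighbors merge into
one region. Tested but non-significant sites interior to the span count
toward `n_cpgs` without breaking the run, so `n_sig`/`n_cpgs` measures
how strongly a region is dominated by DM sites; only gap distance breaks
runs. Each region is summarized by the pooled-count log odds ratio of
the two groups (0.5 added to methylated and 1 to total counts per group
to keep it finite at pooled levels of 0 or 1) and by the minimum over
member sites of the absolute pooled group-level difference — pooled
(coverage-weighted) rather than averaged per-sample ratios, which is
more robust at low coverage. Regions can be filtered by a minimum CpG
count (the conventional report threshold is ≥ 10) and by minimum
methylation difference (strictly above the threshold; the stringent
consistent-change filter used for reporting is 0.55). The pooled-count
log-odds (rather than one derived from fitted $\eta$) was chosen because
it stays defined for regions whose member fits straddle untestable
sites; the alternative is a line of code away in `summarize_region`.

## Fitting and numerics

- The likelihood is maximized over $(\eta, \operatorname{logit}\gamma)$
  with L-BFGS-B using an analytic gradient (digamma identities), from a
  deterministic start: $\eta$ by least squares on smoothed per-sample
  logits $\operatorname{logit}((m_i+0.5)/(n_i+1))$, $\gamma$ from 0.05.
  No randomness enters fitting.
- $\gamma$ is constrained to $[10^{-6}, 1-10^{-6}]$; boundary estimates
  are reported as-is. `log_pmf` itself handles $\gamma = 0$ exactly via
  the binomial branch.
- Convergence: relative log-likelihood change below $10^{-8}$ or
  projected-gradient norm below $10^{-6}$, at most 500 iterations. A
  line-search abort that a restart cannot improve (relative change
  $< 10^{-8}$, small gradient) counts as converged; genuinely failed
  fits retry with Nelder–Mead and are flagged honestly.
- Nested models can come back with the full log-likelihood a hair below
  the reduced one; the full fit is then restarted from the reduced
  optimum, and the LRT statistic is clamped at 0 before the $\chi^2$
  tail.
- `log_pmf` evaluates through log-gamma functions; for
  $0 < \gamma < 10^{-4}$ the huge shape parameters make `betaln` cancel
  catastrophically, so an exact rising-factorial log-sum is used there,
  and below $10^{-12}$ the binomial branch takes over (the two are
  numerically identical at that point).
- Ties in correlation-bin inheritance resolve to the nearer bin;
  estimated $\rho_d$ is clipped to $\pm 0.999$.

## Synthetic data

The generator emulates a two-group WGBS comparison on one synthetic
chromosome: inter-CpG gaps uniform on [2, 200] bp; `n_regions`
non-overlapping DM regions whose sizes are uniform on 10–100 CpGs,
placed by a random composition of the remaining sites; per site *and*
sample, a methylation level drawn from Beta(2, 2) at non-DM sites
(variance 1/20; alternatives Beta(1.5, 1.5), variance 1/16, and the
dispersion-free constant 0.7) and from Beta(6, 1.5) in cases versus
Beta(1.5, 6) in controls at DM sites; coverage i.i.d. Poisson($\lambda$)
with an optional floor, and methylated reads Binomial(level, coverage).
Drawing the level independently per replicate is exactly what makes the
counts beta-binomial across samples ($\gamma = 1/(\alpha+\beta+1)$:
0.2 under the Beta(2,2) null, ≈0.118 at DM sites). A single master seed
drives independent substreams for layout, levels, coverage, and counts,
so datasets are bit-reproducible and the layout can be held fixed while
counts vary.

Defaults are the reference study conditions: 6+6 samples at Poisson
mean coverage 10 (a typical WGBS depth; the preset `low-coverage` uses
50+50 at mean 1.5), 20,000 CpGs with 200 DM regions. The benchmark
scale is a deliberate desk-size reduction of a genome-wide experiment
(1,000 regions, ~54k DM CpGs at full scale); region count and size
range, not per-region structure, are what shrink.

What the generator does **not** emulate — and therefore what passing
benchmarks cannot certify about real data:

- Real per-CpG coverage is positionally correlated and heavy-tailed;
  some CpGs are systematically under-covered in *every* sample. With
  i.i.d. Poisson coverage, group totals concentrate tightly around
  $s\lambda$, so low-coverage benchmarks here are *easier* than their
  empirical counterparts: at 50+50 samples and $\lambda = 1.5$ the
  pipeline's Jaccard index is ≈0.98, whereas the same design driven by
  empirical coverage profiles is reported around 0.92. An
  empirical-coverage file hook (`coverage_file`, one integer depth per
  line, sampled i.i.d.) narrows but does not close that gap.
- Methylation levels are drawn independently across sites; real data
  have spatially correlated levels even outside DM regions, which is
  what the correlation-adjusted combination exists for. Under the
  generator's null the estimated $\rho_d$ are near zero and the
  combination is essentially classic Stouffer.
- No bisulfite-conversion error, strand effects, or copy-number
  artifacts.

## Calibration

The LRT's $\chi^2$ reference is asymptotic in the number of samples. At
12 samples the raw test is measurably anticonservative (≈0.08 rejection
at nominal 0.05 under the generator's null; ≈0.059 at 40 samples, ≈0.046
at 100), which matches the known finite-sample behavior of
likelihood-ratio tests and is not corrected here (no Bartlett
adjustment). Per-site fits were verified to the optimum against an
independent beta-binomial ML implementation (R glmmTMB) to six decimal
places on a fixture, so the inflation is a property of the method at
small $s$, not of the optimizer. Downstream FDR calls at 0.01 remain
conservative under the global null in simulation.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 200 bp | combination window span (±100 bp around a site) |
| `max_dist` | 200 bp | largest pair distance used for correlation estimation |
| `fdr_cutoff` | 0.01 | BH-adjusted significance threshold (strict `<`) |
| `max_gap` | 200 bp | largest gap between DM sites merged into one region |
| `min_cpgs` | 1 (report: 10) | smallest region retained |
| `min_diff` | 0.0 (report: 0.55) | minimum methylation difference filter, strict `>` |
| `clip_eps` | 1e-15 | p-value clipping before the normal quantile |
| `min_pairs` | 50 | smallest correlation bin trusted on its own |

## Known limitations

Binary factors only (multi-level factors must be encoded as several
binary columns; the LRT df follows the number of dropped columns). The
per-site dispersion is fitted without genome-wide shrinkage, which is
noisy at very few replicates — that is a deliberate modelling stance,
not an oversight, and is where the method differs from shrinkage-based
alternatives. The combination assumes the correlation profile is
homogeneous genome-wide. Region merging is rule-based (gap distance
only), not model-based segmentation.
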
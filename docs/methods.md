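# Methods

## The computed-age model

### Motivation and structure

Embryos harvested from timed matings carry three nested sources of staging
error: litters conceive up to about half a day before or after the plug
check implies, embryos within a litter spread over up to a quarter day, and
body weight — otherwise the best continuous stage proxy in the 12–16 d
window — is scaled litter-wide by maternal/pregnancy condition. The model
treats these explicitly, per strain:

| latent | prior | default | units | why |
|---|---|---|---|---|
| conception offset `c_j` | Normal(0, σ_c), truncated ±0.75 | σ_c = 0.25 | days | covers the ±0–0.5 d litter range; truncation adds jitter headroom |
| pregnancy multiplier `m_j` | Uniform(1−r, 1+r) | r = 0.10 (0.20 upper bound) | — | only the bound is known (≈20 mg on a 200 mg embryo, twice that for the upper bound); a flat density is the least-informative choice on the interval |
| within-litter jitter `u_ij` | Normal(0, σ_u) | σ_u = 0.125 | days | half of the printed 0–0.25 d spread |
| residual `ε_ij` | Normal(0, σ) on log weight | estimated | log-mg | weighing error plus non-age individual variation |

Observation model: `log w_ij = log g_s(dpc_ij + c_j + u_ij) + log m_j + ε_ij`
with `g_s` the strain's log-linear growth curve. The growth curve is fitted
by ordinary least squares of log weight on dpc (the litter terms average
out); the default calibration passes exactly through 150 mg ↔ 14.0 d and
250 mg ↔ 15.0 d, giving slope ln(5/3) ≈ 0.51 per day. A strictly
exponential curve cannot also pass exactly through the 200 mg ↔ 14.5 d
anchor (it gives 193.6 mg there, ~3% low); we treat that anchor as
approximate. The curve is considered calibrated over 50–600 mg and the
model is not intended past ~15.5 d, where growth begins to saturate.

The pregnancy effect is modeled multiplicatively: a bound phrased as
"20 mg on a 200 mg embryo" is a fraction of weight, and a multiplicative
litter effect keeps the weight positive and the bound age-independent.

### Inference

Because `log g_s` is linear in age, `u_ij` is conjugate and integrates out:
conditional on `(c_j, m_j)` each log weight is Normal with variance
`β²σ_u² + σ²`. The remaining two latents per litter are evaluated on a
41×41 grid (offset over ±0.75 d, multiplier over [1−r, 1+r]); posterior
means and the central 95% interval of `a_ij = dpc + c_j + u_ij` follow from
the exact normal-mixture posterior. The computation is deterministic — no
sampler, no seed — and a test cross-checks the grid posterior against an
MCMC (emcee) fit of the same density. cdpc is summarized by the posterior
mean. The residual σ is estimated from the pooled within-litter variance of
log weight minus the modeled age-jitter contribution `β²σ_u²`, floored at
0.01; it can also be fixed in `AgeModelConfig`.

A warning is raised when more than 20% of a litter's offset posterior mass
sits on the ±0.75 d truncation boundary — the analogue of a sampler
non-convergence diagnostic for the grid backend.

The weight-only estimator `g_s⁻¹(w)` equals the full model's posterior mean
in the limit of a single litter with the offset and multiplier priors
collapsed and σ → 0; with litter structure present it inherits the full
pregnancy bias, which is what the hierarchical model removes.

## Developmental states and the variation statistic

The four scored characters (R2 Shh, M1 Shh, cap transition, R2
protuberance) have 3, 3, 3 and 2 states; the binary character is taken to
be the protuberance (a presence/absence morphology). This is the only
assignment of "2 or 3" states to four characters whose product is 54. The
state census names each observed state by the zero-padded mean embryo
weight of its members plus the scores (`097_0_0_0_0`) and orders states by
mean weight, ties broken lexicographically.

Developmental distance between two embryos is the sum over characters of
the absolute score difference — the only reading of "sum of score
differences" that yields a metric (verified exhaustively over all 54²
pairs; maximum 7). Pairs are formed within strain among embryos strictly
less than 0.25 cdpc apart. Strains are compared by a two-sided Wilcoxon
rank-sum test on the pair distances: exact by full enumeration when both
groups are small (≤25 pairs and ≤200,000 group assignments; ties handled by
the permutation null), the normal approximation with tie correction
otherwise.

**Caveat — non-independence.** Overlapping pairs share embryos, so the
rank-sum test's nominal calibration does not hold in clustered cohorts: in
simulations with identical generating parameters for both strains the
median p-value is far below 0.5 when litters are large, because litter-level
sampling luck produces genuine distance-distribution differences that the
pair-level test resolves with thousands of dependent pairs. The test is
therefore a descriptive comparison; the suite checks near-calibration only
in a weak-dependence regime (single-embryo litters, known ages), where the
median null p falls in [0.3, 0.7]. A permutation test over embryos (not
pairs) would be the principled extension and is left as such.

The temporal profile is the LOESS (tricube, local linear, span 0.75 by
convention) of each embryo's mean neighbour distance over cdpc, with a
pointwise band equal to the local weighted residual standard deviation.
LOESS follows the textbook definition: `ceil(span·n)` nearest neighbours,
weights scaled by the furthest included distance; degenerate windows fall
back to the local weighted mean. For *peak localization* the reproducibility
experiment uses span 0.4: over a 3.5-day cohort the 0.75 default averages
more than two days of data into every local fit and flattens the
mid-gestation hump into a near-monotone trend whose maximum sits at the
data edge.

## Synthetic cohorts: what they emulate and what they do not

Defaults mirror the study design: two strains, 20 litters each cycling over
the half-day grid 12.0–15.5 dpc, 6–10 embryos per litter, conception
offsets Normal(0, 0.25) truncated ±0.75 d, within-litter jitter
Normal(0, 0.125 d), pregnancy multipliers Uniform(1±0.10), lognormal weight
noise with σ = 0.05 (≈5%, combining weighing error and non-age individual
variation), and strain-specific character transition ages concentrated in
the 14–15 d window, with the long-molar strain retaining R2 longer and
reaching M1 activation and cap transition later. Transition jitter is 0.12 d
per embryo per character. Since no distributional forms are published for
the litter effects, the Normal/Uniform choices above are modeling choices,
not reproductions.

The generator does *not* emulate: growth saturation after ~15.5 d,
correlated character timing within an embryo (jitters are independent per
character), jaw differences (upper and lower molars would be separate
tables), measurement error in the scores themselves, or expression counts
(the pathway module is exercised on hand-built tables). Passing
recovery/power tests therefore show the estimators behave correctly under
the modeled noise structure — not that real cohorts satisfy that structure.

## Reproducibility experiments

* **Recovery** (5 seeds, both strains, ~1,600 embryos): RMSE of cdpc vs
  true age ≈ 0.15 d, against ≈ 0.17 d for weight-only and ≈ 0.29 d for raw
  dpc; 95%-interval coverage ≈ 0.92. Coverage runs slightly below nominal
  because the growth curve and residual σ are estimated, not known.
* **Robustness**: cdpc under r = 0.10 vs 0.20 has Spearman rank correlation
  > 0.99 on default cohorts.
* **Power**: with one strain's timing jitter at 3× the other's and 40
  litters (~320 embryos) per strain, the Wilcoxon comparison rejects at
  α = 0.05 in ≈ 97/100 seeded replicates. Forty litters is the scale at
  which litter-level luck stops dominating the contrast (power is ~0.83 at
  20 litters).
* **Profile peak**: with all transitions injected inside 14–15 d, the
  span-0.4 profile maximum falls inside that window in 30/30 seeds.

`scripts/acceptance.py` reruns all of the above from scratch, deriving every
seed from `--seed`.

## Other numerical and design choices

* Logistic timing models: maximum likelihood via statsmodels, Wald tests.
  Complete separation (common when a character switches sharply in age) is
  detected from the perfect-separation diagnostics and triggers a
  Jeffreys-prior (Firth) penalized IRLS refit, which keeps estimates finite.
* Student's t is the pooled-variance form by design; the variance
  comparison of adult molar dimensions is a two-sided F test (the simplest
  two-sample variance test); χ² goodness-of-fit has no continuity
  correction, df = 1.
* Radial (centroid-radius) Fourier rather than elliptic Fourier: seven
  harmonics × (cos, sin) standardized by a₀ give exactly 14 size-free shape
  variables; an elliptic variant would produce multiples of four. Outlines
  must be star-shaped about their centroid; a non-star-shaped outline (e.g.
  a crescent) raises an error suggesting the elliptic variant. The anterior
  pole defines θ = 0, fixing the phase; resampled outlines carry their
  resampling center so the Fourier step never re-estimates it.
* Covariance (not correlation) PCA with the n−1 denominator; eigenvector
  signs are fixed by making the largest-magnitude loading positive.
  Duplicating every row leaves loadings and percent variances unchanged
  (all eigenvalues rescale by the same factor).
* Anterior elongation in synthetic outlines is a raised-cosine radial bump
  (half-width π/2) on the anterior pole. Note a geometric subtlety: an
  anteriorly elongated shape holds *less* area on the anterior side of its
  own centroid (the centroid balances moments, and the elongated side has
  the longer lever arm), so anterior asymmetry is asserted via the area
  split about the base-ellipse centre and the anterior reach, not about the
  centroid.
* Pathway classification resolves source conflicts toward a designated
  primary source, then excludes genes whose polarity still conflicts
  between tissues (whole tooth germs mix epithelium and mesenchyme). The
  log2FC sign convention is an explicit flag (`caption` default: positive
  fold change = higher in the focal strain; `text` inverts it) because the
  two readings cannot be reconciled from published descriptions alone.
* The packaged `interactions_synthetic.tsv` is a synthetic format
  demonstration; real analyses must supply their own curated table.

## Known limitations

* The hierarchical model assumes exponential growth; outside 12–16 dpc the
  inverse growth curve extrapolates (a warning is issued beyond 50–600 mg).
* The grid posterior bounds conception offsets at ±0.75 d; litters truly
  outside that range will be shrunk onto the boundary (warned).
* The Wilcoxon comparison of pair distances is anti-conservative under
  litter clustering (see above); interpret p-values comparatively.
* Score columns are treated as ordinal with unit steps; if real scoring
  rubrics imply unequal gaps between states, the distance underweights or
  overweights some transitions.
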
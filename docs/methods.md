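# Methods

## The estimation problem

National surveys measure haemoglobin (Hb) in young children (6–59 months)
and women of reproductive age (15–49 years), but any one compilation of
surveys is sparse: most country-years have no measurement, sources mix
individual records with summary statistics, some cover only part of a
country, some pool pregnant and non-pregnant women, and some are not
adjusted for altitude of residence. `hbtrends` estimates, for every
country and year, the *full population distribution* of haemoglobin — not
just its mean — so that the prevalence of anaemia at any cutoff (total,
severe, or anything else) follows coherently from one object, with
uncertainty propagated end to end.

## Model

For each model family (children; women) the population distribution of a
country `c` in year `t` is a five-component normal mixture

    p(h | c, t) = Σ_k w_k N(h; θ_{c,t} + o_k, τ_k²),   k = 1..5,

with component offsets `o_k` strictly increasing (a label-switching guard)
and constrained so that `Σ_k w_k o_k = 0`; the analytic mean of the
mixture is therefore exactly the location `θ_{c,t}`. The shape
`(o, w, τ)` is shared across countries within a family, allowing skewed
population distributions while keeping the shape estimable from pooled
records; a five-component mixture is flexible enough for the mild left
skew seen in haemoglobin data.

The location follows a hierarchical regression:

    θ_{c,t} = (a₀ + a_r + a_c) + (b₀ + b_r + b_c)(t − 2000)
              + u₀(t) + u_r(t) + u_c(t) + x_{c,t}ᵀβ,

i.e. a linear trend plus a smooth nonlinear trend at global, regional and
national level, plus country-year covariates (maternal education, urban
share, absolute latitude, haemoglobinopathy prevalence, and mean BMI for
women / mean weight-for-age Z for children; standardised before entering
the regression). Region and country deviations have Normal shrinkage
priors with half-Normal hyperpriors on their sds, so estimates borrow
strength when data are sparse and follow the data where they are rich.
Each nonlinear term `u(·)` is a second-order random walk (a smoothness
prior on second differences) with soft sum-to-zero and zero-slope
constraints (sd 10⁻³ g/L) so it carries curvature only and cannot be
confounded with the intercepts and slopes.

Pregnant women's location is `θ_{c,t} − δ_c`, with a country-level
pregnancy offset `δ_c ≥ 0` (truncated-Normal) shrunk toward a region mean,
itself shrunk toward a global mean centred at 11 g/L — the middle of the
8–15 g/L range observed across regions. Pregnant and non-pregnant women
share the mixture shape and differ in location only; the synthetic
generator has a switch to break this assumption for robustness
experiments. Pregnancy is defined operationally as more than 8 completed
gestational weeks, because survey reporting of pregnancy only becomes
consistent around weeks 6–10 and the haemoglobin decline is steepest
there; the classifier applies the rule strictly (`> 8`).

### Observation model

* **Individual records** contribute log mixture densities at their cell's
  location plus a per-survey non-sampling effect `e_s ~ N(0, σ_ns² [+
  σ_sub²][+ σ_age²])`. (The public single-observation log-likelihood is
  the version conditional on `e_s`.)
* **Summary means** contribute `N(mean; θ̃, sd²/n + σ_ns² + 1[subnational]
  σ_sub² + 1[age mismatch] σ_age²)`: the non-sampling variance captures
  design factors (sampling design, season, assay) that add variability
  beyond sampling error; subnational sources and sources whose age range
  does not match the target groups get extra variance.
* **Summary prevalences** contribute
  `N(prev; F(cutoff), p(1−p)/n + f(cutoff)²·σ_design²)` — the binomial
  sampling variance plus the design variance propagated to the prevalence
  scale through the density at the cutoff (first-order delta method), with
  `p(1−p)` floored at 10⁻⁴. By default prevalence terms are used **only
  for sources that report no mean** (`prevalence_mode =
  "when_mean_absent"`): a source's mean and prevalence are computed from
  the same sample, and treating both as independent double-counts the draw
  and visibly over-tightens credibility intervals in calibration runs.
  `"always"` and `"never"` are available.
* **Combined-women sources** (pregnant and non-pregnant reported
  together) are pregnancy-fraction mixtures: pooled mean
  `(1−p)θ_np + p·θ_p` and pooled prevalence `(1−p)F_np(cut_np) +
  p·F_p(cut_p)` with each subgroup's own cutoff. The fraction `p` comes
  from the source when recorded, else from a supplied country
  pregnancy-rate table.

Records outside the biological plausibility window 25–220 g/L are flagged
and excluded from the likelihood with a logged count, never silently
dropped.

### Inclusion and adjustment pipeline

Sources are included when nationally representative, or subnational but
covering at least three regions of the country (reason-coded exclusions
otherwise). Haemoglobin from residents above 1000 m is shifted down to its
sea-level equivalent with the CDC polynomial in thousands of feet `A =
metres × 0.0032808`:

    shift(A) = max(0, −0.32·A + 0.22·A²)  g/L,

about 3.8 g/L at 1500 m and 9.2 g/L at 2200 m; the negative low-altitude
branch clamps to zero, and the rule applies only at ≥ 1000 m. Individual
records are adjusted through their altitude of residence; summary sources
can only be adjusted through the country's population distribution over
altitude bands, and only in countries where more than 5% of people live at
1500 m or higher (elsewhere the unadjusted values are used, as the bias is
under 3 g/L and the exact residence mix unknown). Adjusting a summary
prevalence exactly is impossible, so it is recomputed from a normal
approximation with the shifted mean and reported sd, and the approximation
is noted on the observation. Data already adjusted for smoking are used as
such; unadjusted data get no post-adjustment (a ~0.3 g/L effect, an order
of magnitude below altitude).

## Priors and their calibration

| parameter | prior | default scale | rationale |
|---|---|---|---|
| a₀ | Normal(data mean, 50²) | 50 g/L | essentially flat |
| b₀ | Normal(0, 0.3²) | 0.3 g/L/yr | global trends beyond 3 g/L/decade implausible |
| sd(a_r), sd(a_c) | half-Normal | 10 g/L | between-region/country spreads of O(5 g/L) |
| sd(b_r), sd(b_c) | half-Normal | 0.15 / 0.1 g/L/yr | country trends rarely exceed ±2 g/L/decade |
| RW2 innovation sds | half-Normal | 0.2 / 0.1 / 0.1 g/L | smooth curvature of ≲1–2 g/L over two decades |
| σ_ns, σ_sub, σ_age | half-Normal | 5 g/L | non-sampling shifts of a few g/L |
| β (standardised) | Normal(0, 2²) | 2 g/L per sd | with few countries, covariates are weakly identified cross-sectionally; effects beyond ~2 g/L per sd are implausible |
| δ hierarchy | TN/Normal | μ₀ ~ N(11, 5²), region sd 3, country sd half-N(3) | pregnancy offsets span 8–15 g/L across regions |
| mixture | Dirichlet(2) on w; ordered N(0, 20²) on o; half-N(15) on τ | | weakly informative |

The slope and smoothness scales matter: in early calibration runs with
loose scales (0.5 g/L/yr slopes), country trends and random walks absorbed
non-sampling noise, deflating σ_ns and mis-centring data-sparse years.

## Posterior computation

The sampler is a blocked Gibbs scheme written for this model:

1. **Mixture assignments** of individual records are drawn from their
   categorical conditionals (data augmentation), making every location
   parameter conditionally Gaussian.
2. **The full location block** — `a₀, b₀, a_r, b_r, a_c, b_c, u₀, u_r,
   u_c, β` and all survey effects `e_s` (typically 300–400 scalars) — is
   drawn *jointly* from its exact multivariate-normal conditional via a
   dense Cholesky factorisation; individual records enter through
   per-(survey, component) sufficient statistics, so cost is independent
   of record count. Prevalence terms, nonlinear in θ, are folded in by a
   Metropolis accept/reject of this joint proposal (an independence
   proposal from the mean-data conditional), so the chain still targets
   the exact posterior.
3. **Pregnancy offsets** δ_c are truncated-normal Gibbs draws (with the
   same Metropolis correction when prevalence terms are active).
4. **Mixture shape**: adaptive random-walk Metropolis for ordered offsets
   and log-τ, and a Dirichlet independence-style proposal for weights;
   step sizes adapt toward 30% acceptance during warmup only.
5. **Variance hyperparameters** move by univariate slice sampling on the
   log scale, with a floor at 10⁻³ of the prior scale guarding the
   variance-collapse funnel. The non-sampling sds reuse cached model means
   and prevalence stats, which do not depend on them.

Defaults: 4 chains × 1000 warmup, thin 1, pooled to exactly 2500 retained
draws (the number the downstream summaries are built from) regardless of
chain count; everything is deterministic given `(data, config, seed)`.
Convergence is reported per scalar parameter (split R-hat ≤ 1.05, ESS ≥
100 by default); a posterior-predictive check reports the central 95%
interval per summary observation and aggregate coverage.

## Reported quantities

All summaries are computed per draw and then reduced: point estimate =
posterior mean (switchable reading; the median is a one-line change where
used), interval = 2.5th–97.5th centiles with numpy's linear interpolation
between order statistics, applied everywhere. Regional and global
distributions are population-weighted averages of country distributions
within each draw, so conservation (globe = weighted countries) holds draw
by draw to machine precision. Counts are prevalence × population.

Change per decade between two report years is absolute for mean
haemoglobin and proportional for prevalence; the default proportional
convention is geometric, `(p₂/p₁)^(10/(y₂−y₁)) − 1`, with an arithmetic
alternative behind a flag, and draws with zero baseline prevalence are
excluded with a logged count. The posterior probability of an increase is
the fraction of draws in which the quantity rose (ties count one half; 0.5
means an increase is indistinguishable from a decrease).

The iron-amenable share of anaemia applies the supplementation shifts
(10.17 g/L pregnant, 8.64 non-pregnant, 8.0 children) to the estimated
distribution: share = (F(cut) − F(cut − shift)) / F(cut). Shifting only
the sub-cutoff portion or the whole distribution yields the same
post-shift prevalence `F(cut − shift)`, so the two readings coincide for
this statistic.

The probability of halving anaemia prevalence by a target year (default
2011 → 2025) extrapolates each draw's location by continuing its linear
components and freezing the random-walk terms and covariates at their last
fitted values — extrapolating a random walk would inflate variance with no
principled rule — and counts draws whose extrapolated prevalence is at
most half the base-year value.

Estimates are fitted on 1990–2012 but reported for 1995–2011, keeping the
random-walk boundary years out of the reported window.

## The synthetic world

The generator draws a ground-truth world from the same structural
assumptions (hierarchical linear + detrended RW2 trends, covariate
effects, country pregnancy offsets uniform on 8–15 g/L, shared mildly
left-skewed five-component shape) and then simulates a survey compilation
with the heterogeneity real compilations show:

* ~40 distinct sources for 10 countries over 1990–2012
  (1.8 per country-decade), allocated ∝ √population so that populous
  countries are rarely uncovered — real compilations cover most of the
  population even when many countries lack data;
* each source measures children with probability 0.9 and women with 0.85
  (most real sources cover both);
* 40% summary-only; 25% of women's summaries pooled across pregnancy
  status with a recorded pregnant fraction; 15% subnational (2–5 regions
  covered, so some are excluded by the inclusion rule); 10% with
  mismatched age ranges; 15% left unadjusted for altitude (their measured
  values embed the altitude effect, which the pipeline must remove);
* per-survey non-sampling offsets N(0, 2.5²) g/L, plus 2.0 g/L extra sd
  when subnational and 1.5 g/L when age-mismatched; sample sizes uniform
  on 300–1200.

Global curvature is kept under ~1 g/L peak-to-peak (innovation sd 0.04)
so the world-mean trajectories are smooth and near-monotone like reported
global series, while regions and countries wiggle around 1 g/L
(innovation sd 0.08). Gestational ages of biologically pregnant women are
uniform on [0, 42] weeks; only those past 8 weeks draw from the pregnant
distribution, so the generator exercises the operational classifier
end-to-end.

What the generator does **not** emulate: cluster sampling designs,
seasonality, device differences beyond the single non-sampling variance,
duplicate/overlapping sources, and real covariate-haemoglobin causal
structure. Passing recovery tests therefore show that the estimation
machinery is correct and calibrated under the model's own assumptions at
desk scale — not that the model is correctly specified for any real
compilation.

## Numerical choices and degenerate inputs

* Time centred at t_ref = 2000; covariates standardised (means/sds stored
  on the prepared dataset).
* Survey decimal years enter the linear trend exactly; the random-walk and
  covariate terms are read at the nearest grid year.
* Summary sources missing an sd are imputed 12 g/L (a typical population
  sd) with the imputation recorded.
* Cells with a single record are rejected (sd undefined); zero-variance
  cells are flagged degenerate.
* The joint-Gaussian update retries once with a tiny diagonal jitter if
  the precision Cholesky fails.
* Slice sampling is bounded (50 step-outs, 100 shrinkage steps) and keeps
  the current value in the numerical corner case.
* When the retained-draw target does not divide by the chain count, each
  chain draws ⌈target/chains⌉ and the pooled set is truncated to the exact
  target.

## Problem sizes

The packaged validation study uses 2 regions × 5 countries × 23 years with
~40 sources and a reduced sampler (2 chains × 500 warmup, 2500 retained;
about one to two minutes on one core). The test suite's quick fits use a
4-country, 9-year world. Larger worlds and chain counts are configuration
changes, not code changes.

## Known limitations

* Shape sharing across countries within a family is a strong assumption;
  region-level shape deviations are out of scope of the default model.
* The prevalence likelihood is a delta-method normal approximation; for
  very rare events (severe anaemia with small n) it is crude, which is one
  reason prevalence terms default to mean-absent sources only.
* Pregnancy offsets are time-constant per country (δ_c, not δ_{c,t});
  with scarce pregnant data the finer resolution is not identifiable.
* Covariate coefficients are weakly identified when countries are few;
  they are regularised rather than estimated in any causal sense.
* With only two regions, region-level hyper-sds are prior-dominated.
* Posterior medians in data-sparse boundary years can differ from truth
  by more than the reported-year errors; the credibility intervals remain
  honest (truth covered), which is the quantity the method reports.
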
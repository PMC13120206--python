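# Methods

This note documents the models implemented in `sedrisk`, the defaults they
ship with, the numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Data model

The pipeline's raw input is a per-site table of sediment concentrations for
nine metals (As, Cd, Cr, Cu, Hg, Mn, Ni, Pb, Zn; mg/kg dry weight), with an
optional aluminium column used as the conservative reference element of the
enrichment factor and optional, unused coordinates. Concentrations must be
strictly positive: zeros and negatives are rejected rather than imputed,
since no detection-limit convention is part of the model. Summary standard
deviations use the sample (n−1) denominator — the appropriate choice for a
~21-site survey treated as a sample of the lake — and coefficients of
variation are reported in percent.

## Distribution toolkit

A `DistributionSpec` is a family tag plus parameters (point, normal,
lognormal, scaled beta, Weibull, triangular, uniform, discrete uniform),
backed by `scipy.stats` for densities, moments and sampling. Fitting is by
**moment matching** rather than maximum likelihood, because the intended
inputs are published summary rows (min, max, mean, sd/cv), not raw data:

- lognormal: σ² = ln(1 + cv²), μ = ln(mean) − σ²/2 (exact mean match);
- uniform: support [min, max];
- triangular: mode c = 3·mean − min − max, clamped into [min, max] (the
  clamp trades an exact mean for a valid distribution in extreme cases);
- scaled beta: shapes from the mean and variance of the variable rescaled
  to [min, max]; infeasible variances (v ≥ m(1−m)) raise a fit error that
  suggests the triangular or uniform family;
- Weibull: shape solved from the cv by a bracketed root solve on
  Γ(1+2/k)/Γ(1+1/k)² − 1 = cv² (k ∈ [0.05, 200], |Δ| < 1e−12), scale from
  the mean;
- discrete uniform: not recoverable from moments, so it falls back to the
  triangular rule by default, with `discrete_fallback="lognormal"` as the
  alternative used wherever an expectation-based comparison needs an
  untruncated, smooth model (this matters only for Mn).

Goodness of fit uses the **Anderson–Darling statistic** against the fitted
CDF, A² = −n − (1/n)·Σ(2i−1)[ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))], with
probability integrals clipped to [1e−12, 1−1e−12]. It is used purely
comparatively to rank candidate families (ascending A², ties broken by
candidate order); no p-values or critical tables are involved, and scipy's
`anderson` (which estimates parameters internally for a fixed family list)
deliberately is not, since the comparison here is between externally fitted
specs. A caveat of ranking moment-fitted families this way: a scaled beta
fitted to the empirical [min, max] can edge out the true generator on
bounded or truncated data (beta(1,1) *is* the uniform law), so family
"recovery" is only sharp for clearly shaped families such as the lognormal.

Randomness follows one root seed; every named variable (each metal, each
exposure parameter) draws from an independent substream derived from the
seed and a CRC-32 hash of its name, so identical configurations are
bit-reproducible and adding a variable never shifts another's draws.

## Pollution indices

Igeo, EF, Cf, Er and RI are implemented as written in the README, with
grading schemes whose intervals are **closed on the upper end** (a value
exactly on a breakpoint takes the lower grade). Two defaults deserve
explanation:

- **Er mode.** The default `paper_division` computes Er = Tr/Cf, matching
  the study this package reproduces, whose printed per-metal Er means are
  numerically consistent only with the division form (e.g. Pb:
  5·23.3/31.98·(1+cv²) ≈ 3.77, and Hg ≈ 12.8 rather than the ≈ 145 the
  product form would give). Hakanson's standard product Tr·Cf is available
  as `hakanson_product` and is the form to use for comparability with the
  wider literature. Under the division form, larger contamination gives a
  *smaller* Er, so its "risk" ordering is toxicity-dominated.
- **Backgrounds.** Cf and Er use the same Dongting Lake water-system
  background row as Igeo; all reference values are configurable.

For a lognormal concentration model, E[Tr·Cn/C] = Tr·(Cn/mean)·(1 + cv²)
in closed form; this serves as the analytic oracle for Monte Carlo means of
the division-form Er in the test suite.

## Health risk

Doses follow the two-pathway USEPA chronic-exposure model (see README).
Key choices:

- **Unit bridge.** Skin area is published in m², the adherence factor in
  mg/(cm²·d); SA is converted to cm² (×10⁴) inside the dermal dose, with
  CF = 1e−6 kg/mg. This combination reproduces the published child dermal
  hazard index (≈ 0.50); omitting the conversion is off by four orders of
  magnitude.
- **Averaging time.** Non-carcinogenic AT = 365·ED days, so ED cancels and
  the dose is an exposure-day average; carcinogenic AT = 365·70 days, so
  doses scale as ED/70 (1 for the 70-year adult duration, 18/70 for
  children).
- **Exposure distributions** (defaults, per published handbook values):
  ingestion rate point 114 (adults) / 200 (children) mg/d; exposure
  frequency triangular 345 (180–365) d/a; body weight lognormal
  67.55 ± 8.72 kg (adult males) and 57.59 ± 8.03 kg (adult females),
  triangular 29.30 (5.20–56.80) kg (children); skin area triangular per
  group (m²); adherence factor lognormal 0.49 ± 0.54 (adults) and
  0.65 ± 1.2 (children) mg/(cm²·d). "mean ± sd" lognormals are
  parameterized through the same arithmetic-moment bridge as
  concentrations; the child AF has sd > mean and is genuinely heavy-tailed
  — it is left untruncated above, and that tail is what drives most of the
  dermal HI > 1 exceedance probability.
- **Hazard/risk thresholds.** HI ≤ 1 is negligible, strictly above 1
  potential; TCR < 1e−6 negligible, [1e−6, 1e−4) acceptable, ≥ 1e−4
  unacceptable (the boundary point 1e−4 is classed unacceptable; the
  source's wording leaves that point ambiguous). Carcinogenic risk is
  computed only for metal/route pairs with a published slope factor
  (ingestion: As, Cd, Cr, Pb; dermal: As, Cd); elsewhere it is absent, not
  zero.
- The adult-female results follow the published parameters as printed, but
  the source's own printed female ingestion HI (0.31, against 0.15 for
  heavier adult males with identical intake) cannot follow from those
  parameters; female values are therefore reported but not used for any
  quantitative comparison.

## Monte Carlo engine

`run_mc` draws each input from its substream, evaluates the model once,
vectorized, and summarizes with the mean, median and a percentile
confidence interval (default 95%, i.e. the 2.5th/97.5th percentiles — the
plain reading of an unqualified "95% CI"). Class probabilities are the
empirical fractions of draws per grade; exceedance uses a strict ">" to
mirror the "HI > 1" convention, so exceedance at a breakpoint equals the
summed mass of the higher classes exactly. Inputs are independent; a
Gaussian-copula correlation hook was considered and deliberately left out
of the defaults because no inter-metal correlation matrix is published with
coefficients. Sensitivity uses the signed contribution-to-variance
convention of commercial risk simulators: sign(ρ)·ρ²/Σρ²·100 with ρ the
Spearman rank correlation between each input's draws and the output, so
absolute contributions sum to 100 and a single varying input reports ±100.
This convention was chosen because the reproduced study names no method;
its exact sensitivity percentages are therefore not comparison targets,
though the qualitative structure (body weight strongly negative and
dominant for children via ingestion; the adherence factor ≈ 84–85%
positive for dermal exposure in every group) is reproduced.

## Synthetic data generator

The generator stands in for the study's unpublished raw table: 21 sites by
default, each metal drawn from its published family moment-fitted to the
published min/max/mean/cv (sd is derived from the cv where the rounded,
printed sd disagrees with it). Unbounded fits (lognormal, Weibull) are
truncated to the observed [min, max] by rejection sampling — exact for the
truncated law — which keeps synthetic tables inside observed ranges at the
cost of biasing means by a few percent for strongly skewed metals (Hg most
of all); expectation-based comparisons therefore use the untruncated
lognormal models directly. The aluminium column is a truncated-positive
normal ratio (mean 1.655, cv 10%) times a nominal 66,000 mg/kg crustal
background: the 1.655 is reverse-engineered from the uniform ≈ 1.65×
offset between the study's printed EF and Cf means (the background scale
cancels out of EF entirely). What the generator does **not** emulate:
spatial structure (inflow/outflow enrichment, nearshore gradients),
inter-metal correlations, and the genuinely discrete character of the Mn
distribution. Passing tests on synthetic data therefore validate the
arithmetic, the distributional machinery and the published-moment regime —
not spatial inference or correlated-source behaviour on real surveys.

## Problem sizes and tolerances

Stochastic checks use 100,000 draws for concentration-model expectations
and 100,000 iterations for the health-risk simulations (the source's
production setting of 10,000 is the package default elsewhere); at these
sizes every stochastic comparison in the test suite sits several standard
errors inside its tolerance. Fitted-mean identities are asserted to 1e−9;
worked statistic examples to 4 decimal places; Monte Carlo means against
analytic oracles to 3 standard errors.

## Known limitations

- The division-form Er is non-standard; cross-study comparisons should use
  `hakanson_product`.
- No inhalation pathway, no age-resolved child cohorts, no Pb-specific
  biokinetic modelling.
- Independence of all Monte Carlo inputs; real inter-metal correlations
  would mostly widen RI and HI intervals.
- The discrete-uniform family is approximated by continuous stand-ins.
- Published class probabilities derived from the study's own raw data
  (e.g. its 48% moderate-class probability for Hg) reflect distributions
  fitted to data this package cannot access; the moment-matched models
  reproduce published *means* closely but such probabilities only
  approximately.
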
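# sedrisk

Probabilistic heavy-metal pollution and risk assessment for lake sediments.

`sedrisk` is for environmental scientists assessing sediment contamination in
small and medium urban lakes. Starting from a per-site table of nine metal
concentrations (As, Cd, Cr, Cu, Hg, Mn, Ni, Pb, Zn, mg/kg dry weight, with an
optional Al reference-element column), it computes the standard sediment
pollution indices, a two-pathway USEPA-style human health risk model for
three population groups, and propagates uncertainty in both through seeded
Monte Carlo simulation with class probabilities, percentile confidence
intervals and contribution-to-variance sensitivity analysis. A synthetic-data
generator produces study-scale datasets (21 sites by default) whose
per-metal distribution family and moments match a published summary table,
for use when raw per-site data are unavailable.

## The models

**Pollution indices.** For measured concentration $C$ and geochemical
background $C_0$ (Dongting Lake water-system values by default):

- Geo-accumulation index $I_{geo} = \log_2\!\left[C / (1.5\,C_0)\right]$,
  graded 0–5 (uncontaminated → extremely contaminated), intervals closed on
  their upper end.
- Enrichment factor $EF = (C_i/C_{Al})_{sample} / (C_i/C_{Al})_{background}$
  with aluminium as the conservative reference element.
- Contamination factor $Cf_i = C_i / C_{n,i}$; single-metal potential
  ecological risk $Er_i = T_{r,i} / Cf_i$ in the default `paper_division`
  mode (the form the reproduced study prints and its results follow), or
  Hakanson's canonical $Er_i = T_{r,i} \cdot Cf_i$ under
  `mode="hakanson_product"`; comprehensive risk $RI = \sum_i Er_i$.

**Health risk.** Average daily doses via oral ingestion and dermal contact,

$$CDD_{ing} = \frac{C_k \cdot IR_{ing} \cdot ED \cdot EF \cdot CF}{BW \cdot AT},
\qquad
CDD_{derm} = \frac{C_k \cdot SA \cdot AF \cdot ABS \cdot ED \cdot EF \cdot CF}{BW \cdot AT},$$

with hazard quotient $HQ = CDD/RfD$, hazard index $HI = \sum HQ$ (HI > 1
flags potential non-carcinogenic risk), and carcinogenic risk
$CR = CDD \cdot SF$ summed into $TCR$ where slope factors exist. Exposure
parameters are full probability distributions per group (adult males, adult
females, children) rather than fixed points.

**Monte Carlo.** Concentration models are parametric distributions
(lognormal, Weibull, scaled beta, triangular, uniform, …) fitted by moment
matching and ranked by the Anderson–Darling statistic; all random inputs are
drawn from independent, name-keyed substreams of one root seed, so results
are exactly reproducible and adding a variable never perturbs the others.

## Worked example

```python
import sedrisk as sr

# 1. synthetic 21-site dataset under the default lake profile
profile = sr.default_liuye_profile()
table = sr.generate_samples(profile, seed=7)
print(sr.summarize_samples(table).loc[["Hg", "Mn"]].round(3))

# 2. deterministic index at the published mean Hg concentration
ig = float(sr.igeo(0.17, 0.047))
print("Igeo(Hg) =", round(ig, 2), sr.classify_igeo(ig)[1])

# 3. Monte Carlo contamination probabilities for Hg
spec = sr.fit_by_moments("lognormal", {"mean": 0.17, "cv": 55.07})
cfg = sr.MonteCarloConfig(n_iterations=100_000, seed=7)
res = sr.run_mc(lambda c: sr.igeo(c, 0.047), {"c": spec}, cfg)
probs = sr.class_probabilities(res, sr.IGEO_SCHEME)
print("mean Igeo(Hg) =", round(res.mean, 2),
      "P(moderate) =", round(probs["Moderately contaminated"], 3))

# 4. children's ingestion hazard index
conc = {m: p.mean for m, p in profile.metals.items()}
hi = sr.hazard_index_mc(conc, sr.default_profiles()["child"], "ingestion", cfg)
print("child ingestion HI =", round(hi.mean, 2),
      " P(HI>1) =", f"{100 * sr.exceedance_probability(hi, 1.0):.1f}%")
```

prints

```
           min      max    median      mean       sd      cv
metal
Hg       0.092     0.28     0.137     0.149    0.048  32.482
Mn     613.487  1726.21  1022.550  1122.387  331.240  29.512
Igeo(Hg) = 1.27 Moderately contaminated
mean Igeo(Hg) = 1.08 P(moderate) = 0.435
child ingestion HI = 0.65  P(HI>1) = 11.1%
```

Mercury sits a full grade above its background (moderately contaminated,
with ~44% probability of the moderate class once concentration uncertainty
is propagated), and a child's ingestion hazard index averages well below the
threshold of 1 but exceeds it in about 11% of simulated exposure scenarios —
the kind of tail risk a fixed-parameter assessment cannot see.

## Command line

```bash
sedrisk all --seed 1 --outdir report          # full pipeline bundle
sedrisk simulate --seed 1 --out samples.csv   # synthetic dataset only
sedrisk indices --input samples.csv --out indices.csv
sedrisk healthrisk --input samples.csv --out health.csv
```

The `all`/`report` bundle contains summary statistics, fitted distribution
families with Anderson–Darling statistics, per-site index tables with
grades, Monte Carlo index and health-risk summaries with class and
exceedance probabilities, a sensitivity table, and a run log. All outputs
are plain CSV/JSON; identical configurations produce byte-identical tables.

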
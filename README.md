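# mibmodel

Succession modelling for degraded areas, indexed by the **Mean Individual
Biomass (MIB)** of carabid beetles (Coleoptera, Carabidae).

Restoring degraded land — post-agricultural fields, power-station ash
heaps, brown-coal mining heaps — requires knowing how fast, and toward
what state, succession proceeds. Ground beetles are a convenient probe:
as succession advances, large-bodied forest species displace small
pioneer species, so the mean body mass per individual in a pitfall-trap
catch rises with stand age. `mibmodel` turns that observation into a
quantitative workflow for ecologists working with chronosequence (space
for time) designs:

1. **MIB computation** from catch tables:
   `MIB = Σ_s count_s · mass_s / Σ_s count_s` (mg per individual), with
   samples of fewer than 25 individuals flagged as unreliable, and a
   Spearman rank test of the MIB–age trend (exact permutation p for
   n ≤ 8).
2. **A four-parameter delayed-logistic succession model.** The state
   N (mg MIB) stays at an *initial degradation level* N₀ for a *delay*
   t_delay years, then follows logistic growth
   `dN/dt = r N (K − N)/K` with *increase rate* r toward the *recovery
   level* K. With t = t_start − t_delay the closed form is
   `N(t) = K / (1 + ((K − N₀)/N₀) e^{−rt})` for t ≥ 0 and `N = N₀` for
   t < 0. Presets for five degraded-area types are shipped
   (forest-soil, natural and planted post-agricultural, ash heap,
   mining heap).
3. **Parameter estimation**: bounded nonlinear least squares with the
   delay profiled on a grid, plus identifiability flags when the data
   span cannot constrain a parameter (no young stands → N₀/delay
   unverifiable; no old stands → K unverifiable).
4. **A community simulator** that draws synthetic pitfall catches whose
   expected MIB follows any parameter set, via a two-guild (small-early /
   large-late) dominance shift — so the whole pipeline is testable
   without field data.

## Worked example

Simulate a mining-heap chronosequence (4 sites aged 3–23 years, three
consecutive sampling years each, ~200 beetles per site-year), compute the
MIB series, and fit the model with the initial level fixed at 40 mg:

```sh
mibmodel simulate --preset mining_heap --seed 7 --out catches.csv --masses-out masses.csv
mibmodel mib --catches catches.csv --masses masses.csv --area-type mining_heap --out series.csv
mibmodel fit --series series.csv --area-type mining_heap --fix-n0 40 --out params.csv
```

prints

```
delayed-logistic succession fit
  n points used : 12 (ages 3-25 y)
  initial level : 40 mg  [fixed]
  delay         : 10.42 y
  increase rate : 0.7686 1/y
  recovery level: 199.4 mg
  rss           : 602.616 mg^2
```

The simulator's generating parameters were delay 10 y, rate 0.6 y⁻¹ and
recovery level 210 mg: with only 12 site-year points the fit lands within
half a year on the delay and within ~5% on the recovery level, while the
rate is the least precise parameter — exactly the behaviour to expect from
a real 4-site chronosequence. The MIB–age trend itself is strongly
positive (Spearman ρ = 0.89, p ≈ 1.1 × 10⁻⁴, n = 12, via
`spearman_mib_age`).

`mibmodel model --preset ash_heap --out curve.csv --plot curve.png` draws
a preset curve over ages 0–60, dashing the segments whose parameters are
marked unverifiable in the preset file; `mibmodel predict` projects a
fitted curve forward, flagging extrapolated ages.

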
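# lbstock — length-based stock assessment for data-poor fisheries

`lbstock` implements the complete length-based assessment workflow used for
data-poor pelagic stocks such as chub mackerel (*Scomber japonicus*) in the
high-seas Northwest Pacific purse-seine fishery: fisheries there lack the
catch series, abundance indices and ageing data that classical assessment
models require, so everything is estimated from length-frequency (LF)
samples of the commercial catch plus vessel logbooks. The package is aimed
at fisheries scientists who need a tested, reproducible alternative to
running FiSAT II / TropFishR by hand, and at simulation studies of how
length-based estimators behave.

## What it computes

With fork length L (cm unless noted), the pipeline estimates, per year:

* **Length–weight**: W = a·L^b by log₁₀–log₁₀ OLS, with a t-test of b = 3
  classifying growth as isometric or positive/negative allometric.
* **Growth (ELEFAN / VBGF)**: the von Bertalanffy growth function
  L(t) = L∞·(1 − e^(−K(t − t₀))) fitted by electronic length frequency
  analysis — a grid search over (L∞, K) that maximizes the score
  Rn = 10^(ESP/ASP)/10 of restructured LF peaks explained by the growth
  curve; t₀ from the empirical relation
  log₁₀(−t₀) = −0.3922 − 0.2752·log₁₀L∞ − 1.038·log₁₀K, and the growth
  performance index φ′ = log₁₀K + 2·log₁₀L∞.
* **Mortality**: total mortality Z from the length-converted catch curve
  ln(Nᵢ/Δtᵢ) = c + d·tᵢ′ (Z = −d); natural mortality from the empirical
  regression ln M = −0.0152 − 0.279·ln L∞ + 0.654·ln K + 0.463·ln T;
  F = Z − M and exploitation rate E = F/Z.
* **LBB (length-based Bayesian biomass)**: Metropolis–Hastings fit of the
  equilibrium length-structure model
  N_{i+1} = Nᵢ·((L∞−L_{i+1})/(L∞−Lᵢ))^(M/K + F/K·S(Lᵢ)), catch ∝ Nᵢ·S(Lᵢ),
  with logistic gear selectivity S(L) = 1/(1+e^(−α(L−Lc))), giving posterior
  (L∞, Lc, α, M/K, F/K). From these, Beverton–Holt per-recruit theory gives
  Lopt = 3L∞/(3+M/K), Lc-opt = L∞(2+3F/M)/((1+F/M)(3+M/K)), relative yield
  and biomass Y′/R, CPUE′/R, B₀′/R, B/B₀, the proxy Bmsy/B₀ (F = M,
  Lc = Lc-opt), B/Bmsy, length indicators (L95th/L∞, Lmean/Lc-opt,
  Lc/Lc-opt) and a status label (healthy / fully exploited / overfished /
  collapsed).
* **Fishing-ground analytics**: catch and CPUE (tonnes per net deployment)
  on a 0.5° grid, annual catch-weighted gravity centers, and Spearman rank
  correlations of CPUE with year, month, longitude and latitude.

A synthetic-data module generates LF tables, length–weight records and
logbooks with exactly the statistical structure these estimators assume, so
every stage is testable without the proprietary fishery logs.

## Worked example

Fit LBB to a simulated catch sample whose true parameters are known
(L∞ = 40 cm, Lc = 20 cm, α = 2 /cm, M/K = 1.5, F/K = 0.5, 5,000 fish):

```python
import lbstock as lb

scen = lb.PopulationScenario(linf_mean=40.0, linf_cv=0.02, lc=20.0, alpha=2.0,
                             m_over_k=1.5, f_over_k=0.5, n_fish=5000, seed=11)
table = lb.simulate_length_frequency(scen)
priors = lb.LBBPriors.from_table(table, mk_prior=1.5, fk_prior=0.5,
                                 alpha_prior=4.0, fk_cv=0.5, alpha_cv=0.5)
results = lb.LBBModel(table, priors).fit(seed=3)
print(results.summary())
```

prints

```
LBB fit (year 0)
  parameter        median   95% interval
  Linf (cm)         40.490   [40.028, 41.652]
  Lc (cm)           19.900   [19.800, 20.000]
  alpha (1/cm)       2.202   [1.985, 2.440]
  M/K                1.598   [1.046, 2.001]
  F/K                0.521   [0.195, 1.086]
  Z/K = 2.12, F/M = 0.33, E = 0.25
  Lopt = 26 cm, Lc-opt = 20 cm
  B/B0 = 0.65, Bmsy/B0 = 0.363, B/Bmsy = 1.8
  status: healthy
  acceptance 0.29, min ESS 455
```

Every generating parameter is inside its 95% interval; the derived biomass
ratio B/B₀ = 0.65 sits next to the analytic value 0.64 implied by the
generating parameters, and B/Bmsy > 1 with F/M < 1 classifies the simulated
stock as healthy — it is fished at about a third of its natural mortality.

The same workflow runs end-to-end from the shell:

```bash
lbstock simulate --years 2016:2021 --n-fish 4000 --seed 7 --out-prefix demo
lbstock report demo_config.yaml      # lw -> growth -> mortality -> lbb -> spatial
```

where the YAML config names the three CSV inputs, the ELEFAN search ranges,
the LBB priors/MCMC settings and an output directory; the pipeline writes a
full-precision `report.json` and a display-rounded `report.csv`, and the
same config + seed reproduces them byte-for-byte. Individual stages are
also available as subcommands (`lw`, `growth`, `mortality`, `lbb`,
`spatial`).

## Layout

```
src/lbstock/
  simulate.py       population scenarios and synthetic LF / LW / logbook data
  tables.py         LF-table and logbook containers + CSV readers/writers
  length_weight.py  allometric W = a L^b fit and growth-type classification
  growth.py         ELEFAN restructuring/scoring/grid search, VBGF helpers
  mortality.py      length-converted catch curve, empirical M, F and E
  lbb.py            LBB model, MCMC, reference points, indicators, status
  spatial.py        0.5-degree grid CPUE, gravity centers, rank correlations
  pipeline.py       config-driven end-to-end assessment report
  cli.py            `lbstock` command-line interface
docs/methods.md     model assumptions, numerical choices, limitations
```
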
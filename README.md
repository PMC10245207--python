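# noduletrade

Size–number trade-off analysis of *Termitomyces* fungal nodules in
fungus-growing termite nests.

Fungus-growing termites (Macrotermitinae: *Macrotermes*, *Odontotermes*,
*Ancistrotermes*, *Microtermes*) cultivate *Termitomyces* fungi inside
their nests. The fungus produces spherical **nodules** on the fungus
garden that the termites harvest as food. Two per-nest traits describe a
cultivar's provisioning strategy: the average nodule diameter *d* (mm)
and the nodule density *D* (count per gram of fresh fungus garden).
Across clades these trade off: cultivars of large termites make large,
sparse nodules; cultivars of small termites make small, numerous ones.

The core model is a one-parameter **isoquant** (constant-product)
production limit

```
L = V × D,     V = (4π/3) · (d/2)³
```

where *V* is the sphere volume of the average nodule diameter (mm³) and
*L* (mm³ g⁻¹) is the constant total nodule volume producible per gram of
garden. Treating density as the response, nonlinear least squares
minimises Σᵢ (Dᵢ − L/Vᵢ)², which has the closed form
L̂ = Σ(Dᵢ/Vᵢ) / Σ(1/Vᵢ²); the iterative fit is seeded at and verified
against it, and a brute-force grid search provides a third independent
estimate. Around the model sit: a seeded synthetic-survey generator with
known ground truth, per-nest/per-clade trait summaries with coefficients
of variation (CV), one-way ANOVAs (head width ~ genus, diameter and
density ~ clade) and log(n+1) Pearson correlations between farmer head
width and cultivar traits.

The package is aimed at ecologists analysing morphometric surveys of
farming symbioses, and at anyone needing a fully testable reference
implementation of a constant-product trade-off fit.

## Worked example

Simulate the default survey design — 43 nests across 4 genera, 7
cultivar clades, 50 nodule diameters and 3 minor-worker head widths per
nest — and run the full analysis:

```bash
noduletrade run --seed 7 --out-dir demo
```

prints (abridged):

```
Per-clade traits (CV in %):
  clade I: n=9, d=0.599 mm (CV 1.5%), D=265.0/g (CV 41.2%)
  clade III: n=6, d=1.602 mm (CV 5.3%), D=14.5/g (CV 45.9%)
  ...

Isoquant model  V x D = L
============================================
n (nests)                                 43
L_hat (mm^3/g)                       28.9577
se(L)                                1.76147
t                                      16.44
p (two-sided)                      6.623e-20

ANOVA head_width_by_genus: F(3,39) = 849.312, p = 1.51e-35
correlation head_width_vs_diameter: ... r = 0.9525, p = 8.643e-23, n = 43
correlation head_width_vs_density:  ... r = -0.8255, p = 9.657e-12, n = 43
```

Reading it: within each clade the per-nest mean diameter barely varies
(low CV — size is a stabilised trait) while density varies strongly
(high CV — number is plastic); the fitted production limit L̂ ≈ 29 mm³
per gram of garden is the constant product the nests scatter around
(the generator's true value here is 25.067); and head width correlates
positively with nodule size but negatively with nodule number — the
farmer–cultivar size-matching pattern. Stage tables
(`nest_traits.csv`, `clade_summary.csv`, `isoquant_fit.csv`,
`group_stats.csv`, `correlations.csv`), `report.json` and `summary.txt`
are written to `demo/`.

The same analysis is available as a library:

```python
import noduletrade as nt

survey = nt.simulate_survey(nt.default_config(seed=7))
traits = nt.nest_traits_table(survey.nodule_table, survey.nest_table)
res = nt.IsoquantModel.from_dataframe(traits).fit()
print(res.summary())
res.plot()  # volume-density scatter with the fitted isoquant curve
```

Subcommands `simulate`, `traits`, `fit-isoquant`, `stats`, `validate`
expose the individual stages; `noduletrade --help` lists flags
(`--response {density,volume,loglog}`, `--unit {nest,nodule}`,
`--strict-nodule-count`, ...).

## Survey configuration schema

`noduletrade simulate --config my_survey.yaml` accepts a YAML document:

```yaml
seed: 1234
production_limit_L: 25.067     # mm^3 per gram of garden
density_noise_sigma: 0.5       # sd of lognormal noise on density
nodules_per_nest: 50
workers_per_nest: 3
round_density: false
genera:
  - {name: Macrotermes, head_width_mean: 2.6, head_width_sd: 0.18, n_nests: 10}
clades:
  - {name: III, diameter_mean: 1.6, diameter_cv: 30.0}   # CV in percent
compatibility:                 # genus -> {clade: selection weight}
  Macrotermes: {III: 2.0, IV: 1.0}
```

Every genus needs at least one positively weighted clade; degenerate
mean/sd combinations (more than 1% of draws below the truncation
floor) are rejected.

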
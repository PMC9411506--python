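# fertghg

Full-chain greenhouse-gas accounting for synthetic nitrogen fertilisers:
from the factory gate, through transport, to direct and indirect soil
N₂O emissions — with empirical emission-factor estimation from
paired-plot field data and Monte Carlo uncertainty propagation.

The package is aimed at researchers and inventory analysts who want to
quantify the climate footprint of synthetic N fertiliser supply chains
at country, regional and global level, compare emission-factor choices
(IPCC Tier 1, IPCC wet/dry disaggregation, or empirical estimates), and
attach honest uncertainty to every number.

## The model

For each country *i*, six components are evaluated and summed:

```
GHG_i = GHG_M,i + GHG_T,i + GHG_D,i + GHG_V,i + GHG_L,i + GHG_U,i
```

* **Manufacturing** `GHG_M,i = Σ_j A_M,j,i × EF_M,j,k` — tonnes of each
  fertiliser product *j* times the factory-gate EF of the region of
  production *k* (t CO₂e per t product).
* **Transport** `GHG_T,i = Σ_j A_T,j,i × EF_T,j,k` — tonnage times the
  origin→destination transport EF, weighted by the sourcing mix.
* **Direct soil N₂O** `GHG_D,i = (A_D,i × EF_D) × 44/28 × GWP` — N
  applied times the direct emission factor, converted from N₂O–N to N₂O
  mass (×44/28) and to CO₂e with the N₂O 100-year GWP (265).
* **Indirect N₂O** from volatilisation/redeposition
  (`A × FRAC_GASF × EF₄`) and from leaching/runoff
  (`A × FRAC_LEACH × EF₅`), same conversion.
* **Urea hydrolysis** `GHG_U,i = (A_U,i × EF_U) × 44/12` —
  urea-equivalent product tonnage times the hydrolysis factor
  (0.2 ± 0.1 t CO₂–C per t urea), converted CO₂–C → CO₂.

Direct EFs can come from three schemes: the IPCC Tier 1 global default
(0.010, range 0.001–0.018), the IPCC wet/dry disaggregation (wet 0.016 ±
0.003, dry 0.005 ± 0.006), or empirical estimates computed from
paired-plot flux measurements:

```
EF_plot = (N₂O_treated − N₂O_control) / N_applied
```

aggregated to country means, plot-count-weighted regional means, and a
country-count-weighted global mean, with lognormal dispersion.

Uncertainty is propagated by Monte Carlo: 5,000 values are drawn per
emission factor (lognormal factors moment-matched on the natural scale,
bounds enforced by rejection), each draw shared across all countries
using that factor, and the full chain re-evaluated per draw. Results are
reported as mean, sd and coefficient of variation (CV) per component and
aggregation level.

Because the real manufacturing/transport EF tables are
licence-restricted and the activity snapshot is an external download,
the package ships a synthetic-world generator (`fertghg.synthetic`) that
produces structurally faithful stand-ins with known ground truth,
including paired-plot datasets whose generating EFs are recorded so
estimator recovery can be verified.

## Worked example

```
$ fertghg simulate --seed 1 --out bundle/
wrote synthetic bundle (8 files) to bundle

$ fertghg estimate-efs bundle/paired_plots.csv --out efs/
estimated EFs for 45 countries -> efs

$ fertghg account bundle/activity.csv --config bundle/config.yaml \
    --sourcing bundle/sourcing.csv --efs efs/ \
    --scheme empirical_country --out acct/
wrote 1 emissions table(s) to acct

$ fertghg mc bundle/activity.csv --config bundle/config.yaml \
    --sourcing bundle/sourcing.csv --efs efs/ \
    --scheme empirical_country --draws 5000 --seed 1 --out mc/
wrote Monte Carlo summary (5000 draws, seed 1) to mc/mc_summary.csv
```

On this seed the synthetic world consumes 100 Mt N and the empirical
global EF estimated from the 1,605 generated paired plots is 0.0076
(kg N₂O–N per kg N applied); the accounted world total is about
1,225 Mt CO₂e with a Monte Carlo CV of 6.5%. Per-country tables
(`acct/emissions_empirical_country.csv`) list the six components and
each country's share of the global total in Mt CO₂e; the MC summary
adds sd and CV per component and scope.

The same library surface is importable directly — see
`fertghg.efdirect`, `fertghg.engine`, `fertghg.montecarlo`,
`fertghg.indicators`.

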
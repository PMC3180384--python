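# cladediv

Diversification-dynamics analysis for ultrametric chronograms: did a clade
diversify at a constant rate, or did speciation slow down as diversity
accumulated?

The package bundles, as a tested library plus CLI, the statistical battery
used in comparative studies of island radiations (it was built around a
nine-clade comparative analysis of New Caledonian plants, lizards,
harvestmen, diving beetles and caddisflies):

* **γ statistic** — for a chronogram with branching times condensed into
  internode intervals g_k (the duration with exactly k lineages),
  T_i = Σ_{k=2..i} k·g_k and T = T_n,

      γ = [ (1/(n−2)) Σ_{i=2..n−1} T_i − T/2 ] / [ T √(1/(12(n−2))) ]

  Under constant-rate pure birth γ ~ N(0, 1); rate constancy is rejected
  one-tailed at α = 0.05 when γ < −1.645.  Negative γ means nodes
  concentrate early — a slowdown.
* **MCCR test** — when only n of a clade's N species are sampled, the γ
  null shifts left.  The Monte Carlo constant-rates test simulates
  pure-birth trees at the hypothetical full clade size (known species
  + 10% assumed undescribed), randomly prunes them to n tips, and takes
  the empirical 5% quantile γ_C as the corrected critical value.
* **Model fitting and ΔAIC** — maximum-likelihood fits of two
  rate-constant models (1-rate Yule; constant birth–death in r = λ−μ,
  a = μ/λ, via the Nee reconstructed-process likelihood conditioned on
  crown age and survival) and three rate-variable pure-birth models
  (2-rate Yule with a shift at age st; diversity-dependent linear
  λ_k = r1(1 − k/K); diversity-dependent exponential λ_k = r1·k^(−x)).
  ΔAIC = AIC(best rate-constant) − AIC(best rate-variable), with a
  parametric-bootstrap p-value from pruned pure-birth simulations.
  Time-varying birth–death models with exponentially decaying rates
  (SPVAR/EXVAR/BOTHVAR) are fitted alongside.
* **Simulators** — reconstructed trees under yule / birth–death /
  2-rate yule / DDL / DDX, plus a nine-clade synthetic fixture suite and
  LTT-curve export; everything the battery consumes can be generated
  synthetically.

## Worked example

Simulate a 38-tip clade under linear diversity dependence (r1 = 5, K = 40),
rescale to unit depth, and run the battery (38 of 40 species "sampled"):

```python
import cladediv as cd

tree = cd.simulate_tree(cd.SimConfig(model="ddl", n_tips=38, r1=5.0, K=40.0, seed=11))
tree = cd.scale_to_unit_depth(tree)
bt = cd.branching_times(tree)

g = cd.gamma_statistic(bt)
res = cd.mccr_test(g.gamma, n_sampled=38, known_total=40, reps=5000, seed=1)
sel = cd.select_models(bt)
p = cd.delta_aic_p(sel.delta_aic, 38, 40, reps=1000, seed=2)
```

which prints (via the obvious format strings):

```
gamma = -4.379  (one-tailed p = 0.0000)
MCCR:  gamma_C = -1.859  p = 0.0002  (full clade size 44, 5000 replicates)
  ddl    LH =   93.372  AIC =  -182.744
  ddx    LH =   93.225  AIC =  -182.451
  yule2  LH =   91.089  AIC =  -176.177
  yule1  LH =   81.696  AIC =  -161.391
  bd     LH =   81.696  AIC =  -159.391
delta AIC = 21.352
bootstrap p = 0.0020
```

Read: γ is far below the sampling-corrected critical value (slowdown), the
best rate-variable model is the linear diversity-dependent one (fitted
r̂1 = 5.64, K̂ = 39.2 against truth 5 and 40), and the ΔAIC of 21.4 is far
beyond anything constant-rate simulations produce (p ≈ 0.002).

The same battery runs from the shell over a config file of datasets:

```sh
cladediv fixtures --out-dir fixtures --seed 0     # nine synthetic clades
cladediv mccr --tree fixtures/Troglosironidae.nwk --known-total 13 --reps 5000 --seed 1
cladediv run --config battery.cfg --out-dir results   # Table-style TSV + LTT CSVs
```

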
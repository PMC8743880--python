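# domstrat

Tools for detecting **strategic, cost-dependent targeting of dominance
interactions** in animal social groups from observational winner/loser data.

## The problem

In group-living animals, individuals may aim their aggression at particular
group members — for instance at *close competitors*, the individuals ranked
immediately below themselves, who pose the greatest threat of a rank
reversal. Detecting such strategies from field data is treacherous for two
reasons:

1. **Circularity.** The same interactions would be used both to infer the
   dominance hierarchy and to measure who interacts with whom.
2. **Opportunity structure.** Groups fragment into temporary subgroups
   (fission–fusion), and if individuals assort spatially by rank, close-in-
   rank dyads interact more often simply because they meet more often —
   mimicking a close-competitor strategy.

`domstrat` addresses both. The data are randomly split: one part (default
30%) infers the hierarchy by **randomized Elo** (Elo scores averaged over
many random replay orders of the interaction stream), the other part measures
interaction rates. Opportunity is controlled by a **datastream permutation
null**: recipients are repeatedly re-drawn uniformly among the individuals
*actually present* when each interaction took place. The resulting statistic
for each directed dyad (a → b) is the **tendency to interact**,

    T(a, b) = observed count(a → b) − permuted count(a → b),

which is zero when a targets b exactly as often as co-presence alone
predicts. Tendencies are modelled against the signed hierarchy difference
`R = rank(a) − rank(b)` (negative when the actor outranks the recipient) with
cubic smoothing splines, fitted *separately* below and above zero so a signal
at R = −1 is not shrunk through the origin. The whole chain — split, rank,
count, permute, smooth — is repeated many times (default 500) with fresh
random splits; the pointwise median and 2.5–97.5 percentile band of the
spline predictions summarize the strategy, and a grid point whose 95% range
excludes zero marks significantly non-random targeting.

To compare interaction *types*, the package also allocates higher- versus
lower-cost aggression across rank differences with **Bayes' rule**,

    P(A_h | R) = P(R | A_h) · P(A_h) / P(R),

with percentile-bootstrap confidence intervals and the baseline share
P(A_h) as reference.

Finally, an **agent-based simulator** generates ground-truth data: N
individuals with fixed latent ranks meet in X subgroups of mean size G
(random or rank-assorted membership), and in each subgroup one dyadic contest
is decided with dominant-win probability

    P_win = 1 − (1 − P_w)^{r_d},

where P_w is the dominant's win probability at rank difference 1 and r_d the
absolute rank difference. The simulator validates the pipeline: rank
assortment inflates raw close-in-rank counts, yet the permutation-corrected
band must stay flat; an injected recipient preference must be recovered at
the right rank difference.

## Worked example

```python
import domstrat as d

# rank-assorted subgrouping, NO strategy: the hard null case
ds = d.simulate_dataset(d.ABMConfig(n_individuals=20, n_subgroups=100,
                                    mean_size=5, p_win=0.9,
                                    assorted=True, seed=1))
band = d.run_strategy_analysis(
    ds, n_iterations=100,
    perm_config=d.PermutationConfig(n_permutations=1000),
    elo_config=d.EloConfig(n_orderings=500), rng=1)
print(sum(s != "ns" for s in band.significance))   # -> 0
print(band.to_dataframe().query("difference in [-2,-1,1]").round(3))
```

```
 difference  median     lo    hi significance  extrapolation_share
       -2.0   0.010 -0.090 0.121           ns                  0.0
       -1.0   0.004 -0.124 0.141           ns                  0.0
        1.0   0.003 -0.151 0.119           ns                  0.0
```

Despite close-in-rank dyads co-occurring (and hence interacting) far more
often under assortment, the 95% band overlaps zero at every rank difference:
no spurious strategy is inferred. Injecting a true close-competitor
preference (every initiator targets the member one rank below, when present)
flips the picture:

```python
ds2 = d.simulate_dataset(d.ABMConfig(n_subgroups=700, strategy={-1: 1.0},
                                     seed=1))
band2 = d.run_strategy_analysis(
    ds2, n_iterations=100, perm_config=d.PermutationConfig(1000),
    elo_config=d.EloConfig(n_orderings=500), rng=1)
```

```
 difference  median     lo    hi significance
       -3.0   0.766  0.503 1.021        above
       -2.0   0.873  0.551 1.240        above
       -1.0   0.995  0.576 1.456        above
        1.0  -0.283 -0.575 0.107           ns
```

The excess tendency peaks at rank difference −1 and its 95% range sits
entirely above zero there: the injected strategy is recovered.

A command-line interface mirrors the library:

```bash
domstrat simulate --n 20 --subgroups 100 --mean-size 5 --pw 0.9 \
         --assorted --seed 1 --out sim.csv
domstrat rank     --input sim.csv --out hierarchy.csv
domstrat strategy --input sim.csv --iterations 500 --permutations 100000 \
         --seed 1 --out band.csv
domstrat bayes    --input data.csv --out cost_allocation.csv
domstrat run      --config run.yaml       # full pipeline + manifest
```

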
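# telesna

Robustness analysis of animal social networks inferred from GPS telemetry.

Researchers routinely tag a fraction of a wild population with GPS collars,
declare two animals "associated" when their fixes fall within *s* metres and
*t* minutes of each other, and compute network metrics from the result. Every
number obtained this way depends on an incomplete, noisy sample of the
population. `telesna` builds the association network and then answers the
question that matters before any ecological interpretation: **which of these
network metrics can be trusted at this sampling effort?**

## The model

**Edges.** For every dyad, fixes within *t* minutes are matched one-to-one
(greedily by smallest time gap) into *joint observations*. The edge weight is
a modified Simple Ratio Index whose denominator counts only events where both
animals were observed near-simultaneously:

```
SRI_AB = x_AB / (x_AB + y_AB)
```

where `x_AB` is the number of joint observations within *s* metres and
`y_AB` the number farther apart. `SRI = 0` means never observed together,
`1` always together. Nodes are all tagged animals (isolates kept).

**Five-step robustness protocol** on the resulting weighted graph:

1. **Datastream permutation.** Each animal's daily tracks are shuffled across
   its own observed dates, preserving home ranges and movement
   autocorrelation while randomising contacts; global metrics of 1000
   permuted networks give a null distribution and add-one-corrected
   empirical p-values.
2. **Node subsampling.** Induced subnetworks on 10–90% of nodes show the
   bias of each global metric under reduced tagging (density is unbiased;
   mean strength shrinks by (m−1)/(N−1)); the same subsampling of permuted
   networks shows the minimum effort at which the data separate from random.
3. **Node bootstrap.** N nodes resampled with replacement; edges between
   copies of distinct originals are kept, copy-pairs of the same original
   get an edge drawn from the original edge list. Percentile intervals give
   CIs for global metrics, CI width is tracked against sample size (with
   mean strength and diameter scaled by N), and a split-half calibration
   check confirms the bootstrap does not manufacture significance.
4. **Node-metric stability.** Node metrics of induced subnetworks are
   correlated (and regressed) against the same nodes' full-network values;
   metrics holding r > 0.7 at low tagging levels are safe to interpret.
5. **Node-level CIs.** The bootstrap of step 3 applied per node, with the
   value of a node in a replicate averaged over its copies.

A synthetic-data module simulates multi-group fission–fusion herds
(daily parties, per-animal gregariousness, between-group forays) with known
ground truth, so the whole protocol is testable without field data.

## Worked example

```python
import numpy as np
import telesna as t

# a 15-animal, 3-group herd tracked for 30 days at 2-h fixes
ds, truth = t.simulate_population(t.SimulationConfig(seed=1))

net = t.build_network(ds, t.Thresholds(s=15, t=7))
print(t.global_metrics(net, {"density", "mean_strength", "transitivity", "diameter"}))
# {'density': 0.4095, 'diameter': 3, 'mean_strength': 0.2385, 'transitivity': 0.543}

null = t.null_distribution(ds, t.Thresholds(), {"mean_strength"},
                           n_perm=200, rng=np.random.default_rng(1))["mean_strength"]
print(f"observed {null.observed:.4f}  null q95 {null.quantile(0.95):.4f}  p {null.p_upper:.4f}")
# observed 0.2385  null q95 0.0156  p 0.0050
```

The observed mean strength (0.2385) sits far above the 95th percentile of
the permuted-stream null (0.0156): the network captures genuine social
structure rather than incidental co-occurrence (p ≈ 0.005 with 200
permutations, the smallest value 1/(n+1)-corrected p-values allow is 1/201).

The same analysis from a shell:

```sh
telesna simulate --n-individuals 15 --n-groups 3 --seed 1 --out herd.csv
telesna run-all herd.csv --seed 1 --out-dir report/
```

`report/` then contains the network (GraphML + edge list), tidy CSVs and
figures for every step, and a `manifest.json` from which the run is exactly
reproducible. `run-all` on a prebuilt network (`--input-format graphml`)
skips step 1, which only applies to raw telemetry.

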
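# signedcomm

Stability analysis of communities in **signed social networks** — graphs
whose edges carry a sign: friendship (+1) or enmity (−1). The package is
aimed at researchers working with sociometric survey data (e.g. school
friendship/enmity nominations) or any signed relational data where
community structure found on the positive ties must be confronted with the
negative ties that perturb it.

## What it computes

Starting from a **directed** signed network of nominations, the pipeline:

1. **Censuses** ties into best friend / friend / worst enemy / enemy by
   reciprocity and sign, and computes the Dunbar layer ratio
   (one-way / reciprocal counts, ≈ 3 in empirical friendship data).
2. **Completes missing enmities** by structural balance: a one-way negative
   arc *i → j* is upgraded to a reciprocal enmity when, among the triads it
   would close with common reciprocal neighbours, balanced triads
   (sign product +1) hold a strict majority.
3. **Projects** to the undirected reciprocal network and extracts the
   positive subnetwork.
4. **Detects communities** by modularity maximization

   $$Q^{+} = \frac{1}{2w^{+}} \sum_{ij}\Big(w^{+}_{ij} - \gamma\,\frac{k_i k_j}{2w^{+}}\Big)\,\delta(C_i,C_j)$$

   with the deterministic leading-eigenvector method (recursive spectral
   bisection with Kernighan–Lin fine-tuning) and seeded Louvain with
   resolution calibration by run-to-run NMI.
5. **Builds signed communities** (negative edges laid back on the
   partition) and quantifies perturbation:
   - $Q^{-}$: modularity of the partition on the negative subnetwork;
   - $Q^{s} = \dfrac{2w^{+}Q^{+} - 2w^{-}Q^{-}}{2w^{+}+2w^{-}}$ (signed modularity);
   - frustration $F$ = negative-intra + positive-inter edges, normalized by
     $w^{+}+w^{-}$;
   - CSB = balanced / total within-community triangles (strong balance:
     $(-,-,-)$ is unbalanced);
   - $\mathrm{PPC} = 100\,(Q^{+}-Q^{s})/Q^{+}$, mapped to
     stable / semi-stable / unstable classes;
   - negative hubs: nodes with many enmities inside their own community.
6. **Fits** an exponential $e^{-x/\lambda}$ to the community-size CCDF.

A synthetic-data module generates survey-style networks with planted
blocks, tunable reciprocity, censored enmities and injected hubs, with
closed-form expected counts for every statistic (`expected_counts`), plus
regimes matching nine published school networks (`table2_regime`).

## Worked example

```python
import signedcomm as sc

params = sc.table2_regime("esSC", seed=9)      # 108-node elementary regime
net, truth = sc.generate(params)
report = sc.run_pipeline(sc.AnalysisConfig(method="newman"), network=net)

s = report.degree_summary
m = report.metrics
print(f"<k>+ = {s.mean_pos_degree}, <k>- = {s.mean_neg_degree}, "
      f"neg share = {s.neg_fraction_pct}%")
print(f"K = {report.partition.K} communities")
print(f"Q+ = {m.q_pos:.3f}  Qs = {m.q_signed:.3f}  PPC = {m.ppc_pct:.1f}%  "
      f"F = {m.frustration_norm:.3f}  CSB = {m.csb:.2f} -> {m.stability_class}")
```

prints

```
<k>+ = 5.6, <k>- = 1.9, neg share = 25.7%
K = 11 communities
Q+ = 0.907  Qs = 0.576  PPC = 36.5%  F = 0.122  CSB = 0.68 -> unstable
```

Read: each student averages 5.6 reciprocal friendships and 1.9 reciprocal
enmities; the positive subnetwork splits into 11 communities with very
high modularity, but enmities inside them erase 36% of that modularity
(PPC), only 60% of within-community triangles are balanced, and the
partition is classified *unstable* — the elementary-school pattern, where
many enmities sit inside the friendship communities.

The same analysis is scriptable from a shell:

```bash
signedcomm simulate --regime esSC --seed 9 --out net.csv
signedcomm run --config cfg.yaml
signedcomm calibrate --input net.csv --gamma-grid 0.5:2.0:0.25 --runs 300
```

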
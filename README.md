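# scnet — structural covariance networks from regional cortical thickness

`scnet` analyzes the topology of **structural covariance networks**: graphs
whose 68 nodes are cortical regions (Desikan–Killiany parcellation) and whose
edges reflect the across-subject correlation of regional mean cortical
thickness. It is aimed at researchers comparing two groups — e.g. a clinical
cohort such as children with ADHD against typically-developing controls —
who have a per-subject table of regional thickness values and want the full
chain from that table to group-level network statistics:

1. **Nuisance removal.** Each region's thickness is residualized by OLS on
   mean overall cortical thickness, age, and IQ; residuals replace raw values
   everywhere downstream. A per-region two-group ANOVA on the residuals
   provides the regional thinning table.
2. **Network construction.** Per group, the Pearson correlation matrix of
   residuals over all region pairs is binarized at a **network cost**

   $$C_G = \frac{K}{N(N-1)/2},$$

   keeping the `K = round(cost · N(N−1)/2)` pairs with the largest |r|; the
   analysis sweeps costs 0.05–0.4 in steps of 0.005.
3. **Efficiency metrics.** On each binary graph, from hop-count shortest
   paths $L_{ij}$:

   $$E_{glob}(G) = \frac{1}{N(N-1)}\sum_{i \ne j} \frac{1}{L_{ij}}, \qquad
     E_{loc}(G) = \frac{1}{N}\sum_{i} E(G_i), \qquad
     E_{nodal}(G,i) = \frac{1}{N-1}\sum_{j \ne i} \frac{1}{L_{ij}},$$

   where $G_i$ is the subgraph induced on node *i*'s neighbors and
   disconnected pairs contribute $1/L = 0$. Each graph is compared with
   matched regular (ring-lattice) and random ($G(N,K)$) references with the
   same node and edge counts; *G* is small-world when
   $E_{loc}(G_{rand}) < E_{loc}(G) < E_{loc}(G_{reg})$ and
   $E_{glob}(G_{reg}) < E_{glob}(G) < E_{glob}(G_{rand})$.
4. **Inference.** Because each group yields a single network, group
   differences are tested by permuting subject labels (default 5000
   permutations, one-tailed at the 95th percentile, Monte-Carlo-corrected
   $p \ge 1/(n_{perm}+1)$): globally/locally at every cost, and per node at a
   comparison cost (default 0.095). Pairwise correlation differences are
   screened with the Fisher r-to-z statistic
   $Z = (\mathrm{atanh}\,r_1 - \mathrm{atanh}\,r_2)/\sqrt{1/(n_1-3)+1/(n_2-3)}$
   plus a permutation p and Benjamini–Hochberg FDR over all 2278 pairs, and
   regional thickness is related to symptom severity (ADHD index) by Spearman
   correlation.

A **synthetic cohort generator** with known ground truth (planted small-world
correlation topology, group mean shifts, group-specific edge correlations,
age/IQ effects) makes every stage testable without any imaging data.

## Worked example

The packaged demo generates a 40+40-subject synthetic cohort with planted
cortical thinning (entorhinal.L −0.16 mm, superiorfrontal.R −0.10 mm), one
altered correlation pair, and a case-group covariance shifted toward a
lattice topology, then runs the full analysis:

```bash
scnet demo --out demo_out --fast --seed 11
```

`demo_out/summary.txt` (about a minute with `--fast`, i.e. 500 permutations):

```
Structural Covariance Network Analysis
======================================================
Subjects: 80 (case: 40, control: 40); regions: 68
Cost grid: 0.050-0.390 (18 points); comparison cost 0.095; permutations: 500; seed: 11

Regional thickness ANOVA (residualized, df=(1,78)): 5/68 regions with p < 0.05
  entorhinal.L                 F= 19.519  p=0.0000  2.6459 vs 2.7765
  superiorfrontal.R            F=  5.667  p=0.0197  2.7309 vs 2.8103
  ...

Efficiency at cost 0.095 (500 permutations):
  E_glob: diff(case-control) = -0.0103, 95% null band [-0.0174, +0.0208], one-tailed (less) p = 0.1317
  E_loc: diff(case-control) = +0.1612, 95% null band [-0.1282, +0.1239], one-tailed (greater) p = 0.0060
```

Both planted thinning regions top the ANOVA table, and the lattice-shifted
case covariance shows the expected signature — lower global efficiency
(less integrated) and significantly higher local efficiency (more
lattice-like) than controls. The run directory also contains every result
table as CSV, efficiency-versus-cost figures with permutation bands, a
nodal forest plot, a machine-readable `summary.json`, and a
`provenance.json` that reproduces the run exactly.

The same analysis runs on your own data from a tidy CSV (columns
`subject_id, group, age, iq, adhd_index`, then one column per region):

```python
from scnet import StructuralCovarianceModel

model = StructuralCovarianceModel.from_csv("thickness.csv", case_label="patient")
results = model.fit(n_permutations=5000, seed=0)
print(results.summary())
results.anova_table          # regional group comparison (mm scale)
results.curves.table         # efficiency vs cost with null bands
results.edge_table           # Fisher-z pairwise screen with BH q
```

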
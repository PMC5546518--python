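# Methods

This note records the statistical model, the synthetic-data design, the
numerical conventions, and the open design choices behind `scnet`.

## The analysis model and its assumptions

A structural covariance network is a group-level construct: with one
thickness value per subject and region, the edge weight between regions
*i* and *j* is the Pearson correlation of their residualized thickness
across the subjects of one group. Consequences that shape everything
else:

- **One network per group.** There is no subject-level network, so group
  comparisons of network metrics have no parametric sampling
  distribution; inference is by relabeling subjects (permutation).
- **Residualization before correlation.** Each region is OLS-residualized
  on an intercept, mean overall cortical thickness (unweighted mean of
  the 68 regional values when not supplied), age, and IQ. The regression
  is fit on all subjects pooled, once, and held fixed inside permutation
  loops: the fit does not depend on group labels, which keeps the
  permutation null exact. A per-group fit is available
  (`residualize(..., pooled=False)`) but is not the default.
- **Binarization by cost.** Thresholding at cost `c` keeps
  `K = round(c · N(N−1)/2)` edges (round-half-up; the realized cost is
  recorded on the graph). Edges are ranked by |r| — sign is not used,
  which is the standard convention in thickness-covariance work — with
  lexicographic (i, j) tie-breaking so graphs are deterministic.
- **Efficiency conventions.** Shortest paths are hop counts; a
  disconnected pair contributes 1/L = 0, and a neighborhood subgraph
  with fewer than two nodes contributes 0 to local efficiency. These
  conventions keep all three efficiency measures defined on the
  fragmented graphs that low costs produce. Global efficiency equals the
  mean of the nodal efficiencies by construction (an identity the tests
  verify to 1e-12 against brute-force enumeration).
- **Matched references.** The regular reference is a deterministic ring
  lattice filled shell by shell to exactly K edges; the random reference
  is uniform G(N, K), averaged over 20 realizations by default (the
  count is configurable and every seed is recorded). Only N and K are
  matched — no degree-sequence preservation.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| cost grid | 0.05–0.4, step 0.005 | sweep over sparse, estimable graphs |
| comparison cost | 0.095 | single cost for the global/local/nodal tests (K = 216 at N = 68) |
| n_permutations | 5000 | label permutations per test |
| random realizations | 20 | G(N,K) draws averaged per reference value |
| q level | 0.05 | Benjamini–Hochberg FDR level for the edge screen |
| tails | E_glob: less, E_loc: greater, E_nodal: auto | one-tailed directions per the study hypotheses (configurable, always recorded) |

Permutation p-values use the +1 Monte-Carlo correction,
p ≥ 1/(n_perm+1), and the 95% band of the null is reported as the
2.5/97.5 order statistics of the permuted differences. In exact
(enumerated) mode the p is the plain fraction of relabelings, identity
included, at least as extreme as the observed difference.

## The synthetic cohort generator

The generator emulates a two-group pediatric design: 40 subjects per
group, 68 Desikan–Killiany regions, baseline thickness 2.8 mm,
between-subject SD 0.15 mm, ages uniform on 9–15 years, IQ uniform on
85–135, and mild shared covariate effects (−0.02 mm/year of age,
+0.0005 mm/IQ point). Age and IQ are independent of group by default so
covariate and network effects stay separable in tests. Regional vectors
are multivariate normal around the group mean; the ground-truth
correlation matrix is identity plus `within_edge_correlation` on the
edges of a planted graph (ring lattice with per-edge rewiring), with
per-pair overrides (`altered_edges`) and, optionally, a group-specific
rewiring probability (`case_rewiring`) that shifts the case covariance
toward a lattice organization.

Positive definiteness is enforced by eigenvalue clipping at 1e-6
followed by rescaling to unit diagonal; whether a repair occurred and
the largest resulting deviation from a target entry are recorded, and a
deviation above 0.1 is a hard error naming the offending edges. This
repair bounds how strong the planted correlations can be: on the default
small-world topology, 0.35 is about the strongest edge correlation whose
repair distortion stays near 0.05, which is why it is the default (an
iterated alternating-projection repair was evaluated and reduces the
distortion only marginally; the simple clip was kept).

What the generator does **not** emulate: spatially structured
covariance (homotopic or distance-dependent correlations), non-Gaussian
or heteroscedastic thickness distributions, site/scanner effects,
missing data, or any relationship between network topology and the
symptom score (the symptom index is drawn independently of thickness,
with different group means). Multivariate normality is an assumption of
the generator, not a claim about real cortical thickness. Passing tests
therefore demonstrate correctness and calibration of the *pipeline*, not
robustness to real-data pathologies.

### The lattice-shift study condition

Several tests and the acceptance script use a cohort whose case-group
covariance is shifted toward a lattice: backbone ring lattice with 4
neighbors per side (272 edges), edge correlation 0.32, control topology
rewired with probability 0.4, case topology the pure lattice, n = 40 per
group, evaluated at cost 0.095. This condition was fixed by a design
calibration: at n = 40 the correlation estimates are noisy enough that
spurious edges act as shortcuts and dilute the lattice/random contrast,
so the shift must be large (pure lattice vs 40% rewiring) and the
backbone dense enough (272 true edges vs 216 retained) for the direction
of effect — lower global, higher local efficiency in the case group —
to be recovered in the large majority of cohorts. The recovery rate at
this condition is about 0.8–0.9 over independent seed blocks.

## Numerical and degenerate-input choices

- Zero-variance regions in a correlation matrix get zero correlations
  with a warning (they carry no covariance signal) rather than NaN.
- A region where both groups have zero residual variance reports
  F = +inf rather than raising.
- The group-comparison table reports means on the mm scale (residual
  means plus the raw regional grand mean) so it reads like a thickness
  table; with equal group sizes its F is exactly the squared pooled t,
  and is exactly reconstructible from the printed means and SEMs via
  `f_from_group_summary`.
- Degrees of freedom are reported as (1, n1+n2−2); published tables of
  this design sometimes print the total sample size as the error df, and
  the table metadata notes the convention used here.
- The covariate design tolerates exact collinearity among non-constant
  covariates (the least-squares projection, hence the residuals, remain
  unique); a constant covariate is a named hard error. This matters
  because mean overall thickness is exactly collinear with the other
  covariates in some synthetic edge cases.
- Fisher's transform is undefined at |r| = 1 and is a hard error in the
  scalar API; inside the permutation edge screen, correlations are
  clipped at 1 − 1e-15 to keep vectorized nulls finite.

## Known limitations

- The Fisher Z difference for a planted r = 0.7 vs 0.3 at n = 40/40 has
  expectation ≈ 2.4 with unit spread, while the maximum |Z| over the
  2277 null pairs of a 68-region screen is typically ≈ 3.5; a single
  such planted difference is therefore rarely the top-ranked pair, even
  though it sits around the 90th percentile on average and is the kind
  of effect the permutation + FDR machinery is designed to screen, not
  to single out. Detecting individual edges reliably at this effect size
  requires either stronger differences or larger samples.
- Published tables of this kind of screen sometimes print Z scores on a
  different (larger) scale than the standard Fisher formula; `scnet`
  reports the standard formula and the permutation p only.
- Efficiency curves with full defaults (71 costs × 5000 permutations)
  are expensive; the `--fast` pipeline mode (500 permutations, 5 random
  realizations) exists for quick runs, and the test suite and acceptance
  script use reduced problem sizes (e.g. 120–500 permutations, 25–200
  cohorts) chosen to keep the Monte-Carlo error of each check well below
  its decision margin.
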
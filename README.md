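# mccnet

Network analysis of **regional multiple chronic conditions (MCC)**: which
noncommunicable diseases rise and fall together across US counties, which
risk factors drive them, and which diseases sit at the core of, or bridge
between, comorbidity patterns.

The package is aimed at population-health researchers working with
county-level surveillance tables (CDC PLACES / SVI style): one table of
age-adjusted disease prevalence (%) per county, one table of risk-factor
percentages per county.

## The model

Given prevalence columns for diseases *D* and factor columns *U* over the
same counties:

1. **Monomodal disease network** `G = (D, E_DD)`. Every disease pair is
   tested with a Pearson correlation (two-sided t test, n−2 df); pairs with
   `p < 0.05` become edges with adjacency `a_ij = r_ij`. Edge weight is
   `|r|`; the sign is kept as an attribute.
2. **Bipartite disease–factor network** `F = (D, U, E_DU)`. Each disease is
   regressed on all factors at once (OLS, both sides z-scored, classical
   standard errors); significant standardized coefficients become edges with
   weight `|β|`.
3. **Integrated MCC network**: the union of both graphs. Correlation and
   standardized-beta weights are both unitless effect sizes on a comparable
   scale and are mixed unchanged.
4. **Overlapping communities (MCC patterns)** by local fitness maximization:
   a community grows from a random uncovered seed by greedily adding the
   neighbor with the largest gain in fitness
   `f_G = k_in / (k_in + k_out)^α`
   (weighted internal/boundary degree; α controls community size), ejecting
   members whose removal raises fitness, until no neighbor improves it.
   Covers repeat until every node is assigned; communities with overlap
   similarity `S(G1,G2) = |G1∩G2| / min(|G1|,|G2|) > β` are merged.
5. **Node importance and disease roles**: strength `D_i = Σ_j A_ij` and
   influence `NI_i = Σ_j A_ij / D_j` (neighbor-normalized; a literal product
   variant is available). Diseases in ≥2 communities are **bridge**; the
   top-3 remaining by influence are **core**; the rest **general**.

## Worked example

Simulate a study-scale dataset (3,143 counties, 12 diseases in 4 planted
correlation blocks, 10 risk factors) and analyze it:

```sh
$ mccnet simulate --n-counties 3143 --seed 11 --out sim
wrote 3143 counties x (12 diseases + 10 factors) to sim (clip fraction 0.110%)

$ mccnet run --prevalence sim/prevalence.csv --factors sim/risk_factors.csv \
             --seed 11 --out out
analyzed 3143 counties: 63 disease edges, 37 disease-factor edges, 4 communities -> out
  core: chd, diabetes, hypertension
  bridge: -
  general: arthritis, asthma, cancer, ckd, copd, depression, high_cholesterol, obesity, stroke
```

63 of the 66 disease pairs were significantly correlated at n = 3,143 (even
the weak 0.05 background correlation is detectable at this sample size);
37 disease–factor coefficients were significant. The four detected
communities recover the four planted blocks together with their acting
factors — `out/communities.json` lists, for example, a 5-disease/4-factor
community with fitness 0.725, and a singleton community holding the one
factor with no planted effects (isolated nodes are retained, with fitness
0). `out/metrics.tsv` begins

```
node          node_class  strength  influence  degree
diabetes      disease     3.632     1.170      11
hypertension  disease     3.612     1.162      11
ckd           disease     3.486     1.085       9
```

i.e. the cardiometabolic block carries the strongest nodes, and influence
lands in the ~0.4–1.2 range typical of the quotient normalization. All
outputs (edge lists, GraphML, communities, metrics, roles, and a manifest
with config, seed and input hashes) land in `--out`.

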
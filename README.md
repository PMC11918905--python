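# panelwarp

Dynamic-time-warping (DTW) symptom networks from **sparse longitudinal
panel data** — the kind of cohort where depression, anxiety, and worry
questionnaires (30 IDS + 21 BAI + 11 PSWQ items = 62 items) are
administered only 4–5 times over many years, far too sparsely for
vector-autoregressive or cross-sectional network models.

The package is for psychiatric epidemiologists and methodologists who want
to quantify how *similarly pairs of symptoms move over time within a
person*, aggregate that into group-level symptom networks, and relate
overall network density to diagnostic subgroup (controls / anxiety-only /
depression-only / comorbid) and to the (in)stability of disease states
over follow-up.

## The method

For one participant, each item is a short series of group-level
standardized scores over their complete assessment waves. For every
unordered item pair the DTW distance is computed with the **symmetric2**
step pattern under a **Sakoe-Chiba band of width 1** (warping never
crosses more than one assessment):

```
D(i, j) = min( D(i−1, j)   +     c(i, j),
               D(i−1, j−1) + 2 · c(i, j),
               D(i,   j−1) +     c(i, j) ),    |i − j| ≤ 1,
```

with local cost `c(i, j) = |a_i − b_j|` and `D(1, 1) = 2·c(1, 1)`. The
cumulative cost divided by `T_a + T_b` gives a **normalized distance**
that is comparable between participants with 4 and 5 waves. Each
participant yields `(62² − 62)/2 = 1,891` distances.

Downstream statistics:

- **Edges** — a pair is connected when its mean distance across
  participants is significantly *smaller* than that of all remaining
  pairs (one-sided, default α = 10⁻⁴), in a model that adjusts for the
  pair's mean raw score (low-and-flat item pairs give trivially small
  distances) with participant intercepts.
- **Centrality** — mean inverted distance of an item to its connected
  neighbours; node size in plots.
- **Network density** — a participant's mean inverted distance over all
  1,891 pairs; group means are adjusted for mean symptom severity, age,
  sex, and education.
- **Disease-state stability** — the count (0–5) of diagnostic assessments
  with an active anxiety and/or depressive diagnosis; adjusted density is
  regressed on this score with linear + quadratic terms (a negative
  quadratic coefficient = density peaks in the *unstable* mid-range).

Because real cohorts of this kind are access-restricted, the package
ships a **synthetic cohort generator** with a latent-factor model (mood,
cognitive anxiety, somatic arousal, worry, sleep) whose per-subgroup
factor coupling is known ground truth, so the whole pipeline is testable
end-to-end.

## Worked example

```python
from panelwarp import (GeneratorConfig, generate, standardize,
                       cohort_distances, network_density, stability_profiles)
from panelwarp.network import test_edges, centrality

cohort, truth = generate(GeneratorConfig(seed=1))
panel = standardize(cohort)
table = cohort_distances(panel)                     # 550 × 1,891 distances
edges = test_edges(table, alpha=1e-4)
cents = centrality(table, edges)
grouping = stability_profiles(cohort)["subgroup"]
estimates, comparisons, dens = network_density(table, cohort.covariates, grouping)
```

With seed 1 this prints (via the obvious `print` statements):

```
participants: 550, items: 62
distances: 1040050 rows (1891 pairs/participant)
significant edges: 414/1891 (21.9%)
top centrality: PSWQ06 (2.92), PSWQ11 (2.92), PSWQ08 (2.91)
  control    adjusted density 2.489 (SE 0.009, n=120)
  AD_only    adjusted density 2.507 (SE 0.011, n=53)
  MDD_only   adjusted density 2.507 (SE 0.009, n=88)
  comorbid   adjusted density 2.544 (SE 0.005, n=289)
```

Reading this: the 414 significant edges are exactly the within-factor
pairs of the generating model (perfect structure recovery at this effect
size); worry (PSWQ) items are the most central, mirroring their strongest
within-factor coupling; and the adjusted densities reproduce the
generating coupling order — controls loosest, comorbid densest, the two
mono-diagnosis groups in between and nearly tied.

The same pipeline runs from the shell:

```sh
panelwarp simulate --seed 1 --out data/
panelwarp run --out results/        # simulate → distances → networks → density
panelwarp dtw 0,0,0 1,1,1           # inspect one alignment step by step
```

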
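# assemblage

Null-model analysis of microbial community assembly for 16S/OTU count
data — βNTI, abundance-weighted Raup–Crick (RC<sub>bray</sub>), five-way
assembly-process partitioning, the supporting diversity statistics, and
a synthetic metacommunity generator with known ground truth.

It is aimed at microbial ecologists working with community time series
(groundwater wells, sediments, bioreactors, host-associated samples)
who want to ask: *is the turnover between these two communities driven
by selection, dispersal, or drift?* — and to verify that the machinery
answering that question actually works, without needing anyone's raw
data.

## The method

For a pair of communities *A* and *B* with a phylogeny of their taxa:

1. **Phylogenetic turnover.** The abundance-weighted β-mean nearest
   taxon distance,

   βMNTD = ½ [ Σ<sub>i∈A</sub> p<sub>iA</sub> min<sub>j∈B</sub> d(i,j)
             + Σ<sub>j∈B</sub> p<sub>jB</sub> min<sub>i∈A</sub> d(i,j) ],

   where d is patristic distance and p relative abundance, is compared
   against a null built by shuffling taxon labels across the whole
   distance matrix. The standardised deviation is the **β-nearest taxon
   index**: βNTI = (βMNTD<sub>obs</sub> − μ<sub>null</sub>) / σ<sub>null</sub>.
   |βNTI| > 2 indicates deterministic selection (βNTI > 2 variable
   selection, βNTI < −2 homogeneous selection). The within-sample
   analogue gives the NTI (sign-flipped so clustering is positive).

2. **Compositional turnover under a probabilistic-assembly null.** For
   pairs with |βNTI| ≤ 2, each community is rebuilt many times from the
   regional pool: draw its observed richness with probability ∝
   occurrence frequency, then fill to its observed total with
   probability ∝ mean relative abundance. The observed Bray–Curtis
   dissimilarity is ranked in this null and rescaled to
   **RC<sub>bray</sub>** ∈ [−1, 1]. RC<sub>bray</sub> > 0.95 indicates
   dispersal limitation, RC<sub>bray</sub> < −0.95 homogenizing
   dispersal, anything else **undominated** assembly.

The per-pair decision rule (strict inequalities):

| result | process |
|---|---|
| βNTI > 2 | variable selection |
| βNTI < −2 | homogeneous selection |
| \|βNTI\| < 2 and RC<sub>bray</sub> > 0.95 | dispersal limitation |
| \|βNTI\| < 2 and RC<sub>bray</sub> < −0.95 | homogenizing dispersal |
| \|βNTI\| < 2 and \|RC<sub>bray</sub>\| < 0.95 | undominated |

Process fractions are tallied over sample groupings (all pairs,
within-well time series, between wells, or pH categories). Supporting
statistics — Bray–Curtis matrices, richness, Pielou's J = H/ln S,
Mantel tests against environmental differences, the phylogenetic-signal
Mantel correlogram on per-taxon niche values, and a sequential
(vegan-`adonis2`-style) PERMANOVA — live in `assemblage.stats`.

Because real deployments can rarely be validated end to end,
`assemblage.simulate` generates metacommunities whose true assembly
process is known: Brownian niche traits on a simulated phylogeny,
lognormal regional pools, and local communities assembled under
configurable environmental filtering, migration, and Wright–Fisher
drift. Each of the five scenario presets is recovered by the full
pipeline as the modal between-site call.

## Worked example

```python
from assemblage import run_pipeline
from assemblage.pipeline import PipelineConfig
from assemblage.simulate import generate_dataset, preset_config

dataset = generate_dataset(preset_config("variable_selection", seed=7))
result = run_pipeline(
    dataset.counts, dataset.tree, dataset.metadata,
    PipelineConfig(reps=199, seed=7),
)
fr = result.fractions["all"]
for process, pct in fr.percentages.items():
    print(f"{process:24s} {pct:5.1f}%")
print(f"pairs classified: {fr.n_pairs - fr.n_excluded} of {fr.n_pairs}")
```

Output:

```
variable_selection        71.2%
homogeneous_selection      1.3%
dispersal_limitation       7.2%
homogenizing_dispersal     9.8%
undominated               10.5%
pairs classified: 153 of 153
```

The dataset is a six-site pH gradient with strong environmental
filtering of a phylogenetically conserved niche trait, so most pairwise
comparisons between sites at different pH are (correctly) attributed to
variable selection; the residual stochastic calls come from pairs of
sites with similar environments.

The same analysis is available from the shell:

```bash
assemblage simulate --scenario variable_selection --seed 7 --out-dir data/
assemblage run --config config.yaml          # align → bnti → rcbray → classify
assemblage bnti --counts data/counts.tsv --tree data/tree.nwk --out bnti.csv
```

Square matrices are written in the deposited-file layout (ID header row
and ID first column) so precomputed βNTI/RC<sub>bray</sub> matrices can
be read back with `assemblage.io.read_square_matrix` and classified
directly.

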
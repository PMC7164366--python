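# cetdate

Bayesian divergence-time estimation for phylogenomic coding data, built
around the workflow used in large-scale mammalian timetree studies (the
motivating case is cetacean phylogenomics: thousands of protein-coding
genes on a fixed species topology, dated against fossil calibrations).

Large alignments make per-gene dating impractical, so the workflow is:

1. **QC** the gene set — drop genes with pseudogene evidence (internal
   stop codons, frameshift indels), taxa missing most of their exons,
   and duplicate individuals per species;
2. **bin genes by relative rate** (pairwise HKY85 ML distances between a
   reference taxon pair) into 3/6/10 partitions, optionally split by
   codon position;
3. **choose a relaxed-clock model** — strict (STR), independent
   lognormal rates (IR) or autocorrelated geometric-Brownian rates (AR)
   — by stepping-stone marginal likelihoods on small exact-likelihood
   subsets: log mL estimates with standard errors, combined into
   posterior model probabilities under equal priors;
4. **date** the fixed topology by MCMC under a birth–death node-age
   prior with hard/soft fossil calibrations, using either exact pruning
   (HKY85+Γ₅) or the fast quadratic approximation of the log likelihood
   around the branch-length MLEs (gradient + Hessian per partition);
5. **diagnose** with the infinite-sites plot — 95% credibility-interval
   width regressed on posterior mean node age; the slope measures the
   irreducible, calibration-driven share of dating uncertainty — and by
   comparing complete vs clocklike-reduced gene sets.

A first-class synthetic-data module (timetrees from the birth–death
kernel, STR/IR/AR branch rates, HKY85+Γ codon alignments with
slow-to-fast gene multipliers, injected pseudogene artifacts with a
ground-truth log) makes every stage testable without downloading data.
The scientific model and numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a small study, bin the genes, build the approximate-likelihood
surface and date under the AR clock:

```python
from cetdate import (BdParams, ClockModelSpec, DivergenceTimeModel,
                     McmcSettings, SubstitutionParams)
from cetdate.synthetic_data import (simulate_timetree, simulate_gene_set,
                                    make_calibrations)
from cetdate.rate_partition import (gene_rate_table, bin_genes,
                                    partition_alignments)

bd = BdParams(1.0, 1.0, 0.1)                 # birth, death, sampling
sub = SubstitutionParams(kappa=4.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
                         gamma_shape=0.8, n_categories=5)
tree = simulate_timetree(8, root_age=100.0, bd=bd, seed=1)
spec = ClockModelSpec("AR", mu=0.2, sigma2=0.2)  # per 100-Ma unit
genes, mults, rates = simulate_gene_set(tree, spec, sub, n_genes=12,
                                        n_codons=200, seed=1)

table = gene_rate_table(list(genes.values()), ("t1", "t8"),
                        fallback_taxa=tree.labels[1:-1])
parts = partition_alignments(genes, bin_genes(table, 3),
                             taxa=list(tree.labels))
cals = make_calibrations(tree, [("root", "root")],
                         rel_offsets=(0.08, 0.08))   # 92–108 Ma window

model = DivergenceTimeModel.from_alignments(parts, tree, cals,
                                            clock="AR", bd=bd, sub=sub)
res = model.fit(McmcSettings(n_iter=60_000, sample_every=20,
                             n_chains=2, seed=7))
print(res.node_ages().round(2).to_string())
fit = res.infinite_sites()
print(f"infinite-sites slope: {fit.slope:.3f}")
```

Output:

```
             mean   q2.5   q97.5  ci_width     ess  low_ess  clade
parameter
age_8       16.30  12.87   21.15      8.29   42.77     True  t3|t7
age_9       27.91  21.96   34.42     12.46   35.62     True  t2|t5
age_10      38.56  31.97   46.78     14.81   36.89     True  t6|t8
age_11      48.20  39.33   57.72     18.39   28.03     True  t1|t4
age_12      88.88  75.54  100.58     25.04   25.72     True  t1|t4
age_13      91.95  77.90  104.51     26.61   25.42     True  t1|t2
age_14     100.14  92.50  107.73     15.23  186.60    False  t1|t2

infinite-sites slope: 0.147
```

Each `age_*` row is one internal node (`clade` shows two tips that
anchor it): posterior mean age in Ma, the equal-tail 95% credibility
interval and its width, and the effective sample size (ESS < 100 is
flagged — at this short desk-scale chain length most nodes deserve a
longer run). The true simulated ages (13.3, 29.2, 40.0, 48.8, 94.4,
94.6, 100.0 Ma) all fall inside the intervals. The infinite-sites slope
says 0.147 Ma of CI width accrue per 1 Ma of node age.

For clock-model choice, `select_clock_model(...)` returns a table of
log mL ± SE and posterior model probabilities; `fit_prior()` runs the
sampler with the likelihood switched off to expose the effective joint
prior on node ages (recommended before every dating run).

A thin CLI mirrors the stages (`cetdate simulate | qc | partition |
rank-genes | surface | date | select-model | diagnose | run`); `cetdate
run --out DIR` executes the whole synthetic study from a flat key=value
config and is resumable (artifacts are hash-stamped).

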
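# ithmix

Intra-tumor heterogeneity (ITH) inference from bulk somatic point-mutation
read counts, with entropy-based ITH metrics and a survival-association
benchmark.

## The problem

A tumor is a mixture of genetically distinct subclones. Bulk sequencing
observes, for each somatic point mutation (SPM), only an alternate/reference
read-count pair whose expected variant allele frequency is distorted by tumor
purity, local copy number, and the fraction of cancer cells carrying the
mutation. `ithmix` deconvolves this signal into a subclone structure and
summarizes heterogeneity as the Shannon entropy of the subclone proportions —
a continuous ITH measure suitable as a covariate in survival association
studies, where the number of subclones alone is too coarse and unstable.

## The model

Subclones form a rooted tree under a perfect (infinite-sites) phylogeny with
at most two children per node and clonal copy-number events. A mutation
arising in subclone *s* is carried by *s* and its descendants; its allocation
vector **q** indicates that set. Clonal mutations may predate a copy-number
event and carry multiplicity *m* ∈ unique{1, C₁, C₂} > 0; subclonal mutations
always have *m* = 1. For purity φ and subclone proportions **ϑ** (among
cancer cells), the alternate read count at a locus with state (C₁, C₂) and
depth T follows the mixture

    P(A) = ε/T + (1 − ε) Σ_d π_d Binom(A; T, p_d),
    p_d  = m_d φ ϑᵀq_d / ((C₁ + C₂) φ + 2 (1 − φ)),

where the sum runs over the state's allocation × multiplicity combinations,
π is a per-state simplex of mixture weights, and ε absorbs reads unexplained
by any combination. All rooted trees with 1–5 subclones (13 configurations)
are enumerated; each is fitted by EM (closed-form ε and π updates, BFGS for
**ϑ** in a softmax parameterization) and scored by BIC = 2L − m·log(L).
Configurations are averaged with posterior weights ∝ exp(0.5·BIC), giving

* **optimal entropy** E_o — entropy of the best-BIC configuration(s),
* **weighted entropy** E_w — entropy averaged over all retained
  configurations,
* the subclone count S, a high-ITH indicator H, and a model-averaged
  cellular prevalence per mutation.

Configurations in which a subclone is anchored by fewer than two mutations
are dropped before averaging.

The package also ships the full validation machinery: a cohort simulator
(logit-uniform subclone fractions, negative-binomial depths, binomial reads,
proportional-hazards survival with tuned uniform censoring) and a benchmark
harness measuring bias, power, and confidence-interval coverage of Cox
regression on true versus estimated ITH.

## Worked example

```python
import numpy as np
from ithmix import SimConfig, SubcloneEntropy
from ithmix.simulate import draw_ith, draw_reads, truth_to_sample

rng = np.random.default_rng(14)
config = SimConfig(depth_mean=500, n_spms=100)
truth = next(t for t in iter(lambda: draw_ith(config, rng), None)
             if t.n_subclones == 3)
draw_reads(truth, config, rng)

est = SubcloneEntropy(random_state=0).fit(truth_to_sample(truth))
print(est.n_subclones_, np.round(est.theta_, 3))
print(round(est.entropy_optimal_, 4), round(est.entropy_weighted_, 4))
```

prints

```
3 [0.334 0.49  0.176]
1.0215 0.9451
```

against a generating truth of S = 3, ϑ = (0.328, 0.506, 0.166), E = 1.0085,
purity 0.428. The per-configuration table shows why the two entropies differ:
the linear and the branching three-subclone trees fit the read counts almost
equally well (BIC −929.3 each, posterior weight 0.500 each), so the weighted
entropy averages over both topologies while the optimal entropy reflects the
single best-BIC configuration.

The same analysis runs from the shell:

```
ithmix simulate --out sim/ --n-subjects 30 --seed 3
ithmix infer --mutations sim/samples/sim0000.tsv --purity 0.43 \
             --out results/ --seed 1
ithmix benchmark --out bench.tsv --n-reps 50
ithmix burden --mutations muts.tsv --segments segments.tsv --out burden.tsv
```

Mutation tables are headered TSVs (`chrom, pos, ref, alt, alt_count,
ref_count, cn_minor, cn_major`, 1-based coordinates); a VCF with allele
depths plus a segment TSV works as well. Before inference, mutations are
filtered to autosomal single-base substitutions with ≥ 7 alternate reads and
non-zero total copy number.

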
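# mixsquare

Isoform quantification for RNA-Seq that learns positional fragment bias
instead of assuming it away.

cDNA fragments are rarely uniform along a transcript: library preparation
and RNA degradation enrich fragment starts at the 5' end, the 3' end, or
both, and quantifiers that assume uniform coverage misattribute reads
between isoforms of a gene. `mixsquare` implements the Mix² model, which
treats the fragments of a gene locus as draws from a *mixture of
mixtures*:

```
p(r) = Σ_i α_i p(r | t=i)                       (locus superposition)
p(r | t=i) = p(l(r) | t=i, s(r)) Σ_j β_ij p(s(r) | t=i, b=j)
```

Here `α_i` is the relative abundance of isoform `i`, `s(r)` and `l(r)`
are the fragment start and length in transcript coordinates, and the
`p(s | t=i, b=j)` are `M` Gaussian components placed equidistantly along
the transcript (`μ_ij = j·l/M − l/(2M)`, `σ_ij = l/(2M)`, discretised and
renormalised over `s = 1..l`). The component weights `β_ij` determine the
shape of the fragment-start distribution of each isoform and are learned
jointly with the abundances `α_i` by EM — so quantification and
positional-bias estimation happen simultaneously, and the fitted `β`
render per-transcript start distributions that can be clustered to
discover the bias types present in a data set.

Because the `β` rows control distribution shape, they can be *tied*
across transcripts to reduce parameters: `none` (each isoform its own
row, M=3 by default), `global` (one row per gene, M=4), or `group`
(rows shared within gene-and-length groups, M=4; length bins are
log-equidistant between 300 and 5000 bp and merged until every group has
at least 20 supporting reads and at most one group is a singleton).

The package also ships the matching study tooling: a biased-fragment
simulator (Cufflinks-style, 5', 3' and 5'+3' bias families, SAM output
that round-trips through the extractor), GTF/SAM ingestion, the
evaluation metrics (abundance L1, weighted start-distribution L1, log
truncation, fold-change ROC, titration-design checks, detrended
variability) and a UPGMA-based bias-type explorer.

## Worked example

Fit one multi-isoform locus sampled under a 5' bias:

```python
import numpy as np
from mixsquare import Mix2Model
from mixsquare.fixtures import seven_test_genes
from mixsquare.simulate import BiasModel, sample_locus_dataset
from mixsquare.evaluate import l1_abundance

locus = seven_test_genes()[0]
dataset = sample_locus_dataset(locus, BiasModel("five_prime"),
                               n_fragments=10000, seed=42)
result = Mix2Model(locus, dataset.fragments, tying="group").fit()
print(result.summary())
print("true alpha:     ", np.round(dataset.alpha, 4))
print("estimated alpha:", np.round(result.alpha, 4))
print("abundance L1:   ", round(l1_abundance(result.alpha, dataset.alpha), 4))
```

prints

```
Mix2 quantification: locus SYNF1
  tying=group  M=4  groups=2
  fragments=10000 (dropped 0)  iterations=69  converged=True
  log-likelihood=-126545.4814

  transcript            length  group     alpha     count
  SYNF1.t1                1300      1    0.2899    2898.6
  SYNF1.t2                1100      0    0.3058    3057.8
  SYNF1.t3                1150      0    0.3683    3683.2
  SYNF1.t4                 950      0    0.0360     360.4

true alpha:      [0.3247 0.3155 0.322  0.0378]
estimated alpha: [0.2899 0.3058 0.3683 0.036 ]
abundance L1:    0.0926
```

The four isoforms of this gene share most of their exons, yet under a
strong 5' bias the EM fit recovers the Dirichlet-sampled abundances to an
L1 distance of 0.09 (the distance is bounded by [0, 2]; 0.09 means the
estimated and true abundance vectors disagree by under five percentage
points in total). `result.start_distribution(i)` returns the learned
fragment-start distribution of isoform `i`, and `result.fpkm(total)`
converts expected counts to FPKM.

The same pipeline is available from a shell:

```sh
mix2 simulate --out sim --seed 3 --bias five_prime --n-fragments 3000
mix2 quantify --gtf sim/annotation.gtf --bam sim/reads.sam --tying group --out quant --seed 3
mix2 evaluate --truth sim/truth.tsv --est quant/quantification.tsv --out l1.tsv
mix2 cluster-bias --results quant --mode maqc --min-count 100 --out clusters.tsv
```

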
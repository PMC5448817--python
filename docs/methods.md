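# Methods

## The model

A gene locus with `N` annotated isoforms generates fragments according to

```
p(r) = Σ_{i=1..N} α_i p(r | t=i),          Σ_i α_i = 1, α_i ≥ 0,
```

where `α_i` is the probability that a fragment originates from isoform
`i`. The per-isoform fragment distribution factorises over the fragment
start `s(r)` and length `l(r)`, both in 1-based transcript coordinates
(position 1 is the 5' end of the spliced transcript; minus-strand
transcripts map position 1 to their highest genomic coordinate):

```
p(r | t=i) = p(l(r) | t=i, s(r)) · Σ_{j=1..M} β_ij p(s(r) | t=i, b=j),
Σ_j β_ij = 1, β_ij ≥ 0.
```

The `M` positional components are Gaussians placed equidistantly along
the transcript,

```
μ_ij = j·l(t=i)/M − l(t=i)/(2M),   σ_ij = l(t=i)/(2M),
```

evaluated at the integer start positions `s = 1..l(t=i)` and renormalised
to sum to one. No continuity correction is applied; this is the simplest
discretisation consistent with requiring each component to be a proper
distribution over starts. A consequence worth knowing: because
`μ_ij + μ_i,M+1−j = l`, the component placement is symmetric about `l/2`
while the integer grid is symmetric about `(l+1)/2`, so mirror symmetry
of the discretised tables holds only up to a half-position offset.

The length factor `p(l | t, s)` is a Gaussian density (mean 200 bp,
sd 80 bp — the common default for fragment size selection) at integer
lengths, truncated and renormalised over the admissible range
`1..(l(t) − s + 1)`. The truncation makes the joint distribution over
`(s, l)` proper (it sums to exactly 1), which the test suite verifies.
For single-end data the length is unknown and summed out, so the factor
is identically 1 and the fragment start is taken to be the read's
downstream (3'-direction) end in transcript orientation.

## Parameter estimation

Parameters are initialised uniformly, `α_i = 1/N` and `β_kj = 1/M`,
which renders near-uniform initial start distributions (ripple below
1.5× over the central 90% of positions). EM then alternates:

* E-step: `p(t=i, b=j | r) ∝ α_i β_{g(i)j} p(l|t,s) p(s|t,b=j)`, rows
  normalised per fragment; fragments with zero locus probability are
  dropped once, with a logged count.
* M-step: `α_i ← (1/R) Σ_r p(t=i|r)` and, per tying group `k`,
  `β_kj ← Σ_r p(g=k, b=j|r) / Σ_r p(g=k|r)` where the group posteriors
  sum transcript posteriors over the group members. A group with zero
  posterior mass keeps its previous row (logged) rather than being
  renormalised from zeros.

Iteration stops when the largest absolute parameter change falls below
`param_tol = 1e-4`, or the relative log-likelihood change falls below
`loglik_tol = 1e-6`, or after `max_iterations = 1000` (then a warning is
raised and the result returned). The likelihood is monotone along the
path (asserted to 1e-8 in the tests). Identifiability is *not* checked;
the maximum-likelihood solution found is returned. These tolerances are
the package's defaults; only "a predefined threshold" is prescribed by
the method itself.

### Tying

* `none` — one `β` row per transcript, default `M = 3`.
* `global` — one row per gene, default `M = 4`.
* `group` — transcripts are first binned by spliced length into bins
  delimited by 7 boundaries log-equidistant between 300 and 5000 bp
  (shorter transcripts join the first bin, longer ones the last; empty
  bins are dropped), then bins are merged until every group has at least
  20 valid reads (fragments compatible with at least one member) and at
  most one group is a singleton. The merge distance is the percent
  relative difference of group mean lengths,
  `|m₁ − m₂| / min(m₁, m₂) × 100`, closest pair first, ties broken
  toward the lowest pair of group indices. Default `M = 4`.

Transcripts in a group share the weight vector `β_kj`, but each
transcript's Gaussians are placed on its own length — the group shares
*relative-position* shape, not absolute positions. `none` is numerically
identical to `group` with singleton groups and no merging (tested).

The default component counts (3 untied / 4 tied) follow the published
calibration of this model family on artificial data; they are deliberate
defaults, not fitted per dataset, because reference isoform
concentrations are usually unavailable for real data.

## The simulator

The simulator reproduces a four-bias artificial-data design:

* **Cufflinks bias** — the start distribution implied by uniform
  fragmentation plus Gaussian(200, 80) length selection:
  `p(s) ∝ Σ_{l=1}^{L−s+1} φ(l)`. Flat over most of the transcript with a
  3' taper.
* **5', 3', 5'+3' bias** — an initial shape over relative position,
  linearly rescaled to the transcript length, multiplied pointwise by the
  Cufflinks bias and renormalised. A uniform initial shape reproduces the
  Cufflinks bias exactly (special-cased so the equality is bitwise).

The exact parametric form of the initial biased shapes is not published;
this package uses `exp(−5x)` over relative position `x ∈ [0,1]` for the
5' bias, its mirror for the 3' bias, and their normalised sum for 5'+3',
all overridable via custom shape vectors. This choice matters for any
headline number that depends on how far the biased truth sits from the
uniform initialisation (see "Known limitations").

Datasets are sampled per locus: `α ~ Dirichlet(1,…,1)` (or supplied),
isoform per fragment from `α`, start from the isoform's biased
distribution, length from the truncated Gaussian via inverse-CDF on the
discrete admissible range. Per-isoform compatibility of each sampled
fragment reproduces what paired 50 bp reads would show after alignment:
only the two terminal read windows must map contiguously (splice
junctions agreeing exactly) onto another isoform, and the implied span
on that isoform may differ from the originating one. Fragments can also
be written as properly paired 50 bp SAM records with junction-split
CIGARs; the extractor recovers identical per-isoform placements
(round-trip identity is tested), so the in-memory fast path and the
SAM path feed EM the same observations.

The bundled panel is seven synthetic genes with 4–15 isoforms covering
exon skipping, alternative 5'/3' ends, intron retention and both
strands, with spliced lengths from ~250 bp to ~6700 bp. The full design
(7 genes × 200 abundance draws × sample sizes {500, 1000, 5000, 10000} ×
4 biases) enumerates 22400 datasets with per-dataset seeds derived
stably from a master seed.

For transcriptome-scale experiments, `random_transcriptome` generates
multi-isoform genes (5–12 exons, 2–8 isoforms by exon skipping, one
contig per gene) and `transcriptome_profile` assigns an exponential
rank-abundance over genes (default decay 6.9, i.e. ~3 orders of
magnitude dynamic range) with uniform Dirichlet isoform splits —
emulating the long-tailed expression of real samples.

### What the simulator does not emulate

Sequencing errors, quality values, sequence-specific (hexamer/GC) bias,
multi-mapping across genes, incomplete or wrong annotation, and
alignment artefacts. Passing tests therefore demonstrate correct
behaviour of the model and estimator under positional bias with perfect
alignment — not performance on real libraries, where those nuisance
factors additionally apply.

## Evaluation metrics

* Abundance L1: `Σ_i |α̂_i − α_i|`, bounded by [0, 2] on the simplex.
* Weighted start-distribution L1:
  `Σ_i α̂_i · L1(p̂(s|t=i), p(s|t=i))`, each stage of an EM run weighted
  by its own current abundance estimate (uniform at initialisation).
* Log truncation: log10 values below `Q1 − 1.5·IQR` of the finite logs
  (quartiles by linear interpolation, numpy type 7) are set to that
  threshold and flagged not-detected.
* Fold-change ROC: reference labels up (> 2), down (< 0.5), null
  otherwise; for threshold θ a transcript is called up if its estimated
  fold change exceeds θ, down if below 1/θ; TPs are correct-direction
  calls, FPs are calls on null transcripts; TPR at FPR 5/10/15% by
  linear interpolation. Infinite estimated fold changes are allowed.
  Note the null behaviour of this construction: an estimate independent
  of the reference gives TPR ≈ FPR/2 (AUC ≈ 0.25), not the diagonal,
  because wrong-direction calls on true positives count as neither TP
  nor FP.
* Titration design: with mixes C = 3:1 and D = 1:3 of samples A and B
  and mRNA-fraction parameter z = 1.43, the predicted ratio is
  `C/D = (k₁A + (1−k₁)B)/(k₂A + (1−k₂)B)`, `k₁ = 3z/(3z+1)`,
  `k₂ = z/(z+3)`; order consistency requires A > C > D > B when A > B
  (reversed when B > A; ties count as consistent).
* Detrended variability: replicate log10 values shifted so housekeeping
  medians agree, per-transcript mean binned into 100 equal-width bins,
  median per-bin standard deviation reported.

## Bias-type exploration

Estimated start distributions with at least 100 supporting fragments
(and, in SEQC-style mode, length within 200–20000 bp) are
length-normalised onto 100 relative-position bins. MAQC-style mode
clusters the sum-1 profiles; SEQC-style mode peak-scales them to max 1
first (which tightens L1 between visually similar shapes). UPGMA
(average linkage) under L1 builds the tree; a top-down traversal retains
maximal nodes holding at least 5% of the profiles, reporting a parent
instead of its only qualifying child when the median shapes differ by
less than `shape_tol = 0.15` in L1 ("shrinks without changing shape").
Profiles outside every reported cluster form the "other" remainder. The
tree is built on id-sorted input, so the output is invariant to input
order.

## Problem sizes and headline quantities

The packaged experiments run at desk scale, chosen so the full test
suite and the acceptance script complete in minutes on one CPU:

* **Bias convergence** (`scripts/acceptance.py`): 7 genes × 3 Dirichlet
  draws × 3 biased models at 10000 fragments (63 datasets), group
  tying. The reported quantity is the relative decrease of the *average*
  weighted start-distribution L1 across all datasets, from
  initialisation to convergence — the aggregation in which such decreases
  are conventionally reported for this model family. Measured: ~51–53%
  across master seeds, with per-bias decreases of roughly 63% (5'),
  50–52% (3') and 28–34% (5'+3').
* **Transcriptome accuracy**: 500 random multi-isoform genes,
  exponential expression, 10⁶ fragments per bias model, group tying;
  mean abundance L1 over all (multi-isoform) genes, averaged over the
  four biases. Measured: ~0.38.

## Known limitations

* The 5'+3' initial shape is the package's stand-in; because that truth
  sits closer to uniform in L1 than the one-sided biases, its
  *per-dataset relative* reduction is structurally smaller (and the EM
  maximum-likelihood solution need not minimise the L1 to the truth —
  on a few 5'+3' datasets the distribution estimate worsens while the
  likelihood improves). Sharper end-spike shapes would raise both the
  initial distance and the relative reduction.
* Identifiability is not verified; loci whose isoform structures make
  the mixture non-identifiable return one maximum-likelihood solution.
* Group tying assumes fragment-start shape depends on gene membership
  and transcript length only; real libraries violate this, which is
  precisely what the bias explorer is for.
* Sequence-specific bias and multi-mapping across loci are out of scope.
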
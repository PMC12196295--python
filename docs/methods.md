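# Methods

## Statistical model

Counts for feature *i* in sample *j* are treated as negative binomial with
mean s_j·μ_{i,g(j)} and dispersion α_i (Var = μ + αμ²), where g(j) is the
sample's design cell (genotype × age) and s_j a library-depth factor.
α = 0 degenerates to Poisson.

**Size factors.** Median-of-ratios: s_j = median over features expressed in
every sample of count_ij / geometric-mean_i, rescaled to geometric mean 1.
If no feature is expressed in every sample (pathological for bulk data)
the estimator falls back to total-count scaling and warns. The separate
"TPM" matrix used for reinstatement ratios scales each sample to one
million; gene-level counts carry no transcript lengths, so this is
counts-per-million and is labelled as such.

**Dispersion.** Per design cell with ≥ 2 samples, the method-of-moments
estimate (s² − m̄)/m̄² on normalized counts, pooled with df weights and
clamped at 0. Gene-wise values are then shrunk toward a parametric trend
α(μ) = a₁ + a₀/μ fitted by least squares on informative genes (coefficients
clamped ≥ 0), with weight 0.5 on the trend by default. The weight is a
compromise: weight 0 leaves noisy per-gene estimates; weight 1 ignores
genuine dispersion heterogeneity. Everything is closed-form and
deterministic — no empirical-Bayes iteration.

**Wald test.** For a contrast (reference, alternative) the estimate is
log2FC = log2(μ̂_alt + c) − log2(μ̂_ref + c) with pseudocount c = 0.5
(configurable); the difference-of-logs form makes level swapping negate the
estimate exactly. The standard error comes from the delta method under
Var(count) = μs + α(μs)² per sample, the p-value is two-sided normal, and
BH runs per contrast over tested features only. Features with all-zero
counts within a contrast are flagged untested and excluded from the BH
denominator rather than reported as zeros. DEG calls use strict
inequalities: FDR < 0.05 and |log2FC| strictly above the chosen cutoff
(0.1 loose, 0.26 strict), so boundary values are excluded.

Unwanted-variance removal (RUVSeq-style factor estimation) is not
implemented; the design accepts only the genotype × age factors.
Likelihood-ratio tests, GLM interaction terms and LFC shrinkage are out of
scope.

## Compensatory inference

Deregulated genes are the strict-threshold down calls in TG vs WT at the
early age. A deregulated gene is **reinstated** iff its CPM group-mean fold
change across the TG time course, (μ₆ + c)/(μ₃ + c), strictly exceeds 1.5
(an increase of more than 50%). Candidate miRNAs are the strict-threshold
down calls on the TG 3→6 contrast — the time-course reading of the
criterion; a mode comparing WT-vs-TG fold changes across ages would be an
alternative interpretation but the TG time course is the default because
the recovery being explained is itself a TG time-course phenomenon.

Interaction tables pool multiple curated databases under union semantics
(an edge exists if any retained source reports it). Edges a source marks
"weak" are dropped first; unspecified strengths are kept. Identifiers are
join-normalized: species prefixes (mmu-, hsa-, rno-) stripped and miRNA ids
lowercased, gene symbols uppercased.

**Rescued** = reinstated genes targeted by ≥ 1 downregulated miRNA.
**Compensatory miRs** = downregulated miRNAs with ≥ 5 rescued targets
(inclusive at exactly 5). Empty denominators yield fraction 0 with an
explicit flag rather than an error, so parameter sweeps stay total. The
set-chain invariant rescued ⊆ reinstated ⊆ deregulated is asserted on every
call.

## Network truncation

The bipartite graph has directed miR→gene edges (repression); auxiliary
gene–gene edges, when supplied, are bidirectional. Core extraction attaches
a virtual super-source to all source miRs and enumerates loopless paths to
gene nodes best-first in (length, lexicographic node sequence) order —
uniform edge weights, total tie-break, hence fully deterministic — keeping
the union of the first k (default 1000) paths. This replaces a
weighted k-shortest-paths formulation (PathLinker-style) because no edge
weights exist in this setting; the intent (a core subnetwork and the
fraction of rescued transcripts it retains) is preserved. Coverage is
nondecreasing in k and reaches 1 when k meets the number of simple
source→gene paths.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n)
per term, BH across tested terms. The universe defaults to the genes tested
for differential expression in the relevant contrast, not the whole
annotation. Terms are intersected with the universe first; terms smaller
than 3 or larger than 500 genes after intersection are skipped (tiny and
huge terms distort BH), both bounds configurable. The annotation is flat:
no term-ancestry propagation is performed.

## Synthetic data

The generator emulates the target study design: four cells WT/TG × 3/6
months with default sizes 5/6/15/16; ~2000 genes and ~1000 miRNAs with
baseline means log-uniform on [e³, e⁸]; library depth factors log-uniform
on [0.5, 2] applied multiplicatively; shared NB dispersion 0.1. Planted
structure: 10% of genes down in TG@3 by log2FC −1.5, half of them back to
baseline in TG@6 (the rest keep the deficit); 10 compensatory miRNAs down
by −1.5 in TG@6 vs TG@3, each wired to 8 reinstated genes with strong-
evidence edges; decoy edges at rate 0.002 per (miR, gene) pair with mixed
strengths, never from a planted miR into the reinstated set (so the planted
truth stays identifiable — configurable). The planted |log2FC| of 1.5 is a
power choice: with groups of 6 vs 16 and α = 0.1, BH across 1000 miRNAs
needs roughly p < 5·10⁻⁴ for reliable detection, which a unit effect does
not clear consistently. Annotation terms draw genes uniformly except the
first ⌈frac·n_terms⌉ terms, which take ~70% of their members from the
reinstated set.

What the generator does **not** emulate: per-gene dispersion heterogeneity
(optional log-uniform α exists but the default is shared), correlated genes
or co-regulated modules, batch effects or unwanted-variance structure,
miRNA-induced coupling between the miRNA and mRNA matrices (effects are
planted marginally, not mechanistically), and annotation-term overlap
structure. Recovery results on synthetic data therefore validate the
machinery and its thresholds, not performance on any real dataset.

## Numerical and design choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration ⇒ bit-identical
  matrices, tables and reports. Run reports contain no timestamps (timings
  go to `run.log`) so reruns are byte-identical; the report's config hash
  covers analysis parameters and input file bytes, not paths.
- Pseudocount 0.5 on group means keeps fold changes finite for zero groups;
  se = 0 with a zero estimate gives p = 1, with a nonzero estimate p = 0.
- BH is step-up with cap at 1, order-preserving.
- Boundary semantics throughout: FDR and |log2FC| thresholds strict,
  recovery ratio strict at 1.5, target count inclusive at 5.
- Multi-contrast analyses are BH-adjusted per contrast, matching the
  per-contrast reporting convention of the DEG counts.

## Validation design and known limitations

The Wald p is a large-sample normal approximation. Its agreement with an
exact label-permutation p is verified in the well-powered regime
(10 samples/group, α = 0.02, baseline means ≥ e⁵, planted unit effects),
where both tails are driven by the same strong signal and agreement is
~10⁻⁴. In the mid-range (p between ~0.05 and ~0.7) at small n, *no*
parametric tail tracks a per-feature permutation p closely: the permutation
law conditions on each feature's realized spread, and noise in the plug-in
dispersion alone moves mid-range p by several hundredths. Calibration in
that regime is instead validated distributionally — KS uniformity of null
p-values (at 30 samples/group, where the clamped moment estimator's
conservatism has washed out) and empirical FDR ≤ 7% on null datasets at the
study's own group sizes.

Dispersion estimation is method-of-moments, not maximum likelihood: cheap
and deterministic, but inefficient at very small n and biased upward by the
zero clamp under Poisson-like data, making small-n p-values mildly
conservative. The reinstatement call compares group means only; it does not
model within-group variance, so genes with high dispersion near the 1.5
boundary flip more easily. Network truncation treats all edges equally —
evidence strength beyond the weak/strong filter is not used as a weight.
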
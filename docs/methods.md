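# Methods

`gopriorit` integrates heterogeneous cancer-genomics evidence into a drug
priority ranking in four steps: per-gene K-ranks from a multi-study rank
store, permutation-tested essentiality scores for GO biological processes,
harmonic-mean recalibration of gene scores through those process p-values,
and fusion with a per-cohort activity matrix into drug scores and
sensitive-sample strata. This note records the model, its assumptions, the
parameters that matter, and the numerical choices, in enough detail to
reproduce or deliberately deviate from any of them.

## The knowledge-base and K-ranks

The store's atom is a *study*: a ranked gene list from one statistical
analysis of one molecular data type in one cancer cohort, or from one
curated literature collection. Ranks (1 = strongest evidence) rather than
raw statistics are stored because ranks are comparable across measurement
technologies, data scales and study designs, and are less biased toward
well-studied genes. Every study's ranks must form a permutation of `1..N`;
tied or gapped ranks from curated sources are densified by average raw rank
then lexicographic gene id, and a per-study `reverse` flag accommodates
sources that count the other way.

In-house-style studies can be built from per-gene statistics tables: raw
p-values are adjusted with Benjamini–Yekutieli (valid under arbitrary
dependence; the adjustment is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_by")`), genes with
adjusted q ≤ `q_threshold` (default 0.001) are retained, and survivors are
ranked by descending |effect|, ties broken by ascending raw p-value then
gene id. Because only the ordering of effects matters, any strictly
monotone transform of the effect statistic leaves the study — and
everything downstream — bit-identical; for signed effects the invariance
holds for transforms that preserve the |effect| ordering (odd monotone maps
such as cubing, or arbitrary increasing maps on magnitudes).

Within a *study set* S (default sets: activating, inactivating, survival),
each supporting study contributes a normalized rank

    u = (N − r + 1) / N ∈ (0, 1],   u = 1 ⇔ r = 1,

and the gene's K-rank is

    K = Σ_{s ∈ supp(g)} u_s / |S|.

Dividing by the total set size |S| (not the support count) rewards
cross-study recurrence: a gene ranked well in two of three studies
outscores a gene with the same ranks in one. The alternative divisor is
available as `krank_denominator="support"`, under which K becomes the mean
quality of the supporting evidence irrespective of how much there is.
Genes absent from every study of the set receive no K-rank at all — absence
of evidence is not evidence of irrelevance, and scoring such genes 0 would
poison the permutation null below.

## GO-process essentiality and the permutation null

A process's observed score is T = Σ K_g over its regulator genes that carry
a K-rank (positive and negative regulators pooled; a direction-split mode
exists behind `split_directions` but is off by default — downstream
recalibration consumes a single p per process). Significance uses a
*gene-sampling null*: B random subsets of size n (the scored-regulator
count) are drawn uniformly without replacement from the K-ranked gene
universe, each summed, and

    p = (#{T_perm ≥ T_obs} + 1) / (B + 1).

Size-matched sampling from the scored universe is the standard null for
sum-score gene-set statistics; it asks "is this regulator set better-ranked
than a random gene set of the same size", which is exactly the comparison
recalibration needs to be fair across processes of different connectivity.
The +1 pseudocount bounds p in [1/(B+1), 1] so the harmonic mean downstream
is always defined. Default B = 10 000; a seed is mandatory in the CLI, and
per-process generators are spawned from one `numpy` `SeedSequence` in
sorted process order, so results are reproducible and independent of
process iteration order.

Numerical choice: exceedances are counted as `T_perm ≥ T_obs − 1e-9`. A
null draw that reproduces the observed gene set must count as a tie, but
its sum may differ from T_obs in the last bit depending on summation order;
the tolerance makes tie-counting exact while being ~7 orders of magnitude
below the spacing of distinct subset sums in any realistic universe.
Degenerate cases: n = 0 gives p = 1 with a warning; n equal to the universe
size gives p = 1 (the only subset is the observed one).

Subsets are drawn by row-wise `argpartition` of a B×m uniform matrix (the
n smallest of m i.i.d. uniforms index a uniform n-subset), which keeps the
whole test vectorized; B = 2000 across 20 processes costs ~10 ms.

## Recalibration: harmonic mean of process p-values

A gene's recalibrated score pools the processes it regulates *in exactly
one direction* (a gene annotated as both positive and negative regulator of
the same process contributes nothing through that process — the annotation
is self-contradictory) and that carry a p-value:

    H = |U| / Σ_{P ∈ U} 1/p_P,      score = −log10 H.

The harmonic mean satisfies min p ≤ H ≤ max p and is dominated by the
smallest p-values, so one strongly essential pathway suffices for a high
score; and it is independent of |U| when the constituent p-values are equal,
which is the operational sense in which highly connected processes do not
dominate — a gene wired into 200 mediocre processes scores no better than
one wired into 2 equally mediocre ones. All-equal p-vectors return the
common value exactly (special-cased: repeated floating addition of 1/p is
not exact at n in the hundreds). Genes with no usable process are reported
as unscorable rather than scored.

## The activity matrix

The query cohort's discretized layers are fused per cell by precedence:

| priority | layer       | state         | status    |
|----------|-------------|---------------|-----------|
| 1        | mutation    | activating    | active    |
| 1        | mutation    | inactivating  | inactive  |
| 2        | copy-number | amplified     | active    |
| 2        | copy-number | deleted       | inactive  |
| 3        | expression  | up            | active    |
| 3        | expression  | down          | inactive  |
| 4        | —           | anything else | unchanged |

Mutations outrank copy-number because a point mutation is the most direct
evidence about the protein itself; copy-number outranks expression both on
conflict and when expression is silent, because genomic alterations are
more stable and reproducible across cohorts and hence better biomarkers.
Missing values make a layer's rule skip, never force `unchanged`. The table
is a total function over all 4×4×4 layer-state combinations (asserted
exhaustively in the tests) and per-cell provenance records the winning
layer, so any alternative convention can be diffed against this one.

Discretization of continuous expression (the loaders also accept
pre-discretized statuses) uses a per-gene robust z-score
(x − median)/(1.4826·MAD) at |z| ≥ 2 by default, or a rank-based quantile
rule (top/bottom q = 0.1). When the MAD is zero but the row is not constant
(over half the samples tied at the median), the moment z-score
(x − mean)/σ with population σ is used instead so isolated extreme samples
are still detected; truly constant genes are left unchanged with a warning.
Thresholds are configurable; the defaults are conventional outlier cutoffs,
not fitted values.

## Drug prioritization and stratification

A drug's mode of action fixes the target status it exploits: inhibitors
need an *active* target, activators an *inactive* one; drugs with no
recorded action get inhibitor semantics, the dominant case in drug-target
databases. An *eligible (altered) target* is a target gene that (a) has a
recalibrated score and (b) holds the required status in at least one
sample. With f_g the fraction of samples in which target g holds the
required status,

    D_d = Σ_{g ∈ altered(d)} score_g · f_g  /  n_targets(d).

The three factors implement the three balancing criteria: dividing by the
*total* known target count penalizes diffuse polypharmacology, score_g
carries knowledge-base relevance, f_g carries measured cohort activity.
`drug_score_mode="per_altered_targets"` divides by the altered count
instead, for users who prefer not to penalize targets that are simply not
altered in this cohort. Drugs with no altered target are omitted, not
scored 0. Ordering is by descending D, ties by more altered targets, then
drug id, making the ranking fully deterministic.

A drug's *sensitive samples* are the union over its altered targets of the
samples holding the required status; drugs sharing an eligible target set
share their strata exactly. The stratification report is a categorical
sample-by-row table (drug sensitivity rows, gene status rows, optional
annotation rows) with samples ordered by first-drug sensitivity, then
annotations, then sample id; it can be rendered as a categorical heat map.

## The synthetic fixture generator

Real inputs (multi-cohort rank tables, GO, drug-target databases, a tumor
cohort) are emulated by `synthetic_fixtures` with a coherent planted
signal: planted genes receive uniform ranks within the top decile of every
activating-set study, the planted process is regulated exactly by the
planted genes, the planted drug targets a subset of them, and the cohort
activates each planted gene (expression up, amplification in about half of
those samples) independently in `activation_fraction` of samples.
Background genes get uniform ranks; background processes and drugs draw
from background genes; background expression cells flip to up/down at
`noise_rate`. Defaults — 100 genes, 3 studies per set, 20 processes
(4–8 regulators each), 10 drugs (1–3 targets), 50 samples, 10 planted
genes, activation fraction 0.6, noise 0.02 — are desk-scale conditions
under which a correct implementation separates the planted entities
decisively while the negative control (`signal=False`, which removes both
the rank planting *and* the activation planting, since either alone still
identifies the planted drug) stays uniform. Everything derives from one
integer seed and is byte-reproducible.

What the generator deliberately does not emulate: real marginal
distributions of consortium-scale tumor data, inter-study heterogeneity beyond
independent uniform ranks, batch effects, correlated gene modules,
mutation-layer signal, survival endpoints, or realistic GO topology
(no hierarchy; flat regulator sets). Passing the planted-recovery tests
therefore demonstrates algorithmic correctness and end-to-end wiring, not
clinical performance on real cohorts.

## Validation problem sizes

The test-suite and the acceptance script validate at these scales, chosen
so the full battery runs on one CPU in well under the patience of a desk
check: exact-oracle permutation comparisons on universes ≤ 12 genes with
regulator sets ≤ 4 (complete enumeration, B = 10 000); null calibration
with 500 simulated processes over a 200-gene universe at B = 2000
(Kolmogorov–Smirnov at α = 0.01); drug-score brute-force equivalence on 50
random instances (≤ 6 genes, ≤ 5 drugs, ≤ 4 samples); planted-signal
recovery and its negative control across 100 seeds of the default fixture
at B = 2000.

## Known limitations

- The K-rank treats all studies equally; there is no weighting by sample
  size, study quality or data type, and no cap on the contribution of
  correlated studies.
- GO annotations are used as given: no is_a up-propagation, no evidence-code
  filtering. The OBO-based regulation deriver only resolves terms literally
  named "positive/negative regulation of X" to the process named exactly X.
- Classifying mutations as activating/inactivating is the caller's job
  (e.g. from a gene-class annotation); the package performs no
  variant-effect prediction.
- Process p-values are nominal and used only for ranking and recalibration;
  no multiplicity correction is applied to them, by design.
- Binding affinities, drug combinations and synthetic-lethal interactions
  are out of scope; every target of a drug counts equally.
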
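# Methods

## Relative expression

Expression is quantified by the comparative-Ct method. For a biological
sample (treatment, time, replicate) and target gene *g*,

    ΔCt   = Ct_g − Ct_eEF1alpha1
    ΔΔCt  = ΔCt − mean{ ΔCt of control replicates, same gene, same time }
    rel   = 2^(−ΔΔCt)

Technical wells are averaged into one Ct per biological sample first
(duplicates spreading more than one cycle raise a warning; the threshold is
configurable). The control baseline is the mean ΔCt of the time-matched PBS
replicates, not a pooled all-time baseline, so every cell is expressed
relative to its own time point. `2^-ΔΔCt` is computed per biological
replicate and only then summarised (mean, sample SD with the n−1
denominator, median) — replicate-level spread is part of the downstream
correlation and testing contracts. Consequences worth knowing: the
*geometric* mean of control replicates is exactly 1 by construction, while
their arithmetic mean exceeds 1 under noise (Jensen); on noiseless input
the recovered value equals the injected fold change to floating precision.

Fold-change bands classify the cell mean: strong down (< 0.5), mild down
[0.5, 1), no change (exactly 1), mild up (1, 2], strong up (> 2). The value
1 belongs to neither printed band and gets its own label. Efficiency
correction (Pfaffl) and multi-reference normalisation are out of scope.

## Synthetic data

The generator writes noise on the Ct scale, where qPCR error is
approximately log-normal and the ΔΔCt algebra is linear: target
Ct = baseline − log2(FC) + ε_bio + ε_tech, housekeeping
Ct = hk_ct + ε_bio + ε_tech. ε_bio ~ N(0, noise_sd) is drawn once per
biological sample and shared by its technical wells; ε_tech ~ N(0,
tech_noise_sd) independently per well, default half the biological SD.
Defaults: baseline Ct 24, housekeeping Ct 18, noise_sd 0.25 — chosen so the
coefficient of variation of recovered expression (≈ ln2·√2·sd ≈ 25%)
matches the SD/mean ratios typical of screens of this design; the true Ct
variance of any given instrument is a free parameter.

Default fold-change trajectories cover all 10 genes × 2 treatments × 5
time points with the screen's characteristic dynamics (transient NF-κB
regulator peaks at 12 h, AMP bursts of 10–40 fold, biphasic *18w*
repression, sustained oxidase induction). What the generator does *not*
emulate: amplification-efficiency differences between primer pairs,
melt-curve artefacts, plate effects, or inter-larva correlation beyond the
biological-replicate noise term — so passing tests demonstrate the
correctness of the arithmetic and the statistical machinery under the
stated noise model, not robustness to assay-level artefacts in real data.

Health observations are drawn per larva × time × observer from per-group
category distributions over the rubric levels; survival is objective
(shared by observers) and made monotone per larva. Alignment pairs draw
column categories i.i.d. at requested rates (identical / conservative /
single-gap / double-gap / non-conservative remainder), with residues
sampled uniformly within each category's constraint.

## Health index

Score = activity + cocoon + melanisation + survival ∈ [0, 10]. Dead larvae
keep their observed category values — the rubric does not couple
categories. Observer aggregation is the arithmetic mean; concordance is the
mean absolute difference between observers' scores of the same larva, and
disagreements above 2 points are counted separately. On survival
disagreement the larva is counted dead (conservative) with a warning;
a dead-then-alive record warns but is reported as observed.

## Gated hypothesis testing

The reported comparisons are consecutive time points within each treatment
and the treatments pairwise at each time point. Each comparison belongs to
one *family* — the groups entering a single omnibus test: all time points
of one gene × treatment, or all treatments of one gene × time. The gate is
applied per family: if every group passes Shapiro–Wilk (p ≥ 0.05) and the
family passes Levene (p ≥ 0.05), the branch is one-way ANOVA with Tukey HSD
pairwise p-values; otherwise Kruskal–Wallis with Dunn's post hoc test,
Bonferroni-multiplied by the family's pair count. Groups with n < 3 (below
Shapiro's minimum) and constant groups force the non-parametric branch.
Dunn's z uses pooled mid-ranks with the standard tie correction. Stars:
\*\*\* p < 0.001, \*\* p < 0.01, \* p < 0.05, else ns, on the adjusted
pairwise p.

Because Tukey and Dunn–Bonferroni p-values are family-wise adjusted, the
per-comparison false-positive rate sits below the nominal level by design;
the branch's size is therefore validated at the omnibus level: over 2,000
null Gaussian families (5 groups × n = 3) the gate-then-omnibus rejection
rate is ≈ 0.04 at α = 0.05 (the gate discards ~22% of families to the
non-parametric side at n = 3, whose chi-square approximation is mildly
conservative at these sizes).

## Correlation and clustering

Spearman ρ is the Pearson correlation of mid-ranks. Pairing for both
cross-treatment and within-treatment coefficients is replicate-level,
ordered by (time, biological replicate): 5 × 3 = 15 pairs in the default
design. Time-point means alone (n = 5) cannot reach p < 0.001, which the
screen's strongest coefficients do; replicate-level pairing can. Constant
vectors yield an undefined ρ recorded as missing, never zero. Two-sided
p-values use the exact permutation distribution for n < 10 (full
enumeration, feasible to 9! ≈ 3.6·10⁵) and the t-approximation
t = ρ√((n−2)/(1−ρ²)) otherwise. Strength bands on |ρ|: none < 0.3 ≤ weak
< 0.5 ≤ moderate < 0.7 ≤ strong, with any p ≥ α reported "none" regardless
of magnitude; the sign is carried separately.

Clustering runs average linkage on d = 1 − ρ (signed: anti-correlated
genes are maximally distant; `distance="absolute"` gives 1 − |ρ|). Genes
are sorted lexicographically before linkage, which fixes tie-breaking and
makes the tree invariant to input order. Missing coefficients are imputed
as 0 (d = 1) with a warning. Module membership is read off a maxclust cut.

## Alignment consensus

Column rules, in order: both gaps → `-`; exactly one gap → the present
residue; equal symbols → that symbol; same physicochemical class → the
*query* residue (the consensus is query-biased by construction — swapping
query and subject can change conservative columns only); otherwise → `X`.
The class map ships as data and is overridable by YAML: hydrophobic
{A,V,L,I,M,F,W}, positive {K,R,H}, negative {D,E}, polar uncharged
{S,T,N,Q,Y}, special {C,G,P}. Histidine's placement (positive vs polar) is
genuinely contestable; the override hook exists for exactly that reason.
Ambiguity codes (B, Z, X, U, J, O) are accepted in input and treated as
non-conservative partners unless identical. Identity % counts identical
columns over both-residue columns; coverage % is the ungapped query length
over the stated full query length. Producing the alignments themselves
(BLASTP) and domain annotation are out of scope: the module consumes
alignment output.

## Problem sizes and numerical choices

The validation experiments use: 200 seeds for fold-change recovery at
noise_sd 0.1 (bias < 2%, comfortably inside the ±10% Gaussian-propagation
bound); 2,000 null datasets for the type-I estimate; 100 seeds for
two-module recovery at noise_sd 0.2 (two five-gene modules with opposing
trajectories; accuracy 1.0 at this noise level). All randomness flows
through `numpy.random.default_rng` seeded per experiment via
`SeedSequence.spawn`-style child seeds, so every figure in the acceptance
output is reproducible from one integer.

## Known limitations

* The ΔΔCt model assumes 100% amplification efficiency for all primers.
* The gate's conditional inference (test-then-test) mildly deflates the
  omnibus size below nominal at n = 3; this is inherent to the procedure,
  not a defect of the implementation.
* Exact Spearman p-values are only computed below n = 10; at the default
  n = 15 the t-approximation is used, which is anti-conservative for
  |ρ| → 1 at small n.
* The consensus is defined for pairwise alignments only; multi-sequence
  consensus requires a different (profile-based) formulation.
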
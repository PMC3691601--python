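# Methods

## The cross and the genotype model

`crossqtl` models the classical F2 intercross: two grandparents fixed for
alternative alleles at every marker, a uniformly heterozygous F1, and F2
offspring formed from two independent F1 meioses. Genotypes are coded by
the count of grandsire alleles — B (0), H (1), A (2) — so each locus
segregates 1:2:1 and the additive dosage x_add = g − 1 takes values
−1/0/+1 with +1 for the grandsire homozygote. All likelihoods assume
autosomal inheritance, known linkage phase (guaranteed by the cross
design), and no crossover interference; no sex chromosome or sex-specific
recombination is modelled, matching the single-sex F2 panels the package
targets.

## Two-point estimation and map construction

For a marker pair the joint distribution of genotype pairs is the
convolution of two gametes whose haplotypes recombine with probability r;
the double-heterozygote class is the two-phase mixture
((1−r)² + r²)/2. The recombination fraction is the maximiser of the
9-class multinomial log-likelihood over pairwise-complete individuals,
and the two-point LOD is log10 L(r̂) − log10 L(0.5).

Two equivalent optimisers are provided: `estimate_rf` (bounded Brent on
[0, 0.5], absolute tolerance 1e−12) for a single pair, and `pairwise_rf`,
a vectorised EM over all pairs at once in which the latent quantity is
the number of recombinant gametes per individual (every class but the
double heterozygote has a fixed count; the double heterozygote
contributes 2r²/((1−r)²+r²)). The EM runs to a fixed point (Δr < 1e−10,
cap 200 iterations) with r floored at 1e−9 to keep the boundary
differentiable; the test suite checks both paths against an exhaustive
grid-search oracle at 1e−4.

Markers are grouped by single-linkage transitive closure over edges with
two-point LOD ≥ `lod_min` (default 5.0, threshold inclusive) **and**
r̂ ≤ `r_max` (default 0.45): the grouping LOD and the recombination
ceiling are combined into a single edge criterion because a one-rule edge
is directly testable. Groups below `min_group_size` (default 2) are
reported as unplaced, not mapped.

Each group is ordered by SARF seriation — minimise the sum of adjacent
recombination fractions — using a deterministic heuristic: seed with the
highest-LOD pair, extend greedily at whichever chain end offers the
smaller r, then exhaustively permute every sliding window of 4 adjacent
positions until no window improves. Ties break by lexicographic marker
name and the final order is canonicalised so the first marker name sorts
before the last, making output independent of input order. On groups of
≤ 8 markers the heuristic is verified against brute-force permutation
search. This seriation is the package's own construction; widely used
commercial mapping software does not publish its ordering procedure in
reproducible detail, so an open, deterministic criterion is used instead.

Cumulative positions are the running sum of the Kosambi transform
d = 25 ln((1+2r)/(1−2r)) of adjacent r̂ (Haldane d = −50 ln(1−2r)
available via `map_function="haldane"`; recovery tests pair Haldane
estimation with Haldane simulation so the closed form is exact). An
adjacent pair at r̂ ≥ 0.5 breaks the group at that junction (logged);
final groups are renumbered by descending marker count.

## Genotype probabilities and the Haley–Knott scan

Multipoint genotype probabilities come from a three-state HMM per
linkage group: stationary prior (¼, ½, ¼), transitions between loci at
distance d from the F2 transition matrix built with r = kosambi_inv(d)
(consistent with the map's metric), emissions 1−ε for the called state
and ε/2 for each other state (ε default 1e−4), uniform at missing calls
and pseudomarkers (inserted every `step_cm`, default 1 cM). Posteriors
are computed by a scaled forward–backward pass vectorised over
individuals and verified against brute-force path enumeration on small
fixtures.

The scan regresses the phenotype on [1, p_add, p_dom] at every grid
position, complete cases only, with
LOD = (n/2)·log10(RSS₀/RSS₁). The implementation projects the intercept
(and, in multi-QTL fits, the current model matrix) out of phenotype and
regressors and solves the remaining 2×2 normal equations in closed form
across all positions and all phenotype columns at once; this is what
makes 1000 permutations of a ~2,600-position genome a sub-second
operation. Degenerate positions (collinear dominance column) fall back
to the additive regressor alone; a constant phenotype yields an all-zero
curve rather than an error.

Genome-wide significance uses phenotype permutation with genotypes
fixed. The threshold is the ⌈(1−α)(N+1)⌉-th smallest of the N
permutation maxima — the order-statistic rule, exact for finite N —
deterministic given a seed. Type-I calibration (fraction of null traits
whose own scan maximum exceeds their own threshold) is asserted at
5% ± 3 points in the test suite.

## Stepwise multiple-QTL search

The model with QTL set Q and interaction set I is scored by the
penalised LOD, pLOD = LOD − mainPenalty·|Q| − intPenalty·|I|, with
mainPenalty defaulting to the permutation threshold and intPenalty to
twice it (a deliberately conservative default; the interaction penalty
has no natural single-trait calibration and is configurable). Forward
steps add either the best grid position (positions within 10 cM of an
existing QTL on the same group are excluded, preventing duplicate peaks
on a correlated grid) or the best interaction between included QTL
(modelled as the four products of the two QTL's additive/dominance
columns); backward pruning then removes terms while pLOD improves. The
model with the highest pLOD ever visited is returned, capped at
`max_qtl` = 10. Effects are the joint-fit coefficients; model PVE is
1 − 10^(−2·LOD/n).

Bayesian credible intervals normalise 10^LOD over a group's grid and
accept points in decreasing-LOD order until the target mass (default
0.95); points tied with the last accepted one (1e−9) enter as a block so
a symmetric profile yields a symmetric interval. A flat zero curve
returns the whole group flagged degenerate.

Effect summaries at the marker nearest a peak report per-class means and
standard errors, the additive effect (mean_A − mean_B)/2 and dominance
deviation mean_H − (mean_A + mean_B)/2, and classify dominance with a
2-SE equivalence band: additive if |d| ≤ 2·SE(d), overdominant if the
heterozygote mean lies outside the homozygote range by more than the
band, incomplete dominance otherwise; an empty genotype class degrades
the classification to "undetermined" rather than failing.

## Scaffold anchoring

Marker placements are read from 12-column BLAST tabular files. Per
marker the best bitscore hit passing `min_identity` survives unless the
second-best bitscore reaches `uniqueness_ratio` (default 0.9) of the
best, in which case the marker is dropped as ambiguous; strand is taken
from subject coordinate order and coordinates normalised to 1-based
inclusive with sstart ≤ send. A scaffold is anchored to the linkage
group contributing the most of its mapped markers when that count
reaches `min_markers` (default 2); a tie between groups leaves it
unanchored ("LG conflict" — deterministic and conservative), and
single-marker scaffolds are reported separately, never anchored.
Within a group scaffolds are ordered by the mean cM of their supporting
markers (mean, not median: simple and deterministic; ties break by
name) and oriented by the sign of the Kendall rank correlation between
marker cM and scaffold bp midpoint, with "?" when the correlation is
zero or undefined. A whole group's reversal is unidentifiable from
marker data; scoring against simulation truth therefore takes the better
of the two directions per group and flips orientations coherently.

AGP v2.1 output writes one object per linkage group: W lines for
scaffolds and 100-bp U gap lines (gap_type "scaffold", linkage "yes",
evidence "map") between them — the AGP convention for unknown gap sizes.
A validator recomputes object coordinates line by line. Anchoring
statistics report anchored scaffold count, anchored bp, the anchored
fraction of the assembly, and the fraction that would be anchored if
single-hit scaffolds were included.

## The synthetic-data generator

The generator exists so that every stage has inputs with known truth. It
emulates a RAD-seq F2 panel of the kind the package targets: 160
individuals; 22 chromosomes with a linear length taper summing to
1,933 cM; markers every 2.35 cM (~834 markers — the map density implied
by that marker count on that map, with the count matched so that the
missingness calibration below is on the 834-marker scale); per-individual
missing-call rates drawn from a Beta distribution with mean 182/834 and
a dispersion parameter (default 0.15, var = ρ·m(1−m) scale) chosen to
reproduce the strongly right-skewed per-individual missingness of real
reduced-representation panels; and quantitative traits
y = μ + Σ_q (a_q·x_add + d_q·x_dom) + N(0, σ_e²). The helper
`target_pve_to_effect` inverts the F2 variance identity
Var_QTL = a²/2 + d²/4 to hit a requested variance fraction exactly.

Crossovers are a homogeneous Poisson process per chromosome (Haldane,
no interference), implemented as the equivalent interval-wise Markov
chain — exact for the no-interference model. Selecting
`map_function="kosambi"` instead converts interval distances through the
Kosambi inverse in the same Markov scheme; because the Kosambi function
is not multilocus-consistent this is an approximation at the marker
grid, and recovery tests always pair Haldane simulation with Haldane
estimation. Genome layouts tile each chromosome with scaffolds of
lognormal length (given CV) in shuffled order and random orientation;
marker bp positions are linear cM→bp interpolation; each marker gets one
strand-consistent local hit plus, for a configured fraction, a decoy hit
at 0.4× the true bitscore.

What the generator does **not** emulate: segregation distortion (classes
are exactly Mendelian, where real panels often show a few percent skew),
genotyping errors other than missingness, crossover interference,
ordinal trait scales (all traits are Gaussian-residual; a "yellow score"
style ordinal trait is treated as continuous), read-level artefacts, and
assembly errors (scaffolds are always internally colinear with the
chromosome). Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to these
real-data complications.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds carried in
the configs; identical seeds give byte-identical artifacts (asserted in
the test suite). Probabilities are floored at 1e−300 before logs; LOD
values are clipped at 0; per-position normal equations fall back to the
additive-only regressor when the 2×2 determinant is below 1e−10 of its
scale. Chi-square segregation filtering uses df = 2 at α = 0.01 — the
filter's namesake equilibrium test specialised to the F2 1:2:1
expectation, with the threshold a conventional screening level.
Phenotype missingness is handled by per-trait complete-case analysis,
with the per-curve n reported.

Problem sizes in the test suite are chosen to keep the full run at a few
minutes: calibration experiments use 5-chromosome genomes at n = 160,
recovery experiments use the full 22-chromosome panel with the true map,
and the acceptance script reports medians over five replicate panels of
the full pipeline.

## Known limitations

Only codominant markers and a single F2 likelihood are supported (no
dominant markers, no outbred/CP phasing, no composite interval mapping,
no covariates, no multi-trait scans). The seriation heuristic is exact
on small groups but has no global optimality guarantee on large ones.
Map lengths estimated from finite panels carry the usual upward noise
accumulation of summed adjacent r̂ plus the (small) Kosambi-vs-Haldane
metric difference when estimating interference-free simulations with the
Kosambi function. The stepwise search refines positions only to the
scan grid (no continuous refinement), and interaction detection at
n = 160 is severely power-limited by construction.
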
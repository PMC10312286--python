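# Methods

This note documents the analysis model implemented by spnnet, the
numerical conventions it fixes, what the synthetic generator does and
does not emulate, and the design choices that were genuinely open.

## Epoching

Events give the TR index at which the named object appears; with a 2 s
TR and the object onset a few hundred milliseconds into the trial, that
TR already contains object presentation, so the analysis window is the
four TRs `[onset, onset+3]` (configurable via `trs_per_trial`). Only
correct trials of the requested condition contribute. Motion-censored
TRs inside a window are dropped without interpolation; a trial that
loses all of its TRs is skipped with a warning rather than failing the
subject. Runs are laid out on one concatenated TR axis; because trial
windows never straddle a run boundary, per-run epoching followed by
concatenation and epoching on the concatenated axis are identical.

## NMI estimation

MI and the marginal Shannon entropies are plug-in estimates on a joint
equal-width histogram; natural logarithms are used throughout (the base
cancels in the ratio), `0·log 0 = 0`, and the ratio is clipped to
[0, 1] against floating-point dust. Per-series binning maps the sample
range onto `n_bins` equal intervals with the maximum in the last bin.

The default bin count is the Rice rule `⌈2·T^(1/3)⌉`. The plug-in MI
estimator is positively biased by roughly `(n_bins − 1)²/2T` nats; with
`⌈√T⌉` bins the bias at the epoch counts this pipeline produces
(T ≈ 100–500) would push the NMI of *independent* series above 0.1,
which blurs the contrast between planted and absent coupling. The Rice
rule keeps the measured independent-series mean NMI below 0.1 at
T = 480 while retaining enough resolution for strong dependence to
score near 1. `n_bins` is a parameter everywhere, so the square-root
rule remains one flag away. Numeric equality with any particular
published connectivity table is not a goal — binning and estimator
choices there are unreported — so the package validates its estimator
against brute-force reference implementations instead.

The all-pairs matrix builder accumulates every joint histogram in one
blocked matrix product over per-column one-hot indicators; this is
algebraically the pairwise computation and is cross-checked against it
in the tests. Summation inside the pairwise estimator is done in sorted
order so `estimate_nmi(x, y) == estimate_nmi(y, x)` holds exactly.

## Subject exclusion

Subjects whose mean connectivity strength (mean of the upper-triangular
NMI weights) falls outside Tukey's fences `[Q1 − k·IQR, Q3 + k·IQR]`
are excluded from their group average. Quartiles use the
linear-interpolation convention and k defaults to the conventional 1.5;
both are configurable. The fence test needs at least four subjects and
is skipped (with nothing excluded) below that.

## Percolation thresholding

The threshold τ* is the largest observed edge weight such that deleting
every edge *strictly* below it leaves the giant connected component
with the same node set as the unthresholded graph. Edges tied at τ* are
kept — ties are real in averaged data. The search inserts edges in
descending weight order into a union-find structure; τ* is the weight
of the edge that first connects all giant-component nodes, which makes
the maximality property (the next larger observed weight disconnects
the giant set) hold by construction and testable. If the input is
already disconnected the giant component is its largest component and
smaller components pass through unthresholded, with a warning; for
group-averaged NMI matrices the input is in practice complete.

## Network metrics

Degree and strength are divided by the node count N, which gives the
exact identity `mean degree = density · (N−1)/N` used as an internal
consistency check. Clustering is the Onnela geometric-mean form on
weights rescaled by the network maximum, zero for nodes of degree < 2.
Efficiency uses edge length 1/w and Dijkstra shortest paths;
disconnected pairs contribute 0. Reported "mean ± SD" dispersions are
sample standard deviations over nodes (denominator N − 1).

## Community detection

Q uses the weighted configuration-model null. The optimizer interleaves
two restart styles: singleton start followed by greedy pairwise module
agglomeration (random tie-breaks), and a random initial assignment of
nodes to a random number of modules. Both are refined by
Kernighan–Lin-style sweeps that move one node at a time to the module
(including an empty one, allowing splits) with the best positive Q
gain, in per-sweep randomized node order, until no move improves Q by
more than 1e-12. The random-start runs exist because pure greedy
agglomeration is nearly deterministic and can lodge all restarts in the
same local optimum; with the mix, best-of-100 reaches the exhaustive
enumeration optimum on ≥ 95% of random 7-node graphs. The best-Q
partition is returned (max-Q, not consensus); exact ties resolve to the
lexicographically smallest canonical labeling, making results
reproducible from the seed.

Partitions from different networks are aligned by solving the
assignment problem on their module contingency table (surplus modules
keep fresh labels) before side-by-side reporting. The partition
distance is the variation of information from the n-normalized
contingency table divided by log n, in [0, 1]; natural logs cancel.

For group differences in partitions, the permutation unit is the
subject: group labels are exchanged and the whole average → threshold →
optimize pipeline is recomputed on each side, with an add-one p-value.
This is an interpretation — published network comparisons of this kind
rarely state the exchangeable unit — and the run count is configurable
(a few hundred permutations keeps this tractable, since each draw costs
two full pipeline runs). Its power is limited by composition: a
permuted side can echo the minority group's structure only when enough
minority subjects land together, which is rare for unbalanced cohorts.

## Hub taxonomy

Hub means/SDs are taken over all N nodes of the network in question
(sample SD). Hubs use strict `>` ("more than 1 SD"), pillars inclusive
`≥` ("at least 1.5 SD"); since 1.5 SD implies 1 SD, every pillar is a
hub. The connector cutoff is 10% of the network's maximum participation
coefficient; a network with zero intermodular weight everywhere has no
connectors (everything would trivially pass a zero cutoff). The
high-influence band takes the *intersection* of the top-30% degree and
top-30% strength sets (nearest-rank percentile on a descending sort,
ties admitted); the union reading is available via `top_rule="union"`.
Participation uses strength-based module allocations because the graphs
are weighted; a binary-degree variant is a flag. The χ² homogeneity
test drops categories empty in both networks before computing
`Σ(O−E)²/E` without continuity correction, so df equals the remaining
category count minus one — the only reading under which a two-category
contrast yields df = 1.

## Permutation statistics

The test statistic is the pooled-variance two-sample t; the null
re-splits the pooled values at the original group sizes. When the
number of distinct splits is at most `n_perm` the null is enumerated
exactly and p is the exact tail fraction (the fully separated 5-vs-5
case gives p = 2/252); otherwise p uses the add-one Monte-Carlo
convention (1 + exceedances)/(1 + n\_perm), which never returns 0. Node
dispersions exist for degree, strength, clustering and nodal
efficiency, so those are compared at the node level; density and global
efficiency are scalars per network and are compared by subject-label
permutation with full pipeline recomputation. Both units are available
by flag and recorded in the output. A Bonferroni-corrected α (0.05
divided by the number of comparisons) is reported alongside raw p
values.

## Synthetic cohorts

The generator draws, per subject, an independent standard-normal latent
signal per module and per TR; node i's signal is its module's latent
times the within-module loading, plus a small common leak of all
latents, plus white noise. Designated connector nodes additionally load
(0.5 by default) on three foreign modules; designated provincial-role
nodes carry only their own module's latent. The second group's loadings
are scaled by (1 − attenuation). Trials sit on a 5-TR grid (two
conditions alternating, 30 trials per condition per run, two runs of
300 TRs), matching a 2 s TR paradigm with a ~10 s trial; all responses
are correct by default and censoring can be injected. Everything is
reproducible from (master seed, group, subject index) via independent
seed-sequence streams.

Default sizes mirror the emulated study: 212 ROIs in five modules, 23 +
14 subjects. The default noise SD of 0.6 (within-loading 1) puts the
within-module NMI roughly 0.13 above the between-module level at the
study epoch count — strong but not trivial task-locked coupling. A
`desk_spec()` preset (60 nodes, 4 modules, 8 + 8 subjects, one run)
runs the complete pipeline including permutation tests in seconds and
is what most tests use; the validation script uses the full 212-node
scale with noise SD 0.5 ("high SNR") for partition recovery.

What the generator does *not* emulate: hemodynamic convolution and
autocorrelation, scanner noise spectra and drift, realistic motion,
voxel-level structure, and between-subject anatomical variability.
Passing tests therefore demonstrate that the estimators and the
pipeline recover planted statistical structure of the stated form, not
that any particular acquisition will yield such structure.

Connector-detection sensitivity is scored as a ranking problem: among
the planted connector and provincial nodes, the top-|connectors| nodes
by participation coefficient are predicted connectors, and sensitivity
is the fraction of true connectors among them. (The absolute
10%-of-maximum cutoff is a within-network classification device, not a
detector of planted roles, since its scale depends on the network's
overall intermodular weight.)

## Numerical conventions and degenerate inputs

Connectivity diagonals are fixed at 0 and never enter graphs or
statistics. Constant epoch series (zero entropy) raise an error naming
the ROI. Zero-variance samples make the permutation test return p = 1
with a warning rather than dividing by zero. A network with zero
variance in both degree and strength classifies every node normal.
Matrices are kept exactly symmetric by computing each unordered pair
once and mirroring. All stochastic components (optimizer restarts,
permutation draws, cohort simulation) draw from seed sequences derived
from a single master seed, and rerunning a pipeline with the same
config and seed reproduces every number bit for bit.

## Problem sizes used in the shipped checks

Oracle-equivalence checks run on 100 random instances of up to 20
nodes; optimizer optimality on 100 random 7-node graphs against full
Bell-number enumeration (877 partitions); percolation maximality on 100
random graphs of 5–19 nodes; partition recovery on one 212-node,
23-subject group at noise SD 0.5; statistical calibration on 500 null
draws of 10-vs-10 samples at 199 permutations. These sizes make the
whole validation run in tens of seconds while exercising the same code
paths as a full-scale analysis.
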
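# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package, in the order data flow through the pipeline.

## Synthetic communities (`synthio`)

The generator emulates the sampling design the statistics assume: a fully
crossed factorial of land use (industrial/residential) × rain event
(RE1/RE2) × timing (before/after) × replicates; six replicates give the
48-sample design.

**Community model.** Each sample's composition is Dirichlet-multinomial.
A base composition `p` (user-supplied, or a lognormal rank-abundance curve
with σ = 1 drawn once per seed) is perturbed on the log scale,

    log q = log p + x_lu · δ_lu + x_t · δ_rain,   then renormalized,

with ±½ coding of the two-level factors (residential and after-rain
positive). Effects additive on log relative abundance are standard,
invertible, and let tests dial group separation continuously. The sample
composition is then `Dirichlet(c·q)` with concentration `c` (default 200,
i.e. mild compositional overdispersion), and reads are a multinomial draw
of the library size. Library sizes default to 30,000 reads per sample —
the study-scale mean mapped depth (≈3 × 10⁷) scaled down three orders of
magnitude so the full pipeline runs in seconds; read counts per sample
always equal the requested library size exactly.

**Read-level noise.** Each read carries candidate hits: the true species
scores uniformly in [50, 70], safely above the LCA score floor of 35. A
`decoy_rate` fraction of reads gain one random-species decoy whose score
falls inside the 10 % top-score band half the time (these legitimately
coarsen the LCA) and below it otherwise (these must be filtered). A
`nohit_rate` fraction have only a sub-threshold hit (score in [10, 30]), and
a `lowcomplexity_rate` fraction carry a complexity value in [0.05, 0.35],
below the 0.44 filter. The three categories are drawn disjointly per read,
so the no-hit bin fraction is binomial with mean `nohit_rate`. With all
rates zero the pipeline is an exact function of the ground-truth counts —
the round-trip oracle used throughout the tests.

**V6 reads.** Background bases are i.i.d. uniform, which keeps background
complexity near 1 so the complexity filter fires only on deliberately
planted homopolymer-like reads, and makes a chance 19-nt primer match
(probability ≈ 4⁻¹⁴ per position after degeneracy) negligible at desk
scale. Embedded reads contain a random instantiation of the degenerate
primer immediately followed by a catalogue tag, reverse-complemented with
probability `revcomp_rate`; the full 33-nt tag always fits the read.

**Environment/rain coupling.** A Gaussian copula: latent correlation
ρ = sin(πτ/2) yields population Kendall τ exactly, and both margins
(gamma rain intensities, affine-normal environmental variables) are
monotone transforms, which Kendall correlation ignores. Sample τ_b
therefore converges to the target as the series lengthens.

**Seeding.** One integer seed expands into per-operation substreams via
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with fixed operation keys
(taxonomy 0, profiles 1, hits 2, V6 3, environment 4); operations are
reproducible independently and do not consume each other's streams.

What the generator does *not* emulate: base-call errors and quality-score
distributions, insert-size models, chimeras, database incompleteness, or
real taxon co-occurrence structure. Passing tests demonstrate the
*machinery* is correct under the stated stochastic model, not that real
sediment data would behave this way.

## Taxonomic binning (`taxbin`)

Reads are filtered by normalized mononucleotide Shannon entropy
(H of the A/C/G/T composition divided by log 4) against the 0.44 threshold.
This transparent surrogate is used because only the thresholding behavior,
not the exact complexity measure of the original binning tool, is
load-bearing; the threshold is configurable. Surviving reads are assigned
by the LCA rule: discard hits with bit score < Min Score (35), retain hits
within Top Percent (10 %) of the best survivor — boundary ties retained
(≥), which keeps the rule deterministic and order-independent — and assign
to the LCA of the retained taxa, or to the NoHits bin when nothing
survives. The Min Support pass (25) then sweeps the tree deepest-first,
moving the reads of any under-supported node to its parent so they
accumulate until an ancestor qualifies; totals are conserved, and a flag
diverts failing reads to Unassigned instead for the stricter variant.
Rank projection counts each read toward its ancestor at the requested
rank; reads assigned above the rank, NoHits and Unassigned are reported in
audit rows rather than silently dropped. Read pairs are treated as
independent reads; a paired-end voting rule is out of scope.

## Ribotags (`ribotag`)

Exact IUPAC matching of the V6 primer, forward strand first, then the
reverse complement; the first usable match wins (one V6 region expected
per fragment), and reverse-strand tags are reported in primer orientation.
Reads with fewer than 33 nt downstream are discarded. No mismatch
tolerance is applied — deterministic and testable; the matcher is isolated
behind one function so tolerance could be added without touching callers.
Distinct 33-mers are OTUs; the OTU table carries every metadata sample as
a column so empty samples stay visible.

## Profiles and distances (`profiles`)

Normalization to the smallest library scales each column by
(min total / its total) *fractionally* — no re-rounding — so within-sample
proportions are preserved exactly and the operation is deterministic; a
seeded subsampling alternative (`subsample_to_smallest`, multivariate
hypergeometric) exists for parity experiments. Bray-Curtis and Jaccard are
computed directly on column pairs; a pair of all-zero columns is defined
to have distance 0 with a warning (NaN would poison network construction).
The prevalence filter keeps rows present in ≥ ceil(f·n) samples. Row
clustering uses average linkage on Bray-Curtis row distances — the
ecology convention, configurable — with rows pre-sorted lexicographically
so ties break deterministically.

## Diversity and univariate tests (`diversity`)

Shannon H is reported in nats (base configurable), E = e^H/S. Rarefaction
draws without replacement (multivariate hypergeometric) at each depth; the
closed-form expectation E[S_d] = Σᵢ 1 − C(N−nᵢ, d)/C(N, d) is implemented
alongside as the analytic reference. The per-feature group test uses the
Welch statistic (robust default; the study states only "t test") with
label-permutation p-values carrying the +1 correction — p is never zero,
and the test is valid-by-construction — and Bonferroni flagging at
α/n_features. Mann-Whitney U uses midrank ties, exact enumeration of the
C(n, n_a) group assignments for n ≤ 12 and the tie-corrected normal
approximation beyond. Kendall correlations are τ_b via scipy with its
exact-null policy for short untied series. Rain series are expected as
per-interval intensities; callers choose the aggregation window (the
study's correlations used monthly aggregates of hourly data).

## Neighbor-net (`neighbornet`)

**Ordering.** Agglomerative: clusters hold one or two active nodes; the
cluster pair minimizing the NJ-style criterion
(N−2)·D(A,B) − R(A) − R(B) on mean cluster distances is chosen, then the
node pair (x∈A, y∈B) minimizing the analogous criterion in which the
member nodes of A and B act as singleton clusters. Merged paths longer
than two nodes are reduced 3 → 2 with the canonical convex weights — new
end nodes at ⅔ outer + ⅓ middle, and d(u,v) = mean of the three pairwise
distances — applied twice for 2+2 merges. Reductions are recorded and
expanded in reverse to yield the circular ordering, canonicalized (first
sample first, smaller neighbor second) so the output is deterministic and
relabeling-equivariant. Correctness is enforced by oracles rather than
constant-matching: on random additive (tree) metrics the recovered splits,
weights and fitted distances must reproduce the generating tree exactly.

**Split weights.** All n(n−1)/2 interval splits of the ordering form the
split-metric incidence matrix A; weights solve min ‖d − A·w‖², w ≥ 0 by
scipy's Lawson-Hanson active-set NNLS (deterministic given input order).
Splits below the 1e−9 floor are dropped — numerical dust, immaterial to
the metric. For circular-decomposable inputs the fit is exact; for
arbitrary inputs the residual is never worse than the zero-weight vector.

**Splits graph.** The weighted split system is realized as the planar dual
of the chord arrangement of the splits drawn across the circular ordering
(equivalent to the classical band-insertion construction): chords sharing
a gap are nested by construction (endpoints within a gap are ordered by
circular distance to their far endpoint), crossings are decided
combinatorially (partially overlapping intervals) and located numerically,
cells are enumerated by half-edge face traversal, and each split
contributes a band of parallel edges carrying its weight. Deleting a band
disconnects the graph into the split's two sides, and shortest paths
between sample nodes equal the split metric to 1e−9 — the module's master
oracle, checked for every constructed graph in the tests. Node counts are
reported with every network.

## Bootstrap reproducibility (`netboot`)

"Six million reads with replacement from each data set" is implemented as
a per-sample multinomial resample at the observed genus proportions — the
stated purpose is depth standardization across samples, which a pooled
resample would not achieve; `total_pool=True` covers the other reading.
The desk-scale default is 10,000 reads (study-scale six million remains
available), and per-iteration seeds are `seed + iteration` for
reproducible parallelism. Each iteration rebuilds Bray-Curtis distances,
the neighbor-net splits graph, and the weighted shortest-path submatrix
over the sample nodes (hop-count paths optional). The Gower-Krzanowski
decomposition uses squared distances (T = W + B holds exactly and, for
Euclidean input, B equals the MANOVA between-group sum of squares); mean
raw within- and between-group distances are reported alongside, since
summary plots of within/between distances do not specify squaring.

## Permutational statistics (`permstats`)

PERMANOVA partitions tr(G), with G the Gower-centered −½D² matrix, using
balanced-design ANOVA projectors built by Möbius inversion over cell-mean
averaging operators (P_T = Σ_{S⊆T} (−1)^{|T\S|} M_S); the partition is
exact and df sum to n−1. Designs must be balanced and fully crossed, with
at most one random factor. Pseudo-F denominators follow the expected mean
squares of the mixed model: purely fixed terms are tested against their
interaction with the random factor; the random main effect and every
random-containing interaction against the residual. p-values use
Freedman-Lane permutation of reduced-model residuals
(G* = P(R_red G R_red)Pᵀ with the tested term removed from the model),
with the +1 correction, or complete enumeration when requested (the
univariate example (0,1,2,3)/AA-BB yields pseudo-F = 8 and exhaustive
p = 1/3, the classical ANOVA equivalence). Pooling is iterative, highest
order first: interactions with p above the threshold (default 0.25) fold
their SS and df into the residual and the table is recomputed, with pooled
terms flagged; `pool_threshold=None` disables it. Null calibration of the
full mixed design is verified empirically (rejection rate ≈ 5 %).

PERMDISP computes each sample's squared distance to its group centroid
through the Gower kernel, zᵢ² = Gᵢᵢ − (2/n_g)Σ_j Gᵢⱼ + (1/n_g²)ΣΣ G_jk,
which keeps negative principal-coordinate eigenvalues with their sign
(values match vegan's `betadisper` with centroid type); tiny negative zᵢ²
are clamped at zero. F is the one-way ANOVA statistic on zᵢ, permuting
group labels and recomputing centroids each time. Spatial medians are not
implemented; centroids are the documented default.

SIMPER averages the per-feature Bray-Curtis numerator share
|xᵢⱼ−xᵢₖ| / Σᵢ(xᵢⱼ+xᵢₖ) over all between-group pairs; contributions sum
to the mean between-group dissimilarity by construction, and the caller
supplies the same (square-root-transformed) matrix used for the distance
analysis. RELATE is Spearman ρ between the off-diagonal upper triangles,
with a one-sided (large positive ρ) Mantel-type permutation of one
matrix's sample identities and the +1 correction.

## Problem sizes and determinism

Desk-scale defaults throughout (30–120 taxa, 10³–10⁴ reads per sample,
10–100 bootstrap iterations, 199–999 permutations in examples and tests)
were chosen so the complete analysis and its verification run in minutes
on one core; study-scale values (six million reads, 9,999 permutations)
remain one argument away. Every stochastic routine takes an explicit seed
and identical seeds give byte-identical outputs, including the full
pipeline's tables and manifest.

## Known limitations

- Neighbor-net selection criteria follow the published agglomeration
  scheme but an independent reference implementation may differ in
  tie-breaking, so orderings (not fitted metrics) can differ legitimately.
- PERMANOVA supports balanced crossed designs with one random factor only;
  nested or unbalanced designs are rejected rather than approximated.
- The LCA monotonicity folklore ("stricter thresholds give shallower
  assignments") is not a theorem: removing the best hit can deepen the
  assignment. The implementation follows the assignment rule, not the
  folklore.
- Exact-p paths (PERMANOVA enumeration, Mann-Whitney enumeration, RELATE
  enumeration) are restricted to small n by design.
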
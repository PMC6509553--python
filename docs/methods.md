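# Methods

This note documents the models and procedures `phylostruct` implements,
the defaults it ships, and what its synthetic study system does and does
not establish about real data.

## Supertree construction and dating

The species pool is attached to a family/genus backbone by taxonomy:
species → genus node if one exists, otherwise a new genus node under the
family node; species whose family is missing are collected into an
"ungraftable" report and the operation fails unless explicitly asked to
drop them. Attachment creates polytomies (all congeners share one node and
therefore one divergence time), the result is pruned to exactly the
requested species, and any branch lengths the backbone carried are
discarded: dating is the sole source of lengths, because silently mixing
backbone lengths with interpolated ages would corrupt every downstream
distance.

Dating (BLADJ) fixes the ages of nodes named in the age table (the root
must be named; tips default to age 0) and assigns every other age by even
spacing. The dated node with the greatest age that still has undated
descendants anchors a path: among the dated nodes reachable from it
through undated intermediates only, it selects the terminal with the
fewest intervening edges (ties go to the oldest terminal, then the
lexicographically smallest name), and the j-th of the k−1 intermediate
nodes on the k-edge path receives age(A) − j·(age(A) − age(B))/k.
Assigned ages are then treated as fixed. One guard extends the plain
path rule: an interpolated age is floored at the age of the node's oldest
fixed descendant. Without the floor, a short path to a young terminal
can contradict an older fixed node on a side branch; with it, the output
is ultrametric for every internally consistent age table (the floor
sequence is non-increasing along any path, so monotonicity is preserved).
Fixed-versus-fixed conflicts (an ancestor younger than a descendant) are
detected up front and reported by name.

## Diversity metrics

* **Faith's PD**: branch-length sum of the minimal subtree spanning the
  sample's taxa *and the root* (root-inclusive), matching the common
  default of reference implementations; `include_root=False` gives the
  MRCA-rooted variant. PD is monotone under taxon addition.
* **MPD**: mean patristic distance over unordered pairs; presence-based by
  default, with an abundance-weighted mode
  (Σ wᵢwⱼ dᵢⱼ / Σ wᵢwⱼ, i ≠ j) behind a flag since presence data are the
  default interpretation of the index.
* **MNTD**: mean nearest-neighbour patristic distance.
* Samples with fewer than two taxa cannot support pairwise metrics; they
  are excluded from standardization with a warning rather than failing a
  whole run.

## Null model and standardized effect sizes

The null model is richness-preserving and pool-based: for a sample of
richness r, each replicate draws r tips uniformly without replacement from
all tips of the phylogeny (a `sample_pool` variant restricts the pool to
species observed anywhere in the matrix, for sensitivity analysis).
Defaults: 999 replicates, α = 0.05. NRI (from MPD) and NTI (from MNTD)
carry the ecologist's −1 sign, so clustering is positive. Significance
uses the two-sided rank p-value 2·min(r+1, R−r+1)/(R+1) with r the count
of null values strictly below the observed one; the +1 correction keeps p
in (0, 1]. Classification: clustered if NRI > 0 and p < α; overdispersed
if NRI < 0 and p < α; otherwise random. A degenerate null distribution
(SD = 0, e.g. a star phylogeny) yields a flagged, missing index rather
than an arbitrary number.

Randomness is reproducible by construction: each sample's replicate stream
is derived from (master seed, sample index), so identical inputs and seed
give bit-identical tables and appending samples never perturbs earlier
ones.

## Ordination

PCA eigen-decomposes the covariance of the centered (optionally
standardized) matrix; community matrices default to the Hellinger
transform first, the standard guard against the arch effect with raw
abundances. RDA column-standardizes both tables (the variables mix units —
cm²/g, mg/g, %, pH — so covariance-based RDA would be dominated by scale),
fits the responses on the predictors by least squares (least-norm
pseudo-inverse, so collinear predictors degrade gracefully), and
eigen-decomposes the fitted-value covariance; eigenvalue proportions are
reported against total response variance. Predictor–axis correlations are
Pearson correlations between each predictor and the constrained site
scores ("intraset" correlations), starred at 0.05/0.01 by the parametric
t-approximation with n = number of samples. Axis summaries print
eigenvalues, percentage variance and exact-cumulative percentages rounded
to one decimal for display.

## Synthetic study system

The generator emulates a five-level slope gradient over an 88-species pool:

* **Backbone**: 12 families of 2–6 genera; families are nested into a
  random binary arrangement of named, dated order-level clades rather than
  a root polytomy — a star of families would make every inter-family
  distance identical and flatten the phylogenetic signal the assembly
  knob is supposed to create. Ages: root 140 (arbitrary consistent time
  units), family crown ages 25–50% of the root, genus crown ages 15–45% of
  their family, and order-level joins decaying geometrically from the root
  (55–90%... of the parent per level, floored above the oldest family
  below). These ranges were chosen once as a plausible shape for a
  temperate herbaceous pool and to satisfy the generator's own contract —
  a monotone, detectably signed mapping from the assembly knob to NRI.
* **Communities**: per-level richness schedule (51, 41, 34, 29, 23), four
  quadrats per level, each quadrat assembled sequentially: first species
  uniform, each later pick with weight ∝ exp(−λ · mean patristic distance
  to the picks so far / tree depth). λ > 0 concentrates picks among
  relatives, λ = 0 reduces exactly to the null draw, λ < 0 repels
  relatives. The default λ schedule is (+2, 0, −1, −1.5, −2) from north to
  south. The richness schedule applies per quadrat; pooled slope-level
  richness therefore exceeds it. Abundances are log-normal (meanlog 1,
  sdlog 1) rounded up to counts; they only matter to the weighted-MPD flag
  and ordination.
* **Soil and traits**: eight soil factors follow a monotone north→south
  gradient (moisture and nutrients decreasing, pH increasing) with
  independent noise; eight leaf traits respond linearly to the realized
  (noisy) soil axis with coupling R² = 0.9 by default plus independent
  noise, mapped into field-typical units. Strong coupling gives the RDA a
  dominant first axis (≈ 0.9 of response variance); coupling 0 leaves only
  the chance-level share.

What the synthetic system does **not** emulate: spatial autocorrelation
between quadrats, abundance-dependent detection, taxonomic misassignment,
realistic soil chemistry covariance, or phylogenetic signal in the traits.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behaviour of the indices under known assembly processes — not
that any particular field system behaves this way.

## Numerical and design choices

* Newick writing is canonical: children ordered by smallest descendant tip
  name, branch lengths at 6 significant digits; missing lengths are a
  distinct absent state, never zero. NEXUS files are accepted on read.
* Name matching is case-insensitive with underscore/space equivalence,
  since field species lists are inconsistently cased.
* The "near-zero" middle level in the gradient-pattern check is defined as
  |mean NRI| < 1.5 over a level's four quadrats: the per-quadrat index is
  approximately standard normal under the null, so 1.5 is three standard
  errors of a 4-quadrat mean.
* Problem sizes used by the verification runs: 1,000 null samples and 999
  replicates for calibration; 200 samples per λ for the knob-recovery
  check; 100 seeded runs (20 in the acceptance script) for the gradient
  pattern.
* Two-sided rank p-values are capped at 1; NRI recomputability
  (−(obs − mean)/SD) is asserted from the stored result fields.

## Known limitations

* Grafting resolves names only through the supplied taxonomy; no synonymy
  service is consulted.
* BLADJ's path rule is one deterministic reading of even spacing; other
  implementations may place undated nodes differently when several dated
  descendants compete, though all consistent tables yield ultrametric
  output here.
* The RDA significance stars use the parametric correlation test, not a
  permutation test; with few samples they are indicative only.
* Polytomy-rich supertrees understate fine-scale distances between
  congeners (all congeners are equidistant), which compresses the range of
  MNTD more than MPD.
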
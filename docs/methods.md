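# Methods

## Data model

A germplasm panel couples three blocks, row-aligned by genotype: nine
continuous agro-morphological traits (DFI, DFC days; PH, HD, SC cm; LA cm²;
LP count; HSW, SYP g), a binary SSR band-presence matrix and a binary
seed-protein band-presence matrix.  Validation rejects duplicate ids,
negative or missing trait values (an explicit column-mean imputation switch
exists but is off by default, since reported trait tables are complete) and
non-binary band entries, naming the offending cells.  Replicated line ×
tester trials are long tables (line, tester, rep, trait, value) and must be
balanced: every missing plot is named.

Cross identifiers are stored as (tester, line) pairs and rendered
"TESTER × LINE" — the pollinator first — matching the convention of the
bundled reference tables.

## Preprocessing

Continuous traits are optionally passed through the Yeo–Johnson power
transform before scaling.  ψ(x, λ) is the standard two-branch map
(((x+1)^λ − 1)/λ for x ≥ 0 with the log limit at λ = 0; the mirrored
(2 − λ)-power branch for x < 0), and λ̂ maximizes the Gaussian profile
log-likelihood, Jacobian included, over λ ∈ [−5, 5] via bounded scalar
minimization (xatol 1e-8); a 10 001-point grid search is the test oracle.
Each column is then min–max scaled to [0, 1]; constant columns map to 0
(kept, with a warning) so column bookkeeping survives degenerate input.
Binary band columns are never transformed — {0, 1} ⊂ [0, 1] already.  The
integrated matrix concatenates [traits | SSR | protein] with per-column
provenance tags; no block weighting is applied, so a 40-marker block simply
carries 40 columns of weight.  Yeo–Johnson-before-min–max is the default
order; the reverse order is exposed as a flag because either reading of
"normalize then scale" is defensible and the choice is recorded in the run
report together with the fitted λ per trait.

## Clustering

All three classifiers operate on Euclidean distances over the integrated
matrix (Ward requires Euclidean geometry; the [0, 1] scaling puts blocks on
a comparable footing).

**Ward.D2.** Agglomeration by the Lance–Williams recurrence on *squared*
distances,
D²(i∪j, k) = [(nᵢ+nₖ)D²(i,k) + (nⱼ+nₖ)D²(j,k) − nₖD²(i,j)]/(nᵢ+nⱼ+nₖ),
with merge heights reported on the distance scale (√D², so two singletons
merge exactly at their distance).  The globally minimal pair merges at each
step; ties break toward the smallest cluster-id pair, making the procedure
deterministic.  Height inversions are impossible for Euclidean input and
therefore warn rather than fail.  The implementation is O(n³), ample for
panel sizes in the hundreds; it matches scipy's `ward` linkage to machine
precision and an exhaustive from-coordinates criterion oracle on small
point sets.

**Tree cutting.** k-mode removes the k − 1 highest merges; height-mode
removes merges above the threshold.  Labels are 1-based in first-leaf
order.  Cutting one tree at k_major and k_sub yields nested major/sub
heterotic groups by construction; the nesting is still asserted.

**k-means.** Lloyd iterations from k-means++ seeds, best of `n_init`
restarts (default 10), convergence on unchanged labels or 300 iterations.
An empty cluster is repaired by reseeding its center at the point farthest
from its current center — deterministic given the state, and logged.

**hkmeans.** The Ward.D2 cut at k supplies centroids for a single Lloyd
refinement with no random restarts, so the hybrid is fully deterministic
and its WSS can only be ≤ that of the hierarchical partition.

**Resolution power.** Purity (fraction of genotypes falling in their
cluster's majority line type) and the Hubert–Arabie adjusted Rand index
computed from the contingency table; both are cross-checked against
counting oracles and scikit-learn.

## Parent selection and cross design

The major cluster with the highest restorer share is restricted to R
candidates and the other to CMS candidates; each sub-cluster contributes
its highest seed-yield (configurable trait) eligible genotype, ties
breaking to the lexicographically smaller id.  B and SFP lines are never
selected — only CMS × R crosses are field-feasible in a male-sterility
system, and this is the package's explicit resolution of what to do when a
sub-cluster's top yielder is neither.  The design is the full factorial
l × t cross list; a parent may not appear on both sides.

## Heterosis

MPH = 100(F₁ − MP)/MP and BPH = 100(F₁ − BP)/BP with BP = max(P₁, P₂)
regardless of trait polarity: for traits where small is agronomically
better (flowering dates, plant height) the convention still uses the larger
parent mean, which is how the reference tables reconcile.  Zero MP or BP is
an error rather than a silent infinity.  When a replicated-trial error mean
square is available the deviations are tested with Var(F₁ − MP) = 3·MSE/(2r)
and Var(F₁ − BP) = 2·MSE/r (each mean is an average of r plots; MP averages
two such means, hence the 3/2 factor), two-sided t at the ANOVA error df —
or the normal reference when σ² is treated as known (`error_df=inf`).
Stars: * p < 0.05, ** p < 0.01.  Means-only input yields `na` flags rather
than fabricated stars.  Reports round to 2 decimals; full precision is kept
internally.

## Combining ability

From the per-trait l × t cross-mean table: gᵢ = Ȳᵢ·· − Ȳ···,
gⱼ = Ȳ·ⱼ· − Ȳ···, sᵢⱼ = Ȳᵢⱼ· − Ȳᵢ·· − Ȳ·ⱼ· + Ȳ···, so
Ȳᵢⱼ· = Ȳ··· + gᵢ + gⱼ + sᵢⱼ holds cell-exactly and all effect sets sum to
zero (asserted to 1e-9).  Parents and reciprocals do not enter the model.
The randomized-block ANOVA partitions total SS into replications (df r−1),
crosses (lt−1) = lines (l−1) + testers (t−1) + line×tester ((l−1)(t−1)),
and error ((lt−1)(r−1)) by subtraction; F-ratios test against the error
mean square.  Standard errors: SE(g_line) = √(MSE/rt),
SE(g_tester) = √(MSE/rl), SE(s) = √(MSE/r), differences √2 larger.  With
means-only input the effects are computed but significance is reported
"unavailable" — no error stratum exists.  Notably, the GCA/SCA values
reported alongside the bundled reference means do **not** reconcile with
these (or any obvious) formulas applied to the printed cross means (e.g.
DFI GCA of CMS-HAP-12: reported 7.65 vs ≈ 2.0 recomputed), so those
reported tables are treated as non-reproducible from the available data;
correctness is governed by the algebraic identities and simulation recovery
instead, and a test documents the discrepancy.

## Synthetic data

The panel generator plants the structure the analysis assumes.  Defaults
describe a 109-genotype panel: 31 restorers (population 1) and 26 each of
CMS, B and SFP (population 2), each population split into 6 sub-clusters by
dealing genotypes round-robin within type so every sub-cluster of the mixed
population contains CMS candidates.  Traits are Normal(cluster mean,
within-SD 1.0 trait unit) around realistic base levels taken from the
bundled parent means, with sub-cluster offsets of δ = 6 within-SD units
along random unit directions and population offsets of 2δ; draws are
clipped at 0 to respect the trait domain (negligible at these settings).
Band frequencies are hierarchical: the two populations take anti-phase
bases 0.5 ± 0.25 per column (`major_band_divergence` = 0.5) and each
sub-cluster shifts its base by ±ε (default 0.4), clipped to [0.02, 0.98].
These defaults make the restorer/non-restorer split dominate — the k = 2
cut and k-means at k = 2 recover it exactly — while the 12 sub-clusters
remain recoverable (Ward.D2 k = 12 ARI ≥ 0.9 across seeds).  Traits are
drawn independently within cluster; real trait covariance, linkage between
markers, multi-allelic SSRs (one column per marker here) and field spatial
effects are *not* simulated, so passing recovery tests demonstrate
correctness of the estimators under the assumed model, not robustness to
real-world noise.

Trials are balanced draws from y_ijk = μ + gᵢ + gⱼ + sᵢⱼ + rep_k + e_ijk
with e ~ N(0, σ²); effects are centered at construction so estimates are
comparable to truth without identifiability caveats.  All generators are
pure functions of their seed.

## Numerical and design choices

- Distances via `scipy.spatial.distance.pdist`; everything downstream of
  the distance matrix is implemented in-package.
- Merge-height ties in Ward break by cluster id; k-means restarts tie-break
  to the first-best WSS; selection ties break lexicographically — all runs
  are bit-reproducible, and the pipeline test hashes entire artifact trees
  to enforce it.
- CSV writers emit shortest round-trip float strings and readers parse with
  round-trip precision, so write → read → write is byte-identical.
- The Newick export assigns branch lengths as height differences, making
  every leaf's root distance equal the root merge height; dendropy parses
  it back in tests.
- Simulation sizes used by the validation suite: 50 seeded point sets
  (n ≤ 8) for the Ward oracle, 10 random 3×3×2 trials for the ANOVA oracle,
  500 seeded 6×6×3 trials (σ = 5) for recovery, 20 panel seeds for
  clustering recovery, 10 000 replicates for t-test calibration.

## Known limitations

- Cut heights are in units of the integrated [0, 1] feature space; they are
  not comparable to dendrogram heights computed on unscaled data, so
  canonical runs cut by k (2 major, 12 sub) rather than by a fixed height.
- Heterosis significance requires replicate-level data; the bundled
  reference means carry none, so stars are only reproduced on synthetic
  trials.
- Economic heterosis over a check cultivar, diallel/reciprocal designs,
  genetic variance components (σ²_A, σ²_D), heritability and path analysis
  are out of scope.
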
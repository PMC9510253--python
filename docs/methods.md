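# Methods

## Hashing model

A patient record is the row vector `V(p_i) = (a_{i,1}, ..., a_{i,n})` of
nonnegative health-monitoring values.  One random hyperplane `V`
contributes the bit `1{V(p_i) · V > 0}`; a dot product of exactly zero
maps to bit 0 (the `<= 0` branch), a convention that only matters on a
measure-zero set for continuous data but is fixed so that ties are
deterministic.  `c` bits form a band code read most-significant-bit
first (bits `(1,1,0)` → 6); `r` band codes form the key of one table;
`k` tables are built.  All `k·r·c` hyperplanes are drawn independently —
sharing planes across bands or tables would correlate the tables and
defeat the OR-amplification.

Two sampling modes exist:

* `uniform` (default): entries i.i.d. Uniform(−1, 1).  Endpoint
  inclusion is immaterial for continuous draws.
* `gaussian`: standard normal entries.  Only this mode is rotationally
  invariant, so the closed form below is exact only here; it is the mode
  used by every test that compares against the closed form.  For fixed
  vectors the two modes give similar but not identical collision
  probabilities, so uniform-mode validation uses Monte-Carlo
  self-consistency instead.

For Gaussian hyperplanes, vectors at angle `θ` share a bit with
probability `p(θ) = 1 − θ/π`; a full key matches with `p^(c·r)` and at
least one of `k` tables matches with `1 − (1 − p^(c·r))^k`.

**Missing entries** are resolved before projection, identically for all
patients: substituted by 0 by default (an unobserved indicator
contributes nothing to any projection) or by the column's observed mean
(`missing_policy="column_mean"`).

**Randomness.** A single root seed derives one independent stream per
(table, band) via `SeedSequence(entropy=seed, spawn_key=(table, band))`,
so enlarging `k` or `r` never perturbs hyperplanes already drawn for
earlier tables — table prefixes nest, which is also what makes the
"edges only grow with k" property testable.

## Clustering semantics

Key equality in any table is a pairwise relation, not an equivalence:
it is reflexive and symmetric but not transitive.  "Put similar
patients in the same group" therefore requires a closure choice, and we
take the transitive closure: clusters are the connected components of
the collision graph, computed by union-find, with group ids numbered by
each component's first patient in matrix order so output is
reproducible.  Patients that collide with no one stay singletons; they
are never force-assigned to a nearest cluster.  This is the package's
key interpretive choice: it maximizes recall and means a *single*
spurious collision merges two whole clusters (see Limitations).

The clustering stage consumes only `IndexTable`/`SimilarityGraph`
objects.  Its serialized input, the index-table JSON, contains patient
ids and band codes (integers `< 2^c`) and nothing else; privacy here
means exactly "only hashes leave the hashing stage" — no cryptographic
guarantee is claimed or implied.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `c` | bits per band | 2 | evaluation setting of the study design |
| `r` | bands per key | 4 | lower end of the studied grid {4,6,8,10} |
| `k` | index tables | 4 | lower end of the studied grid {4,6,8,10} |
| `seed` | root RNG seed | 0 | |
| `hyperplane_distribution` | uniform / gaussian | uniform | definition of the hash family |
| `missing_policy` | zero / column_mean | zero | neutral under projection |
| `mask_fraction` | held-out share of observed cells | 0.2 | standard hold-out; the accuracy protocol is otherwise unspecified in the study design |
| `top_n` | UPCC neighbourhood size | 10 | classical choice for user-based CF |

## Evaluation protocol

The accuracy experiment masks `mask_fraction` of the observed cells
uniformly at random (re-drawing, with a log message, if a patient or
disease would lose its last observation), trains on the rest and
predicts the hidden cells.

* **Cluster predictor**: mean of the target disease's observed values
  over the patient's cluster-mates; if none exists, fall back to the
  disease's global observed mean, then to the overall observed mean.
  Fallback predictions are counted (`n_fallback`).  The clustering
  itself never sees the raw values; prediction necessarily does.
* **UPCC baseline**: Pearson correlation over co-observed diseases
  (fewer than two co-observed cells, or zero variance, gives similarity
  0); prediction is `r̄_u + Σ_v sim(u,v)(a_{v,j} − r̄_v) / Σ_v |sim(u,v)|`
  over the `top_n` most-similar patients with positive similarity and an
  observed value at `j`, with the same fallback chain.
* **Cost proxy**: wall-clock comparisons are hardware-bound, so the
  harness counts similarity operations — `(m − 1)` Pearson pairs per
  test patient for UPCC, and `Σ_tables Σ_buckets C(|bucket|, 2)`
  enumerated pairs for the index-based method.  Wall-clock is not
  reported.

Each repetition draws its own mask and its own hyperplane bank (both
derived deterministically from the configured seed and the run seed);
reports are arithmetic means over repetitions.  Per-seed vectorized
prediction paths are tested cell-by-cell against the scalar
definitions.

## Synthetic data

The generator emulates a matrix-structured benchmark with planted
structure: `g` groups, each with a disjoint block of `⌊n/g⌋` "signature"
diseases; centroid entries on the block are `centroid_scale ·
Uniform(0.5, 1.5)`, zero elsewhere; patients are centroid plus
`N(0, noise_sd²)` noise clipped at 0; cells are masked missing at
`missing_rate`.  Disjoint supports make centroids pairwise orthogonal —
the widest separation nonnegative data admit — and the requested
`min_centroid_angle` is verified after drawing (values above π/2 raise
a generation error, as no nonnegative construction can satisfy them).
Angular rather than Euclidean separation is the difficulty knob because
the hash is scale-invariant.  Defaults are 300 patients × 5000
indicators in 4 equal groups, `centroid_scale` 10, `noise_sd` 0.5
(5% of scale — clearly separable), no missingness.

What the generator does **not** emulate: realistic marginal
distributions, correlated indicators, heteroscedastic noise, structured
(non-uniform) missingness, or unbalanced group sizes beyond what
`group_sizes` is explicitly given.  Passing tests therefore demonstrate
the mechanics and the probability model of the hash, not clinical
performance.

## Problem sizes used by the test suite

The suite and the acceptance script run reduced instances chosen to
exercise the same regimes at interactive cost: the planted clustering
fixture is 200 × 120 (50 patients per group — large enough for bucket
statistics to behave as at full scale, since collision probabilities
depend on angles, not on `n`), and the prediction comparison runs at
the full 300 patients but 400 indicators with 3 mask repetitions.
Monte-Carlo validations use 10⁴ hyperplane draws, giving standard
errors below 0.005.

## Numerical choices

* Bit order MSB-first; tie (zero dot product) → bit 0.
* Band codes and keys are plain Python ints/tuples; serialized JSON
  preserves patient order so clustering from a loaded file reproduces
  in-memory group numbering byte-for-byte; floats are written with
  shortest round-trip `repr`.
* Pearson degeneracy: similarity 0 for < 2 co-observed cells or zero
  variance; the vectorized route guards with a relative-variance
  threshold (1e-12) and clips to [−1, 1].
* UPCC neighbour ties are broken by patient position after similarity,
  so rankings are deterministic.
* Union-find uses union-by-size with path compression.

## Limitations

* **False-positive floor on nonnegative data.**  Nonnegative vectors
  can be at most orthogonal, so a cross-cluster pair's per-table
  key-match probability never falls below `2^−(r·c)` (1/256 at the
  studied `c = 2, r = 4`).  Under transitive closure one collision
  merges two clusters; with 4 planted groups and `k = 8` tables this
  happens in a large fraction of runs even at 5% noise, which the
  acceptance script quantifies (`planted_ari_*` entries).  Raising `r`
  or `c` suppresses it exponentially.
* **More tables can hurt.**  On a low-noise separable fixture,
  within-group recall saturates at `k ≤ 2`; additional tables then only
  add false positives, so clustering quality is non-*increasing* in `k`
  in that regime.  OR-amplification pays off only when false negatives
  dominate (high noise or very small groups).
* **Sparse or masked data scatter keys.**  Treating missing entries as
  0 perturbs angles; at 20% masking the within-group per-table collision
  probability drops enough that patients spread over many keys, and the
  accumulated cross-collisions can percolate into one giant cluster.
  The cluster predictor's MAE is accordingly well above the exhaustive
  Pearson baseline's in the masked-prediction experiment — the accuracy
  vs. cost trade the harness is built to expose.
* Index construction is `O(m·n·c·r·k)` work; no sub-linear or "offline,
  near-zero" cost is claimed for it.  The `O(1)`-per-query behaviour
  applies to bucket lookups, not to building the tables.
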
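# Methods

This note documents the statistical model the package estimates, the
conventions every estimator follows, the synthetic generative model and its
exact oracle, and the numerical/design choices that were genuinely open.

## The learning matrix

For a player with attempts recorded as (region, outcome) sequences, define

- `P_j` — the prior probability of attempting a field goal (FG) from region
  `j`, estimated from **all** of the player's included attempts;
- `P(j|S_i)`, `P(j|F_i)` — the probability that the next within-game attempt
  is from region `j`, given the previous attempt was made (`S`) or missed
  (`F`) from region `i`.

The learning matrix is

    L_ij = ( P(j|S_i) − P(j|F_i) ) / P_j .

`L = 0` identically for outcome-insensitive (memoryless) behavior. A pure
win-stay/lose-shift player has positive diagonal and non-positive
off-diagonal entries. `L_ij > 0` for `i ≠ j` means outcomes in `i`
*generalize* to subsequent attempts from `j`. The normalization by `P_j`
makes entries comparable across regions with very different base rates: the
entry is the outcome-induced change in the next-shot probability *relative*
to the base rate.

Two scalar summaries are used throughout: the **diagonal mean** of the
cohort-averaged matrix (overall win-stay/lose-shift tendency) and the
**off-diagonal SD** (spatial heterogeneity of generalization).

### Estimation conventions

- A "player" is a player-season; players are never pooled across seasons.
- Pairs are within a game only: the outcomes of attempts `1..N−1` condition
  the locations of attempts `2..N`. Nothing crosses a game boundary.
- "Previous FG" is the player's own immediately preceding attempt in that
  game, regardless of intervening events.
- The prior `P_j` uses all included attempts (positions `1..N` of every
  game), not only consequents. The conditionals use only antecedent-consequent
  pairs. The two choices are consistent in the one-step generative model
  below, where the conditional rows are position-independent.
- Attempts outside every region of the map (`< 1%` in realistic data) are
  dropped *before* pairing; consecutive surviving attempts form the pairs.
- Cohort statistics weight every player equally; uncertainty is the SEM over
  players with the `n−1` sample SD. Duplicating data *within* a player
  changes nothing (asserted by test).
- Fine selection: a player-season enters the 16-region analysis only with at
  least `min_per_region` (default 10) attempts from every region **and** a
  fully defined matrix (≥1 made and ≥1 missed antecedent from every region).
  A player with any ill-defined row is excluded from that analysis entirely.
- The coarse 3×3 matrix (groups THREE / LONG2 / SHORT2) is **re-estimated on
  grouped events**, not aggregated from the 16×16 matrix: the index is
  nonlinear in the probabilities, so the two differ. If a map contains no
  region of some group, the coarse label set shrinks accordingly.

## Court geometry and the default region map

Coordinates are continuous feet; origin at the baseline–long-axis
intersection; basket at `(0, 5.25)`. The 3 pt line is an arc of radius
23.75 ft joined to straight corner segments at `|x| = 22`; a shot between 22
and 23.75 ft from the basket is therefore a 2 or a 3 depending on angle.
All constants live in `CourtSpec` (other leagues' lines can be modeled).

The default 16-region `SectorRegionMap` is a parameterized reconstruction —
a central disc (radius 8 ft, label 16), five angular sectors (edges 0°, 30°,
75°, 105°, 150°, 180° measured from the right baseline), and three radial
bands per sector: short-2 (to 16 ft), long-2 (to the actual 3 pt line), and
3 pt (line to 30 ft). Its structural invariants — pairwise disjointness,
THREE = {1,4,7,11,14} strictly beyond the line, LONG2 = {2,5,8,12,15},
SHORT2 = the rest — are what the analyses rely on; the exact polygon shapes
are a modeling choice, and every analysis accepts a user-supplied map. The
map is analytic (each point maps to exactly one region), so the
lowest-label-wins boundary rule only matters for user maps with overlapping
predicates, where `assign` scans regions in ascending label order.

## Clustering

Prospective similarity compares the **rows** of the averaged matrix (how a
region's outcomes redistribute future attempts); retrospective similarity
compares its **columns** (how a region is affected by outcomes everywhere).
Because the matrix is asymmetric the two are logically distinct analyses.

Ward linkage is computed from cluster centroids:
`d(A,B) = sqrt(2 n_A n_B / (n_A + n_B)) · ‖c_A − c_B‖`. The square-root form
is the default because it reduces to the plain Euclidean distance for
singleton clusters, putting dendrogram heights on the scale of the reported
dissimilarity matrix; the squared variant (`form="squared"`) produces the
same merge order with squared heights. Exact distance ties are broken by the
lexicographically smallest cluster-id pair, making output deterministic.
Implementation is the O(n³) centroid recomputation — intended for
region-scale inputs (n ≤ dozens), verified against an exhaustive
re-derivation and against SciPy's Ward heights.

Row vectors enter the dissimilarity with all coordinates, including the
self-coordinate (`include_self=False` drops the diagonal entry, as a
sensitivity option). Flat partitions cut the `k−1` highest merges (Ward
heights are monotone).

## Permutation tests and the sign test

The surrogate null destroys outcome dependence while preserving marginals:
per player, the consequent of every within-game pair is replaced by an
independent draw from that player's estimated prior; antecedents and the
game skeleton are untouched, and the surrogate learning index reuses the
player's original prior estimate. The p-value is the fraction of `n_rep`
(default 10⁴) repetitions whose surrogate statistic **strictly exceeds** the
observed one; ties count as non-exceeding (the conservative direction), and
`p = 0` is reportable only as `p < 1/n_rep` (the floor is included in every
result record).

Because the surrogate statistics depend on the redrawn tables only through
per-(antecedent-row) multinomial counts — or per-bin binomial counts for the
distance-bin tests — repetitions are sampled directly from those
distributions instead of materializing 10⁴ tables. This is distributionally
identical to the explicit surrogate and orders of magnitude faster;
`surrogate_table` still materializes explicit surrogate tables for
inspection and unit tests. Null calibration (uniform p-values) is verified
in the acceptance suite.

The sign test on the diagonal is the exact one-tailed binomial upper tail,
computed by direct summation of `C(n,k) p^k (1−p)^(n−k)` terms.

## Distance curves, returns, matching

Attempts are sorted into half-open 2 ft distance bins over 2–30 ft by
default, **separately** for 2 pt and 3 pt attempts; the 22–24 ft bin pair
straddling the line is the corner/arc dissociation probe. Per player and
bin-cell the scalar learning signal is
`P(next FG is 3 pt | make) − P(next FG is 3 pt | miss)` (the consequent's
recorded point value is used; a mismatch against the geometry triggers a
warning), the difficulty proxy is makes/attempts, and curves are equal-weight
player means with SEM. Selection follows the ≥1-make-and-≥1-miss-per-cell
rule over the cells that are non-empty cohort-wide; players whose
conditionals are undefined in a particular cell are skipped in that cell and
the per-cell `n_players` is reported.

The return of an FG is the number of points the shooter's team gained from
the attempt until the opponent gained possession (its own points if made,
plus e.g. putback points before the change of possession).
`compute_returns` derives returns by walking explicit possession logs;
synthetic tables carry returns generated by the possession model directly.
Matching is summarized per player by the fraction of 3 pt attempts against
the fractional 3 pt income, and at cohort level by the mean absolute
deviation from the matching diagonal; equal per-attempt returns in the two
classes place a player exactly on the diagonal (an algebraic identity,
asserted by test).

## The synthetic generative model

### ONE_STEP mode

Regions are abstract states with an emit point (a fixed representative
interior point of the corresponding court region), a base weight `w_r` and a
make probability `q_r` (by default the decreasing difficulty profile
`q(d) = 0.63 − 0.0105 d`, clipped to [0.05, 0.95] — ≈0.6 at the rim, ≈0.39
at the arc). The first attempt of each game samples a region ∝ `w`; after an
attempt from `i` with outcome `o`, the next attempt samples from the softmax
of `log w ± η K_i·` (`+` for make, `−` for miss), after which the policy
resets to `w` (one-step memory). Outcomes are Bernoulli(`q_region`); returns
are point value if made, otherwise a 2 pt putback with probability
`putback_prob` (default 0.1).

The multiplicative-exponential update keeps every pipeline statistic exactly
computable. The chain on (region, outcome) states has transition
`P((i,o)→(j,o')) = P(j|i,o) · q_j^[o'=S] (1−q_j)^[o'=F]` with `P(·|i,o)` the
softmax rows. `oracle_statistics` iterates it from the base-policy law of a
game's first attempt to obtain the exact position marginals, hence the exact
prior (averaged over the `shots_per_game` positions, exactly what the prior
estimator measures), the exact antecedent weights used to pool conditionals
over groups or distance bins, the exact fine and coarse learning matrices,
binned learning differences, per-class returns, and the stationary law (for
balance diagnostics). For small `η`,
`L_ij ≈ 2η (K_ij − Σ_k P_k K_ik)` — the kernel is identifiable from the
matrix up to its row means.

Two reference scenarios are provided:

- `planted_paper_scenario` — a categorical 2 pt/3 pt group kernel
  (rows × THREE/LONG2/SHORT2: `[[1.2, 0, .15], [.15, .45, −.3], [0, 0, .1]]`,
  `η = 0.3`) whose oracle coarse matrix has a dominant (THREE, THREE) entry,
  a positive (LONG2, LONG2) at the expense of (LONG2, SHORT2), and small
  short-2 effects; two emit points are placed at 23.1 ft (corner three) and
  22.7 ft (deep corner two) so the 22–24 ft bin contains both classes with a
  large learning contrast (oracle ≈ 0.124 vs 0.019) and a tiny difficulty
  contrast (|Δq| ≈ 0.004).
- `three_block_scenario` — within-group kernel 1, between-group 0: sharp,
  equal-magnitude block structure in every row and column; the reference for
  estimator-consistency and cluster-recovery checks.

Default cohort sizes (100 players × 50 games × 20 shots ≈ an NBA season's
FG volume per player) are the stated world for the calibration and
dissociation checks. The cohort-of-3 cluster-recovery check uses 800 games
× 20 shots per player: a design-time power analysis (per-entry noise scales
as `(1/P_j)·sqrt(p(1−p)/n_pairs)`, so small-prior regions need ~10⁴ attempts
before the block signal dominates Ward distances) showed ~16,000 attempts
per player give recovery with a comfortable margin over the 95% requirement;
this is a synthetic identifiability setting, not a claim about season-scale
data volumes.

### MELIORATION mode

Two choice classes (2 pt at 5–20 ft, 3 pt at 23.9–27 ft on the center axis)
with diminishing returns: `q₃ = 0.36 − 0.30 f₃ − 0.01 (d − d̄₃)` and
`q₂ = 0.50 − 0.10 f₂ − 0.01 (d − d̄₂)`, where `f_c` is the player's recent
attempt frequency of class `c` (EMA, α = 0.02). Each player tracks EMA
per-attempt returns of both classes and drifts the 3 pt propensity `θ` by
`Δθ = λ (R̂₃ − R̂₂) θ(1−θ)` (λ = 0.01, clipped to [0.02, 0.98]) — melioration
dynamics whose fixed point equalizes class returns, i.e. the matching law.
With the default putback rate the deterministic fixed point is `f₃* ≈ 0.28`
with per-attempt return ≈ 0.9. Because `q` also falls with distance within
each class, returns at 2 ft resolution remain unequal at equilibrium — the
coarse-matching/fine-violation pattern. Equilibrium statistics discard a
2,000-shot burn-in (`discard_burn_in`).

### What the generator does not emulate

Shots are emitted at fixed per-region points, so within-region and
within-bin location scatter is absent; there are no defenders, teammates,
free throws, shot-clock or score context, and no cross-game carry-over of
the one-step policy. Cohorts are homogeneous (players share parameters) and
players are simulated in lockstep from a single seeded stream. A green test
therefore establishes that the estimators recover a known one-step
generative structure at realistic sample sizes — not that real behavior has
that structure.

## Numerical and statistical choices

- Softmax rows are computed with max-subtraction; the oracle's stationary
  law comes from the unit left eigenvector, checked against the balance
  equations to 1e-10.
- Aggregated oracle-agreement checks use a joint z,
  `sqrt(Σ dev² / Σ sem²)`: across the 256 entries of a fine matrix a
  per-entry 3-SEM gate would fail a perfect estimator roughly half the time
  (≈0.7 expected chance exceedances), while the joint z concentrates near 1
  under agreement and grows with any systematic bias. Per-entry 3-SEM gates
  are retained where the entry count is small (coarse 3×3, single bins).
- Monte-Carlo p-values are granular (`k/n_rep`); the uniformity check uses a
  KS test, whose bias from granularity at `n_rep = 200` is far below the
  α = 0.01 critical distance with 200 runs.
- `order_in_game` is 1-based; boundary distances use half-open bins
  `[lo, hi)`; absent returns are NA, never 0.

## Known limitations

- The default region map is a structural reconstruction, not a tracing of
  any particular published partition; analyses on real data should supply
  the partition actually used.
- The permutation machinery assumes the statistic depends on the data only
  through the per-player count tables it redraws; custom statistics need the
  explicit `surrogate_table` route.
- The O(n³) Ward implementation is deliberate (determinism, tie-break
  contract) and unsuitable for thousands of leaves.
- Oracle values for distance bins assume bins align with emit-point
  distances; a bin boundary crossing an emit point's distance is a user
  error the oracle reports as an empty bin.
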
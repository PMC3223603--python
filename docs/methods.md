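# Methods

## Gaussian representation and overlap integrals

Every heavy atom is one spherical Gaussian
`rho_i(r) = p * exp(-kappa_i * |r - r_i|^2)` with amplitude `p = 2.7`
(dimensionless) and decay `kappa_i = pi * (3p / (4 pi R_i^3))^(2/3)`,
chosen so that the isolated-atom density integral `p (pi/kappa)^(3/2)`
equals the hard-sphere volume `4/3 pi R^3`.  All heavy atoms share the
carbon-convention radius R = 1.70 Å (`kappa ≈ 0.8112 Å⁻²`); hydrogens are
dropped at ingest and contribute nothing.  Feature ("color") points use
the same amplitude with R = 1.0 Å (`kappa_c ≈ 2.344 Å⁻²`).  All three
parameters are configurable (`ScoringConfig`).

Score volumes are *product-density* integrals,
`V_AB = Σ_{i∈A, j∈B} p² (pi/(kappa_i+kappa_j))^{3/2} exp(-kappa_i kappa_j/(kappa_i+kappa_j) d_ij²)`,
first order only (no triple-overlap corrections).  This convention makes
the Tanimoto of an identical pair exactly 1 and keeps the objective
smooth and analytically differentiable.  Sums run over all atom pairs
exactly; terms whose exponent argument exceeds 30 may be skipped
(relative error < 1e-13).  A grid-quadrature oracle
(`grid_overlap_oracle`, product density on a regular grid with 4 Å
padding) exists purely for testing and agrees with the analytic integrals
to well below 1% at 0.1 Å spacing.

The *descriptor* volume is a different quantity: the first-order
inclusion-exclusion volume `Σ_i v_i − Σ_{i<j} V^prod_ij` with
`v_i = 4/3 pi R³`, reported per conformer alongside the shape quadrupole.
The quadrupole is the set of principal second moments (Qx ≥ Qy ≥ Qz,
Å⁵) of the summed Gaussian density about its centroid — no mass
weighting, no trace removal — giving a sense of conformer length, width
and height.  Both descriptors are rigid-motion invariant; both are
validated against grid quadrature.  Note the quadrupole normalization is
one of several defensible conventions, so its absolute scale should only
be compared within this package.

## Similarity scores

- `ST = V_AB / (V_AA + V_BB − V_AB)` on atom Gaussians; clamped to
  [0, 1] against roundoff.
- `CT`: per-type feature overlaps are summed over the six independent
  types (donor, acceptor, cation, anion, hydrophobe, ring) and combined
  as one Tanimoto (sum-then-Tanimoto, the standard color construction),
  not a mean of per-type Tanimotos.  Cross-type overlap is identically
  zero.  When both conformers are featureless `CT := 0` (so pure
  hydrocarbons score 0, matching the behaviour expected of random pairs).
- `ComboT = ST + CT`, computed from the final ST/CT values with no
  rescaling, so the sum identity is exact bit for bit.

## Superposition optimization

Six rigid degrees of freedom (rotation vector, translation) are locally
maximized with L-BFGS using analytic gradients; the rotation gradient
uses the right Jacobian of SO(3) and is verified against finite
differences in the tests.  Rotation is taken about the centroid of the
moving conformer, which decouples the rotational and translational
parameters.  Convergence: relative objective tolerance 1e-10 (about
1e-8 Å³ at typical overlap magnitudes), gradient tolerance 1e-8, at most
200 iterations; non-converged local searches return best-so-far and are
flagged on the record.

Start poses: both conformers are moved to their inertial frames
(principal axes of the Gaussian density second moments, descending; sign
convention: each axis's largest-magnitude component positive, third axis
flipped if needed to keep det = +1, so the pose is deterministic even for
degenerate spectra), and the four proper axis-flip relative poses seed
the shape search.  The color search adds, per shared feature type, a
translation-adjusted start aligning that type's centroids.  Improper
(mirror) poses are not searched.  Ties between converged starts are
broken by larger objective, then by the *other* channel's overlap at the
candidate pose (shape overlap for the color search and vice versa — this
settles degenerate optima such as a single shared feature point, for
which any pose that superposes the feature maximizes CT), then by
lexicographically smaller canonical quaternion, making records bitwise
reproducible.

`score_pair` additionally cross-seeds the two searches with each other's
final poses, iterated to a fixed point (at most five rounds, normally
one).  This is a deliberate design choice: it guarantees — rather than
merely makes likely — the argmax inequalities
`ST(shape-opt) ≥ ST(color-opt pose)` and `CT(color-opt) ≥ CT(shape-opt
pose)` that define the six-measure table.  If either conformer lacks
features the color result is the shape pose with CT = 0.

Scores are never rounded internally; serialization rounds scores to 4
decimal places (half-even) and transforms to 6, and the stored ComboT
column is the exact sum of the stored ST and CT columns so written files
are self-consistent.

## Assay statistics

Outcome classification is deliberately inclusive: only a case-insensitive
"inactive" is inactive; active, inconclusive, probe and unspecified are
all *noninactive*.  A compound reported with conflicting outcomes within
one assay resolves to noninactive (any non-inactive report wins) with a
logged warning.  NN pairs are unordered pairs of distinct noninactives,
NI pairs cross noninactive with inactive; inactive-inactive pairs carry
no signal for the question asked and are dropped.  Assays need at least
six NN and six NI pairs to enter the analysis (configurable).

Per assay and measure: `mu_diff = mu_NN − mu_NI`, which equals the mean
of all `n_NN × n_NI` cross differences exactly (asserted in tests);
`sd_diff = sqrt(sd_NN² + sd_NI²)`, the exact SD of that full
cross-difference population (a pooled `sqrt(sd_NN²/n_NN + sd_NI²/n_NI)`
variant is available by configuration).  All SDs are population SDs
(divisor n), treating the assay's pair set as a fixed finite population;
a sample-SD switch exists.  Cross-assay aggregation reports the mean and
SD of the per-assay means and SDs, per measure and pair class, for each
assay category (screening, confirmatory, summary, other, unspecified)
and overall.

Outliers: an assay is an upper-bound (lower-bound) outlier for a measure
when its `mu_diff` exceeds (falls below) `mu ± k·sigma` of `mu_diff`
across all eligible assays; k = 1 by default.  The report carries all six
measures so cross-measure and cross-optimization overlaps can be counted
directly.  Zero variance across assays yields empty outlier sets with a
warning.  Ranking averages the two ComboT separations
`(mu_diff^ST-opt + mu_diff^CT-opt)/2`, descending.

Histograms bin scores in 0.01 increments with round-half-to-even bin
assignment (C `rint` semantics); reported values round half-even to 2
decimals.  Significance thresholds are `mu + k·sigma` with the covered
fraction of scores; the chance-neighbor probability follows the
tail-product convention (the two tail percentages multiplied directly
and quoted in percent, capped at 100), with the companion count
"1 in round(100/P)".  Pair-graph connectivity at a score threshold is
computed as connected components over all compounds appearing in the
records.

## Synthetic data

The generator emulates a compound archive at desk scale.  Conformers are
self-avoiding chains: successive bonds of 1.54 Å, bond angles 109.5° ±
10° (normal jitter), uniform dihedrals, minimum non-bonded distance 2.0
Å enforced by rejection (60 placement attempts per atom, 50 chain
restarts, then error).  Elements are carbon with 25% probability of N/O
substitution — enough chemical flavour for feature placement without
perception chemistry.  Heavy-atom counts are drawn from a rounded normal
(mean 24.6, SD 6.4) truncated by rejection to [5, 50], so every generated
compound passes the eligibility rules (single component, organic
elements, ≤ 50 heavy atoms, ≤ 15 effective rotors, ≤ 5 undefined
stereocenters).  Features are generator-assigned, one atom per feature,
with per-type counts from truncated normals at rates acceptor 2.9 ± 1.6,
donor 1.1 ± 1.0, anion 0.2 ± 0.4, cation 0.6 ± 0.8, hydrophobe 0.3 ±
0.6, ring 3.0 ± 1.2.  Explicit feature assignment deliberately decouples
the statistical pipeline from any particular feature-perception scheme.

Assay studies come in two modes.  *Null*: tested compounds are an i.i.d.
draw from the population and the noninactive labels are arbitrary, so NN
and NI score distributions coincide by construction — the pipeline's
null calibration.  *Clustered*: the noninactives are jittered copies
(per-coordinate Gaussian noise, default SD 0.25 Å; features follow their
member atoms and are kept with probability 0.9) of one or two template
conformers, modelling a compound series; inactives come from the
background.  Ground-truth mode labels are returned for recovery
experiments.  All draws flow through a single seeded generator in a
fixed, documented order, so studies are bitwise reproducible.

What the generator does *not* model: realistic torsional ensembles,
rings and branched topologies, 2-D structure, potency values, assay
noise or false positives/negatives.  Passing the null-calibration and
recovery tests therefore shows the statistical machinery is sound and
sensitive to genuine 3-D relatedness of the kind injected — not that any
particular real archive separates actives from inactives.

## Problem sizes and numerical conventions

The shipped statistical experiments use desk-scale study conditions
chosen once: populations of ~120 compounds, 50 assays of 5 noninactives
and 7 inactives (10 NN, 35 NI pairs each — comfortably above the
six-pair eligibility floor), clustered-mode noise 0.25 Å.  Optimizer
determinism plus the fixed start set make all derived tables exactly
reproducible for a given seed.  Degenerate inputs are handled
explicitly: empty conformers are rejected at construction; single atoms
take the identity principal pose; featureless sides force CT = 0 with
the denominator reducing to the featured side's self overlap; zero
across-assay variance disables outlier extraction with a warning.

## Known limitations

- No numeric parity with any proprietary shape toolkit is promised: the
  Gaussian parameters, start-pose scheme and optimizer are this
  package's own (published conventions, unpublished elsewhere).
- Single conformer per compound throughout; best-pair selection over
  conformer ensembles is out of scope.
- The statistical framework is the mu ± sigma heuristic it implements —
  no hypothesis testing or multiple-testing correction.
- The SDF feature tag is this package's dialect (count line plus
  "k a1 ... ak type" rows over heavy-atom indices); only V2000 records
  are read.
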
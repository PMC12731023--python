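# Methods

## Scope and data situation

The package implements a decision-analysis pipeline for ankle-joint
rehabilitation.  The clinical study it reimplements enrolled 100 patients
whose data exist only as printed summary tables (baseline proportions,
conditional probabilities, post-intervention posteriors, factor scores);
no record-level data are deposited.  The package therefore treats those
printed tables as inputs — shipped verbatim under `bigrehab/data/` with
provenance notes — and supplies a seeded synthetic-cohort generator so the
full pipeline is testable.  Quantities that depend only on printed inputs
(the goal-posterior marginalisation, the mobility count, the entropy
worked example) are reproduced exactly; cohort-level clinical outcomes are
not independently reproducible and are covered instead by property tests
(oracle cross-checks, parameter recovery, convergence).

## Network model

Eleven discrete nodes: injury grade `P1` ∈ {Level I, II, III} (coded
0/1/2); repair states `R1` (talocrural) and `R2` (subtalar), recovered=0 /
impaired=1; functional states `B1–B4` with 0=normal, 1=mildly, 2=severely
restricted; goals `G1–G4` with 0=achieved, 1=not achieved.

Structure: `P1 → {R1, R2}`; each functional node has a single repair
parent chosen anatomically — flexion–extension (`B1`) and stretch (`B4`)
under the talocrural joint, inversion–eversion (`B2`) and rotation (`B3`)
under the subtalar joint; every goal node has parents `{R1, R2}`.  The
single-parent assignment for the `B` nodes is a design choice: the
product-form repair update `P(R=r|b) ∝ P(R) Π_j P(B_j=b_j|R=r)` is exact
under it, and only this direction is quantified by the printed conditional
tables.  Rotation is anatomically a coordinated motion of both joints;
assigning it to the subtalar node keeps the model tractable and is
configurable.

Parameter learning is maximum likelihood with an optional Dirichlet
pseudocount α added to every cell (α=0 reproduces the pure MLE; pipeline
runs default to α=1).  A parent stratum with zero observations at α=0 is
filled uniform and a warning emitted.  Overfitting control follows the
train/validation split: a patient-level split, the largest absolute
train-vs-full CPT cell difference, and the validation log-likelihood under
the train fit.

### Inference

Two exact algorithms are implemented and cross-checked to 1e-10 on random
networks: full joint enumeration (the 11-node joint has 3·3⁴·2⁶ = 15,552
entries) and variable elimination.  `exact_inference` picks enumeration
automatically while the joint stays below 2×10⁵ entries and elimination
beyond.  All products are computed in linear space: no factor in these
networks is below ~10⁻³, so float64 cannot underflow at ≤11 factors; this
was preferred over log-space for simplicity.

The hierarchical session update mirrors the clinical update order:

1. **Observation nodes** — `B` marginals replaced by batch frequencies.
2. **Intermediate nodes** — per observed functional configuration, the
   Bayes-rule inversion above; batch-level repair marginals are the
   count-weighted average over configurations.
3. **Target nodes** — `P(G=g) = Σ_{r1,r2} P(G=g|r1,r2) P(r1) P(r2)`,
   treating the repair nodes as independent marginals.  This independence
   product is deliberate: the published goal posteriors are reproducible
   only under it.  `exact_inference` does not assume it, and the two
   routes agree exactly on structures where the assumption holds (tested
   on such fixtures); on the default network with a shared grade parent
   they diverge slightly, which is visible rather than hidden.
4. **Grade node** — no printed formula exists for this step; the package
   reweights the grade prior by the expected likelihood of the repair
   posteriors (a soft-evidence update), documented here as an
   implementation choice.

### Reference-table handling

The printed tables contain internal inconsistencies, preserved rather
than reconciled: the baseline table lists one state-probability per node
(loaders spread the remaining mass equally and flag it imputed; two rows
reference a state outside their node's coding and are kept with notes);
the posterior table prints two rows labelled for the talocrural joint (the
second is read as the subtalar joint) and one pair sums to 0.996
(renormalisation is a switch, off by default); the weight-bearing goal
column prints duplicated achieved/not-achieved values and is loaded as
achieved-probability p with complement 1−p, flagged corrected.  The
published entropy table's gains are consistent with a dataset entropy of
1.492 bits, not the separately printed 1.58; only the internal-consistency
property (IG + conditional entropy constant across features) is asserted.

## Information gain

Base-2 entropies with the 0·log 0 := 0 convention; empty strata contribute
nothing.  Continuous measurements are refused and must be discretised at
explicit cut-points first, mirroring the three-level ordinal clinical
coding.  Rankings break exact ties toward the feature listed first so
reports are deterministic.

## Strategy layer

Goal priorities use `score(G achieved) × P(G not achieved)` — the expected
scoreable gain from flipping the goal.  The scoring framework assigns
weights only to achieved goal states (the intervention priority of an
unachieved state is implicit in its achieved weight), so the score table
validator rejects scores on unachieved goal states.  The rule is the
minimal one consistent with that framework; it is invariant under positive
rescaling of the scores.

Action selection maximises summed expected information gain over the
query set {grade, four goals} (configurable), computed via exact
inference; EIG equals conditional mutual information and is verified
against enumerated joints.  CPT recalibration in the session loop uses
cumulative counts with the loop's pseudocount rather than sliding windows
— the simplest rule consistent with dynamic recalibration, and one whose
drift provably shrinks as counts accumulate (tested).  Ties everywhere
break toward the lowest node index.

## Synthetic cohorts

Ancestral sampling through the generative network (grade → repair →
functional/goal states).  The grade prior defaults to the printed baseline
(0.22 Level I; the remainder split equally as the printed table lists only
one state per node).  The repair and functional CPTs are never printed;
the shipped defaults were chosen to (a) reproduce the printed baseline
marginals to within ~0.01–0.03 (repair achieved 0.304 vs the stated 31%,
functional-state marginals within 0.01) and (b) emulate the stated feature
structure — pain and swelling only weakly grade-informative, stability
moderate, functional limitation the most discriminative.  They are inputs,
not claims.

Ordinal features: `A4` (functional limitation) is the deterministic map of
the worst functional state; `A1–A3` are drawn from grade-conditioned
tables.  The "weak feature correlation" mechanism fires per record with
probability `discordance_rate` (default 0.1) and forces either swelling
high or pain low regardless of grade — the discordant clinical
presentations the feature-selection stage must tolerate.  Discordance
touches only feature fields, never node states, so network learning is
unaffected by it (tested).

Signals: EMG features and trajectory error are state-conditioned
Gaussians whose means shift monotonically with functional severity
(trajectory error truncated at zero).  The study names these signals but
gives no distributions; the defaults are documented placeholders in
arbitrary units and millimetres.

Sessions: each transition moves every repair/functional/goal state one
step toward recovery with its class's probability (default 0.133 per
weekly block for all three classes, chosen so a 20% goal-achievement
baseline reaches ~66% after six blocks via `a_t = 1 − (1−a₀)(1−p)^t`,
matching the reported six-week improvement trajectory).  Both the
100-patient cohort and the 40-patient entropy-example cohort sizes are
plain spec parameters.

Determinism: one counter-based Philox stream per master seed, vectorised
across patients; identical seeds give bit-identical cohorts at any size.

**What passing tests do and do not show.**  The generator reproduces the
marginal structure, the qualitative feature-information ordering, and the
improvement trajectory of the study — not real clinical correlations.  In
particular the absolute information gain of functional limitation (~0.2
bits at the defaults) is bounded by the strength of the
grade→repair→function chain and stays below the published 0.591 bits;
tests that pass on synthetic cohorts validate the machinery, not clinical
effect sizes.  No dropout, sEMG waveforms, or biomechanically realistic
gait are modelled.

## Kinematics

Screws are stored in Plücker ray coordinates (axis; moment); the
reciprocal product interchanges the triples, and reciprocal systems are
computed as the SVD null space of the interchanged matrix.  The branch
screw system's Hooke-position parameters are never given numerically, so
tests sample generic values and verify the structural result: a
one-dimensional constraint system spanned by the x-axis couple, hence
6 − 3 = 3 parallel DoF, agreeing with the Kutzbach–Grübler count
(n=8, g=9, Σf=15, v=0).

Inverse kinematics solves the per-branch quadratic
`|c_i − m_i M_i| = e_i` with `c_i = P + R f_i − n_i`.  Root choice: a root
inside the stroke limits; if both qualify, the nearer to the previous
stroke (trajectory continuity), else the smaller.  Platform attachment
offsets are stored in the moving frame and rotated to the fixed frame at
the current pose wherever they enter a Jacobian — the source leaves frames
implicit, so this is stated once and used consistently.  Accelerations
differentiate `ṁ = (u·E)/(M·E)` directly, with rod angular velocity
`w = E × (u − ṁM)/e` under the no-spin convention (the spin of a UU rod
about its own axis is unobservable); the printed acceleration expressions
mix symbols without defining the pedal angular rate, and the implemented
reading identifies pedal, platform, and the undefined intermediate
angular velocity, verified against finite differences rather than symbol
matching.  Singularity guard: `|M_i·E_i| < 1e-8` (rod orthogonal to its
drive axis) raises rather than returning amplified rates.

The default geometry (symmetric 120° branches, 0.12 m base / 0.08 m
platform circles, 0.20 m rods, 0.30 m strokes) is illustrative — the
published design prints no dimensions — scaled to the device's 20–30 cm
foot-length range.  ROM limits ship in three presets because the sources
disagree on external rotation (10° in the tabulated limits, 50° in the
design prose): `physiological`, `physiological_extended`, and `gait`,
with gait bounded by physiological.

## Numerical conventions

Distribution sums are validated to 1e-9 (CPT rows) and 1e-6 (user-supplied
marginals); rotations must be proper orthogonal to 1e-9; IK loop residuals
are ~1e-16 and tested below 1e-10; Jacobians are validated against central
differences at 1e-5 and accelerations at 1e-4 (step sizes 1e-6 and 1e-4).
Problem sizes in the test suite — 50,000-record cohorts for convergence
and 20-seed parameter recovery, 200 random networks for the dual-oracle
inference check, 200 random trajectories for the finite-difference checks
— were chosen so sampling error sits well below the asserted tolerances
while the whole suite runs in seconds.

## Known limitations

Structure learning, continuous/hybrid nodes, MCMC, sliding-window
recalibration, dynamics/forces, contact, and motor sizing are out of
scope.  The grade-node soft update and the subtalar assignment of the
rotation function are modelling choices the source leaves open; both are
isolated behind configuration and documented above.
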
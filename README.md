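# bigrehab

Decision analysis for personalised ankle rehabilitation, combining
information-gain feature ranking, a discrete Bayesian network over clinical
recovery states, and a value-of-information strategy loop — plus
screw-theory kinematics of the 3-PUU-R hybrid serial–parallel mechanism
that delivers the training.

## Who this is for

Researchers in rehabilitation robotics and clinical biostatistics who want
a tested, reproducible implementation of the "Bayesian information gain"
(BIG) pipeline: rank which clinical features best discriminate ankle-injury
disability grades, learn and update a probabilistic model of recovery, and
drive session-by-session training decisions by expected information gain.
No patient-level data ships with the package; a seeded synthetic-cohort
generator reproduces the statistical structure the analysis assumes, so
every stage runs end to end out of the box.

## The model

**Feature ranking.** For disability grade `D` (Levels I–III) and an ordinal
clinical feature `A` (pain level, swelling, joint stability, functional
limitation):

    H(D)     = −Σ_k p_k log2 p_k
    H(D|A)   = Σ_i P(A = a_i) · H(D | A = a_i)
    IG(D, A) = H(D) − H(D|A)

all in bits; the features with the largest gain drive the network design
and the training priorities.

**Bayesian network.** Eleven discrete nodes: injury grade `P1`; repair
states of the talocrural (`R1`) and subtalar (`R2`) joints
(recovered/impaired); four functional states `B1–B4` (flexion–extension,
inversion–eversion, rotation, stretch; normal / mildly / severely
restricted); four rehabilitation goals `G1–G4` (pain control, tissue
repair, stability, weight-bearing; achieved / not achieved).  Edges run
`P1 → {R1, R2}`, each `B` hangs off its anatomical repair node, and every
`G` has parents `{R1, R2}`.  CPTs are learned by maximum likelihood with
optional Dirichlet smoothing (`P(Y=y|pa) = (N_{y,pa} + α) / (N_pa + α·|Y|)`),
and posteriors update hierarchically: observation frequencies → repair
nodes by Bayes-rule inversion → goal nodes by marginalising
`P(G|r1,r2)` over the repair posteriors → injury grade.  Exact inference
(full enumeration and variable elimination, cross-checked) is available
for arbitrary evidence.

**Strategy.** Goal priorities combine the published factor scores with the
posterior: `priority(G) = score(G achieved) × P(G not achieved)`.  The
next observation to make is the node with the largest expected information
gain (expected posterior-entropy reduction, i.e. conditional mutual
information) about the grade and goal nodes.

**Kinematics.** The 3-PUU-R module covers the modified Kutzbach–Grübler
mobility count `M = d(n − g − 1) + Σf_i + v`, branch motion screws and
their reciprocal constraint system in Plücker ray coordinates, inverse
kinematics of the vector loop `P + R·f_i = n_i + m_i M_i + e_i E_i`, the
Jacobians `J_x`, `J_m = diag(M_i·E_i)`, `J_p = J_m⁻¹ J_x`, platform↔pedal
twist/acceleration transfer across the revolute offset, and
range-of-motion checking of labelled ankle-angle trajectories.

## Worked example

```python
import numpy as np
from bigrehab import (CohortSpec, generate_cohort, rank_features,
                      default_network, posterior_target,
                      joint_census_puu, mobility)

cohort = generate_cohort(CohortSpec(n_patients=100, seed=42))
print(rank_features(cohort, ["A1", "A2", "A3", "A4"]).to_markdown())

net = default_network()
repair = {"R1": np.array([0.584, 0.416]), "R2": np.array([0.577, 0.423])}
goals = posterior_target(net, repair, g_nodes=["G1", "G2", "G3", "G4"])
print({g: round(float(v[0]), 3) for g, v in goals.items()})

print(mobility(joint_census_puu()))
```

prints

```
Dataset entropy H(D) = 1.519 bits

| Feature | Conditional entropy (bits) | Information gain (bits) |
| --- | --- | --- |
| A4 | 1.275 | 0.244 |
| A3 | 1.399 | 0.120 |
| A2 | 1.431 | 0.088 |
| A1 | 1.483 | 0.036 |

{'G1': 0.631, 'G2': 0.68, 'G3': 0.688, 'G4': 0.671}
3
```

Functional limitation (`A4`) is the most informative feature about the
disability grade in this synthetic 100-patient cohort, with pain and
swelling only weakly informative — the qualitative structure the clinical
study reports.  Marginalising the goal CPTs over the post-intervention
repair posteriors (58.4% / 57.7% achieved) gives a 63.1% probability of
achieving pain control and 68.0% for tissue repair, matching the published
62.9% / 67.6% within rounding of the printed inputs.  The parallel
mechanism has 3 degrees of freedom (4 with the serial revolute pedal
joint).

The same workflow is available from the shell:

```bash
bigrehab simulate --seed 42 --out out/
bigrehab analyze --cohort out/cohort.csv --out out/
bigrehab loop --cohort out/cohort.csv --sessions 6 --out out/
bigrehab kinematics mobility --out out/
```

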
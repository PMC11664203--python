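# platformtrial

Design calculator for **preplanned multi-stage platform trials** in which
new experimental arms join at arbitrary, prespecified points of control
accrual — and every arm is tested to its own conclusion, even after a
superior treatment has already been found.

It is aimed at trial statisticians designing group-sequential multi-arm
studies (normal endpoint, known variance) who need:

* stopping boundaries that control the **familywise error rate (FWER) in
  the strong sense** when arms are added mid-trial,
* sample sizes for **pairwise**, **conjunctive** or **disjunctive** power,
* the **sample-size distribution** and **expected sample size** of the
  resulting adaptive design (with or without pausing recruitment while no
  experimental arm is open), and
* a quantitative comparison against simply running **separate trials**.

## The model

Arm k (k = 1..K) is compared with a shared control using the standardised
statistic at its j-th analysis,

    Z_kj = (X̄_k,j − X̄_0,kj) / (σ √(1/n_kj + 1/m_kj)),

where X̄_0,kj averages only the *concurrent* controls — the m_kj control
patients recruited after arm k joined.  Arm k joins once n(k) control
patients have accrued; n(k) = 0 for arms present at the start.  The vector
of all Z_kj is multivariate normal: E Z_kj = θ_k √I_kj with
I_kj = [σ²(1/n_kj + 1/m_kj)]⁻¹, and the correlations follow from the
patients two statistics share (nested treatment samples within an arm,
overlapping control windows across arms; arms with disjoint control
windows are independent).

A one-parameter boundary family (triangular, Pocock or O'Brien–Fleming)
supplies efficacy bounds u_kj and futility bounds l_kj; the scale *a* is
calibrated by root-finding so that

    FWER = 1 − Σ over stop-stage vectors  Φ(region where every arm exits
           through its futility bound)  = α

under the global null (binding version; the nonbinding version drops the
interim futility bounds).  Power, outcome probabilities and expected
sample size are sums of the same kind of multivariate-normal rectangle
probabilities, and a patient-level Monte Carlo simulator independently
checks every analytic quantity.

## Worked example

The motivating two-arm design: clinically relevant effect
θ′ = −log(0.69) ≈ 0.371, σ = 1, one-sided FWER 2.5%, 80% pairwise power,
one interim halfway through each arm, second arm added halfway through
arm 1's recruitment (addition ratio 1), binding triangular bounds:

```python
import numpy as np
from platformtrial import (PowerRequest, find_n, power_table,
                           enumerate_outcomes)

thp = -np.log(0.69)
layout, bounds = find_n(2, 2, [0, 1], "triangular", 0.025,
                        PowerRequest(type="pairwise", target=0.8),
                        theta_prime=thp)
print(layout.n1, layout.max_N)          # 76 532.0
print([round(u, 3) for u in bounds.U[0]],
      [round(l, 3) for l in bounds.L[0]])
# [2.501, 2.358] [0.834, 2.358]
tab = power_table(layout, bounds, [thp, thp])
print({k: round(v, 3) for k, v in tab.items()})
# {'pairwise_1': 0.8, 'pairwise_2': 0.8,
#  'conjunctive': 0.66, 'disjunctive': 0.941}
print(round(enumerate_outcomes(layout, bounds, [thp, thp]).expected_N(), 1))
# 420.6
```

Reading: 76 patients per arm per stage (maximum 532 in total) give each
arm an 80% chance of being found superior when its effect is θ′; the
chance of finding *both* such arms is 66%, of finding *at least one* is
94.1%; and early stopping brings the expected total down to ~421 patients.

The same engine answers the "platform or separate trials?" question:

```python
from platformtrial import SeparateTrialsSpec, design_separate, \
    PlatformSpec, crossover_n_add

sep = design_separate(SeparateTrialsSpec(K=2, alpha_mode="per_trial"), thp)
spec = PlatformSpec(K=2, J=2, shape="triangular", alpha=0.025,
                    request=PowerRequest(type="pairwise", target=0.8),
                    theta_prime=thp)
print(sep.combined_max_N)                       # 520.0
print(crossover_n_add(spec, sep, "max_N"))      # 64
```

If each separate trial may keep the full 2.5% error, two of them need at
most 520 patients — and once the second arm would join after more than 64
control patients, the FWER-controlling platform is no longer smaller.

The same operations are available from the shell
(`platformtrial size|calibrate|power|expected-n|ssdist|simulate|compare|table3|run`),
e.g.

```bash
platformtrial size --K 2 --J 2 --r-add 0,1 --alpha 0.025 \
    --theta-prime 0.3711 --power-type pairwise --target 0.8 --out design.json
platformtrial power --design design.json --theta 0.3711,0
```

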
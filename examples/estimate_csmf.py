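"""Estimate community cause-specific mortality fractions from paired samples.

Simulates a hospital sample (causes medically certified) and a community
sample (causes unknown) from one symptom model, then back-calculates the
community CSMF from symptom profiles alone and compares it with the truth.
"""

import numpy as np

from vacsmf import (
    EstimatorConfig,
    SimulationDesign,
    estimate_csmf,
    simulate_design,
)

design = SimulationDesign(
    n_causes=10, n_symptoms=30, n_hospital=3000, n_community=3000,
    case_control=True,  # equal hospital deaths per cause
    s_max=0.98,
)
study = simulate_design(design, seed=7)

est = estimate_csmf(
    study.hospital, study.community, EstimatorConfig(subset_size=6, seed=7)
)

print(f"{'cause':>10} {'true':>7} {'estimate':>9}")
for name, t, e in zip(est.cause_names, study.true_csmf.fractions,
                      est.point.fractions):
    print(f"{name:>10} {t:7.3f} {e:9.3f}")
mae = np.abs(est.point.fractions - study.true_csmf.fractions).mean()
print(f"\nmean absolute error: {mae:.4f} "
      f"({100 * mae:.2f} percentage points per cause)")
print("The estimate tracks the community mix even though the hospital sample "
      "was case-control (uniform across causes).")
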
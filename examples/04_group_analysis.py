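"""Vertex-wise mixed-effects analysis and normative Z-score classification.

Fits, at every vertex, thickness ~ baseline age + time + diagnosis with
per-subject random intercepts and slopes, then scores every scan against an
age-bracketed control reference and classifies disease vs control from the
mean Z-score.
"""

import numpy as np

from longicortex import (SubjectRecord, SyntheticCohortConfig, auc,
                         generate_subject, normative_zscores, vertexwise_lme)
from longicortex.group_stats import simulate_mixed_model_records

# 1) noise-free data generated exactly from the mixed model: exact recovery
records = simulate_mixed_model_records(n_subjects=20, n_vertices=4,
                                       re_sd=(0, 0), noise_sd=0.0, seed=1)
res = vertexwise_lme(records)
print(f"injected diagnosis effect -0.300, recovered {res.beta3.mean():+.6f}")

# 2) noisy data: effect still detected
records = simulate_mixed_model_records(n_subjects=40, n_vertices=6, seed=2)
res = vertexwise_lme(records)
print(f"noisy cohort: mean beta3 {res.beta3.mean():+.3f}, "
      f"all p < 0.05: {bool(np.all(res.pvalue < 0.05))}")

# 3) normative Z-scores on the synthetic generator's disease contrast
cfg = SyntheticCohortConfig(n_subjects=30, grid_shape=(16, 16, 16), radius_mm=4.5,
                            radius_sd=0.2, thickness_mm=1.2, thickness_variation=0.1,
                            template_subdivisions=2, rng_seed=5)
rng = np.random.default_rng(5)
subject_records = []
for i in range(cfg.n_subjects):
    s = generate_subject(cfg, int(rng.integers(2 ** 31)), subject_id=f"s{i}")
    subject_records.append(SubjectRecord(s.subject_id, s.baseline_age, s.visit_times,
                                         np.stack(s.thickness_fields), s.diagnosis))
z = normative_zscores(subject_records, on_missing_bracket="nearest")
score = auc(-z["mean_z"].to_numpy(), z["diagnosis"].to_numpy())
print(f"normative mean-Z AUC (disease vs control): {score:.3f}")
print("Thinner-than-normal cortex yields negative Z; the AUC measures how well")
print("the mean Z separates the accelerated-atrophy group from controls.")
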
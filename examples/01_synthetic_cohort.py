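"""Generate a small synthetic longitudinal cohort and inspect its ground truth.

Each subject has nested white/pial surfaces with known vertex correspondence
across visits, noisy occupancy volumes, and covariates.  The script prints the
injected disease contrast: the diseased group loses cortical thickness faster.
"""

import numpy as np

from longicortex import SyntheticCohortConfig, cortical_thickness, generate_cohort

config = SyntheticCohortConfig(n_subjects=6, grid_shape=(32, 32, 32), radius_mm=9.0,
                               radius_sd=0.5, rng_seed=42)
cohort = generate_cohort(config)

print(f"{'subject':<10}{'diagnosis':<11}{'visits':<8}{'baseline thickness':<20}"
      f"{'slope mm/yr':<12}")
for subj in cohort:
    means = [cortical_thickness(w, p).values.mean()
             for w, p in zip(subj.white_meshes, subj.pial_meshes)]
    slope = np.polyfit(subj.visit_times, means, 1)[0] if subj.n_visits > 1 else np.nan
    print(f"{subj.subject_id:<10}{subj.diagnosis:<11}{subj.n_visits:<8}"
          f"{means[0]:<20.3f}{slope:<12.3f}")

print("\nDiagnosis 1 subjects thin at ~0.1 mm/yr, diagnosis 0 at ~0.01 mm/yr —")
print("the contrast the group-analysis examples recover downstream.")
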
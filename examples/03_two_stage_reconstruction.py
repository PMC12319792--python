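"""Train the two-stage pipeline on a small synthetic cohort and measure the
consistency gain of the within-subject-template composition.

Stage 1 deforms the population template to every scan; the per-visit outputs
are averaged into a within-subject template (with deep vertex features);
stage 2 deforms that template to each visit.  The second stage's outputs are
far more consistent across visits (lower MCVar/CThVar) at comparable accuracy.
Takes a minute or two on one CPU.
"""

from longicortex import SyntheticCohortConfig, TrainConfig, run_two_stage_benchmark

cohort_config = SyntheticCohortConfig(n_subjects=8, grid_shape=(32, 32, 32),
                                      radius_mm=9.0, radius_sd=0.7, rng_seed=11)
res = run_two_stage_benchmark(cohort_config, TrainConfig(epochs=15), model_seed=0)

print(f"held-out subjects: {res['test_subjects']}")
print(f"{'':<28}{'stage 1':>12}{'stage 2':>12}")
print(f"{'ASSD (voxels)':<28}{res['assd_voxels'][1]:>12.3f}{res['assd_voxels'][2]:>12.3f}")
print(f"{'MCVar (subject median)':<28}{res['mcvar'][1]:>12.5f}{res['mcvar'][2]:>12.5f}")
print(f"{'CThVar (subject median)':<28}{res['cthvar'][1]:>12.5f}{res['cthvar'][2]:>12.5f}")
print("\nBoth stages reconstruct to sub-voxel accuracy; composing through the")
print("within-subject template cuts the across-visit variance of curvature and")
print("thickness by one to two orders of magnitude.")
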
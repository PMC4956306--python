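"""Sphere-ROI quantification of SAC protein levels at kinetochores.

Around each kinetochore a 0.45 um sphere (average HeLa kinetochore size)
is integrated in both channels; the local background — the median of a
surrounding shell, with neighbouring kinetochores' spheres masked out —
is subtracted, and the SAC level is the ratio corrected_sac/corrected_crest.
"""

from kinetoquant import (
    SimulationConfig,
    detect_kinetochores,
    measure_cell,
    measurements_to_frame,
    simulate_cell,
)

stack, truth = simulate_cell(SimulationConfig(seed=3), cell_id="demo")
spots = detect_kinetochores(stack)
measurements = measure_cell(stack, spots)
frame = measurements_to_frame(measurements)

print(frame[["kt_id", "raw_sac", "bg_sac_per_voxel", "corrected_sac",
             "corrected_crest", "n_voxels", "ratio"]].head(6).to_string(index=False))
true_ratio = (truth.amp_sac / truth.amp_crest).mean()
print(f"\nmean measured SAC/CREST ratio: {frame['ratio'].mean():.3f} "
      f"(true amplitude ratio in this cell: {true_ratio:.3f})")
print(
    "\nNormalising to CREST in the same sphere cancels kinetochore size, "
    "staining and focus differences, so the ratio tracks SAC occupancy."
)
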
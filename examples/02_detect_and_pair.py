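"""Detect kinetochores in 3D and pair sisters.

Detection runs on the CREST channel only (kinetochore identity never comes
from the SAC channel): an anisotropic blob filter, a robust scale-free
threshold, and sub-voxel centroid refinement.  Pairing is mutual nearest
neighbour gated by the spindle axis estimated from the detected cloud.
"""

import numpy as np

from kinetoquant import (
    SimulationConfig,
    detect_kinetochores,
    interkinetochore_distances,
    match_to_truth,
    pair_sisters,
    simulate_cell,
)

stack, truth = simulate_cell(SimulationConfig(seed=2), cell_id="demo")
spots = detect_kinetochores(stack)
metrics = match_to_truth(spots, truth.positions_um, tol_um=0.3)
print(f"detected {len(spots)} spots (truth: {truth.n_kinetochores})")
print(f"recall {metrics.recall:.3f}, precision {metrics.precision:.3f}, "
      f"localisation RMSE {metrics.rmse_um*1000:.0f} nm")

pairs, unpaired = pair_sisters(spots)
sample = interkinetochore_distances(pairs)
print(f"\n{len(pairs)} sister pairs, {len(unpaired)} unpaired spots")
print(f"mean inter-kinetochore distance over the 10 reported pairs: "
      f"{sample.mean_reported_um:.3f} um (true mean separation "
      f"{np.mean(truth.sister_sep_um):.3f} um)")
print(
    "\nThe inter-kinetochore distance is the 3D Euclidean distance between "
    "refined sister centres; it increases when the checkpoint holds "
    "chromosomes under spindle tension."
)
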
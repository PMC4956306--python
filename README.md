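# kinetoquant

Quantitative 3D immunofluorescence analysis of spindle-assembly-checkpoint
(SAC) proteins at metaphase kinetochores.

## The problem

Anaphase onset requires removal ("stripping") of SAC proteins — Mad1, Mad2,
Zw10 (attachment sensors) and BubR1 (tension sensor) — from metaphase
kinetochores. Perturbations that block stripping (e.g. depletion of dynein
light-intermediate-chain subunits) leave SAC proteins accumulated at aligned
kinetochores, arrest cells in metaphase and change inter-kinetochore
tension. Quantifying this from confocal z-stacks requires, per cell:

1. **Detection** of kinetochores as diffraction-limited 3D spots in a CREST
   (anti-centromere) reference channel, with sub-voxel localisation on
   anisotropic voxels.
2. **Sphere-ROI photometry**: around each kinetochore centre a sphere of
   diameter 0.45 µm (average HeLa kinetochore size) is integrated in both
   channels; a local background (median of a surrounding shell, neighbours
   masked) is subtracted; the SAC level is reported as the ratio

   $R_k = \dfrac{I_{\mathrm{SAC}}(S_k) - n_k\,\hat b_{\mathrm{SAC}}}{I_{\mathrm{CREST}}(S_k) - n_k\,\hat b_{\mathrm{CREST}}}$

   over the identical sphere $S_k$ ($n_k$ voxels, shell-median background
   $\hat b$), which cancels staining, size and focus differences.
3. **Sister pairing** and 3D inter-kinetochore distances (a tension readout),
   with a fixed number of pairs reported per cell (default 10).
4. **Selection and statistics**: per cell, the mean ratio over either the
   20 brightest kinetochores (Mad1/Mad2/Zw10 convention) or all
   kinetochores (BubR1 convention); per condition, mean ± SEM of cell
   means, fold change over control, Welch t-test or one-way ANOVA with
   Tukey's HSD, and the usual significance stars.
5. **Population summaries**: metaphase index (% of living cells in
   metaphase, mean ± SD over replicates) and mitotic timing from annotated
   event tables (mean NEB→anaphase duration, fraction arrested ≥ 80 min,
   fraction of arrested cells dying after > 4 h).

Because such datasets are rarely deposited, the package ships a synthetic
metaphase-cell generator (`simulate_cell` / `simulate_experiment`) that
renders two-channel stacks — paired Gaussian spots on a metaphase plate,
Poisson shot noise, read noise, anisotropic voxels — with a full ground-truth
table, so every stage is validated by parameter recovery.

## Worked example

```python
from kinetoquant import SimulationConfig, analyze_cells, simulate_experiment

control  = SimulationConfig(condition="control",  condition_multiplier=1.0)
depleted = SimulationConfig(condition="depleted", condition_multiplier=2.0)
exp = simulate_experiment(control, depleted, n_cells_per_group=10, master_seed=4)

result = analyze_cells([s for s, _ in exp.cells], control_condition="control")
print(result.comparisons.iloc[0])
```

prints (from `examples/04_fold_change_experiment.py`):

```
depleted vs control: fold change 2.00 (true 2.0), Welch t = 18.36, df = 16.9, p = 1.35e-12 ***
```

i.e. a simulated 2-fold retention of a SAC protein at kinetochores is
recovered as a 2.00-fold increase in the normalized (SAC/CREST) intensity,
highly significant across 10 cells per group. The `examples/` directory has
one short script per capability (simulation, detection/pairing,
quantification, group statistics, timing/metaphase index); each prints what
it computes and what the numbers mean.

For file-based work, `run_quantification(RunConfig(...))` takes a CSV
manifest of OME-TIFF stacks (columns `cell_id, path, condition, qualifies`)
and writes `spots.csv`, `pairs.csv`, `measurements.csv`,
`cell_summaries.csv`, `group_comparison.csv` and a JSON run log; reruns on
identical inputs are byte-identical.

## Self-validation

`scripts/acceptance.py` re-runs the package's end-to-end recovery
computation from scratch: it simulates a control-vs-depletion experiment
(2-fold SAC amplitude) with the given seed, runs the full pipeline, and
prints recovered fold change, group mean inter-kinetochore distances and
detection recall/precision against the known ground truth:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the imaging model, parameter defaults, numerical
conventions and limitations.
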
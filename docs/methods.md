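# Methods

## Coordinate and calibration conventions

All geometry is computed in physical micrometres. Stacks are held as
`(channel, Z, Y, X)` arrays; the physical centre of voxel index `i` along an
axis with spacing `s` is `(i + 0.5)·s`. Voxel size comes from OME-TIFF
metadata; a stack without calibration is an error unless an override is
supplied — there is no silent default. This makes sphere-membership tests
unambiguous under anisotropic sampling (confocal z-spacing, default 0.3 µm,
is typically 3× the xy pixel size, default 0.1 µm).

## Synthetic metaphase cells

`simulate_cell` renders what the quantification stages consume: a
two-channel (CREST, SAC) z-stack of one metaphase cell.

**Geometry.** The spindle axis is fixed along stack X. Pair centres are
drawn uniformly on a disk of radius 4 µm (the metaphase plate) in the (Z, Y)
plane through the stack centre; sisters are displaced symmetrically along a
unit vector tilted ≤ 10° from X, with separation drawn from a normal
(default 1.0 ± 0.1 µm, truncated below 0.1 µm). Layouts are rejection-sampled
(≤ 10 000 attempts per pair) until no two non-sister kinetochores are closer
than 0.9 µm in 3D; an unsatisfiable configuration fails loudly naming the
violated gap, never silently relaxing it. The default plate (40 pairs,
radius 4 µm, gap 0.9 µm) packs the plate to ~93 % of the random-sequential-
addition jamming density — deliberately crowded, matching the ~46 chromosome
pairs of a HeLa cell on a real plate.

**Photometry.** Each kinetochore is an anisotropic 3D Gaussian
(σ_xy = 0.10 µm, σ_z = 0.30 µm) whose amplitude is its total expected photon
count; rendering integrates the Gaussian over each voxel extent (erf form)
and truncates at ±4σ per axis, so the voxel sum equals the amplitude to
< 0.1 %. Amplitudes are lognormal, parameterised by arithmetic mean and CV
(defaults: CREST 5000 ± 30 %, SAC 3000 ± 30 %). The per-condition
`condition_multiplier` scales SAC amplitudes only — the fold-change knob
emulating checkpoint-protein retention. Noise follows the standard camera
model: Poisson on (signal + background), then Gaussian read noise
(default SD 2), clipped and quantised to 16 bits. With every noise source
disabled the *expected-photon* image is returned unquantised, so photon
conservation holds exactly up to PSF truncation (quantisation belongs to the
camera model, not to the ideal image).

Defaults for quantities with no community-standard value (photon budget,
voxel size, grid 32×96×64) are conventional confocal settings, exposed in
`SimulationConfig` rather than asserted as facts about any instrument.

**What the generator does not emulate** — and hence what a green recovery
test does not establish robustness against: chromatic shift between
channels, non-Gaussian PSF tails and spherical aberration, cytoplasmic
autofluorescence structure (background is constant or a linear gradient),
kinetochore shape (spots are points), and movement during acquisition.

## Detection

The CREST channel is filtered with a negated Laplacian-of-Gaussian using
per-axis sigmas converted from physical units, so one blob scale serves
anisotropic voxels. The threshold is robust and scale-free:
`median + k·1.4826·MAD` of the response (k = 6). On noise-free sparse images
the MAD is zero without the image being degenerate; the scale then falls
back to the mean absolute deviation (still scale-free); only a genuinely
flat response is an error. Local maxima within an ellipsoidal 0.3 µm
neighbourhood are kept, then greedily suppressed by physical distance in
descending score order (ties broken by lexicographic (z, y, x) index, for
determinism). Each survivor is refined by an intensity-weighted centroid
over voxels within 0.225 µm, iterated ≤ 3 times to 0.01 µm. Note the
refinement radius is smaller than the z-spacing, so z-localisation stays at
plane resolution (±0.15 µm) — adequate for the 0.3 µm matching tolerance and
for distances, whose z-component across a sister pair largely cancels.
Spots whose 0.45 µm quantification sphere would leave the stack are flagged
`edge` and excluded from quantification by default.

## Sister pairing

Plain mutual-nearest-neighbour pairing is ambiguous on a crowded plate: the
sister sits ~1.0 µm away along the spindle axis, while the nearest
non-sister within the plate can sit at ~0.9–1.1 µm. Measured on true
positions of default simulated plates, distance-only mutual-NN mispairs
roughly a third of formed pairs. Direction disambiguates: sisters separate
along the spindle axis, in-plate neighbours perpendicular to it. Pairing is
therefore mutual-nearest-neighbour with two gates: distance in
[0.4, 2.5] µm, and displacement within 45° of the spindle axis. The axis is
estimated from the kinetochore cloud itself: for a plate-like cloud the
smallest principal axis of the position covariance; for a near-collinear
cloud (eigenvalue ratio < 10⁻², e.g. a handful of spots on one line) the
largest. With the gate, pairing recovers 100 % of true pairs on default
simulated plates; `axis_mode="none"` restores plain mutual-NN for sparse
preparations. Mutuality guarantees each kinetochore appears in at most one
pair; the result is invariant under input permutation.

The "10 pairs per cell" report selects pairs by highest combined
background-corrected CREST intensity (ties by kt_id) — a reproducible proxy
for the by-eye choice of well-resolved pairs; all distances are always
retained alongside the reported subset, and cells with fewer pairs than
requested are flagged, not dropped. Distances are 3D Euclidean; this is a
declared convention (a single-plane 2D measurement would be systematically
shorter for tilted pairs).

## Sphere quantification

Sphere membership is a centre-in-sphere test on voxel centres — no
partial-volume weighting — making every integral exactly reproducible by a
brute-force masked sum (the test suite enforces integer-exact agreement).
On 0.1 µm isotropic voxels the 0.45 µm sphere centred on a voxel centre
contains 57 voxels; with 0.3 µm z-spacing, 21 (a single-plane disk).

The local background per channel is the **median** of the shell
(r, r + 0.15 µm] around the sphere, excluding voxels inside any other
kinetochore's sphere — median rather than mean for robustness to bleed-
through from a bright neighbour partially in the shell; the exclusion
prevents the ~1 µm sister from inflating the estimate. An empty shell after
exclusion is an error instructing a larger shell width. Corrected integrals
are `raw − n_voxels·background`; negatives clamp to zero with an audit flag
rather than erroring, preserving dataset completeness. Both channels use
the identical sphere, so the ratio is invariant to global intensity scaling
and each corrected integral is exactly invariant to adding a constant to
its channel.

The sphere (radius 0.225 µm) captures only ~50 % of a spot's photons with
σ_z = 0.3 µm — but the *same* fraction in both channels, since both share
the PSF; the SAC/CREST ratio is therefore an unbiased estimate of the
amplitude ratio, which is what recovery tests confirm (per-spot ratios
within 5 % noise-free, group fold change within the [1.8, 2.2] band at
2-fold truth).

## Statistics

The unit of analysis is the **cell** (mean ratio over its selected
kinetochores): replicate counts in such experiments are cells, and
kinetochores within a cell are not independent. "Visibly brightest" is
operationalised as rank by background-corrected SAC sphere intensity
(default k = 20; ties by corrected CREST, then kt_id); `mode="all"` covers
proteins quantified on every kinetochore. Fewer than k valid kinetochores
uses all with a flag.

Two-group comparisons use the unequal-variance (Welch) t-test — the safer
default when only "t-test" is specified; more than two groups use one-way
ANOVA with Tukey-HSD-adjusted pairwise p-values against control. Fold
change is the ratio of group means of cell means. Stars: p < 0.05 `*`,
< 0.01 `**`, < 0.001 `***`, else `ns`. Type-I error of the full pipeline
(simulation → detection → quantification → Welch) is verified at 3–4 %
rejection over 200 null replicates, i.e. correctly calibrated, slightly
conservative at n = 6 cells/group.

Metaphase index is `100·n_metaphase/n_total_living` per replicate, averaged
with SD across replicates (single replicates report SD as unavailable
rather than 0).

Timing summaries take annotated event times (NEB, anaphase, death, movie
end — event detection from video is out of scope). Per condition: mean
NEB→anaphase among cells reaching anaphase; fraction arrested, where
arrested means no anaphase within the threshold (default 80 min) after NEB,
assessed only on cells observable to the threshold (cells whose movie ends
earlier with no event are censored: excluded from the denominator and
counted); and among arrested cells, the fraction dying later than the death
window (default 240 min) after NEB. A cell that dies before the arrest
threshold counts as assessable but not arrested — it left metaphase, though
not by division; this convention matters only for very early deaths.

## Numerical and reproducibility choices

- All randomness flows from explicit seeds; per-cell seeds derive
  deterministically from a master seed (`SeedSequence`), so experiments are
  bit-reproducible.
- CSV output uses 6-significant-digit floats; reruns on identical inputs
  are byte-identical.
- Per-cell failures in a multi-cell run are recorded with cell id and stage
  and do not abort the run; a group comparison that becomes impossible
  (e.g. < 2 surviving cells in a condition) is itself recorded as a failure
  entry rather than crashing.

## Known limitations

- Detection z-localisation is quantised to plane spacing (see above).
- The spindle-axis estimate assumes a roughly plate-like (or collinear)
  kinetochore cloud; prometaphase rosettes or severely scattered plates
  would need an external axis or `axis_mode="none"`.
- Background is estimated per kinetochore from a thin shell; structured
  backgrounds varying on scales below ~0.4 µm are not separable from
  signal.
- The generator's realism limits, listed above, bound what recovery tests
  can certify.
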
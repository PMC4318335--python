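# Methods

## Measurement model

The pipeline measures cortical morphology from a two-channel, 0.7 mm
isotropic acquisition: a T1-weighted channel whose intracortical contrast
tracks myelin content, and a predominantly proton-density FLASH channel.
Dividing the summed T1w repeats by the summed, median-filtered FLASH
repeats cancels the receive/transmit field the channels share and leaves a
ratio image in which tissue classes are separated by intensity alone, in
the order CSF < GM < mGM < WM. Only the FLASH denominator is smoothed
(two passes of a 3-voxel cubic median filter, reflect borders); the T1w
numerator keeps full resolution. Division is guarded: voxels whose
denominator falls below a scale-free epsilon (1e-6 of the median in-mask
FLASH intensity) are zeroed and counted.

Segmentation is standard fuzzy c-means on the masked ratio intensities
(fuzziness q = 2, relative-centroid tolerance 1e-5, max 300 iterations),
classes relabeled by ascending centroid. The alternating updates make the
objective non-increasing, which the implementation records and the tests
assert. Initial centroids are spread evenly between the 1st and 99th
in-mask intensity percentiles. Quantile-based initialization (an obvious
alternative, available as `init="quantile"`) fails on realistic class
imbalance: when CSF and WM dominate the voxel count, two or more initial
centroids land in the same intensity population and — in the noise-free
limit — identical centroids receive identical updates and can never
separate. The spread initialization places exactly one centroid near each
quarter of the intensity range and is deterministic, so the `seed`
argument matters only for `init="random"`.

Labels are the membership argmax (which subsumes the conventional 0.5
threshold: any membership above 0.5 is the argmax, and argmax makes the
labeling total). One asymmetry is deliberate: voxels with WM membership
≥ 0.1 that are 26-connected to the main WM body are relabeled WM. This
recovers thin WM blades in gyral crowns, where partial voluming depresses
WM intensity below the argmax criterion. Finally, each class keeps only
its largest 26-connected component; island voxels are reassigned to their
next-highest-membership class (or background without memberships).

Thickness follows the level-set subtraction construction. Each of the
three nested boundaries (pial = CSF|cortex, outer-myelin = GM|mGM,
outer-white = mGM|WM) becomes a signed Euclidean distance field, positive
on the deep side, computed with physical anisotropic spacing as the
difference of the two one-sided exact distance transforms, shifted by half
a voxel so the zero crossing sits on the interface between voxel sheets
rather than on voxel centers. Then t = φ_p − φ_w, d = φ_p − φ_m,
m = t − d on the ribbon (GM ∪ mGM). The subtraction equals the true
inter-surface distance only for nested, locally parallel boundaries; where
segmentation topology breaks that assumption the maps can go non-positive,
which is reported as a warning with a voxel count, never clipped
silently. Streamline (Laplacian) or coupled-surface thickness definitions
are out of scope.

The pial surface is triangulated by marching cubes at the 0.5 level of the
cortex-interior indicator after a 0.7-voxel Gaussian anti-aliasing blur.
The blur does not move a flat interface; it removes the staircase bias
that makes meshes of raw binary masks overestimate area by ~7 % on a
digital sphere (−0.2 % after the blur). This is part of surface
extraction; the *display* smoothing sometimes applied to cortical surfaces
is excluded from all measurement paths. Projection nudges each vertex half
a voxel along its normal (both signs tried, since the marching-cubes
normal orientation follows the indicator gradient) and interpolates the
thickness map trilinearly with ribbon-indicator weighting; vertices with
no ribbon support within 2 voxels are marked missing. ROIs grow from a
seed vertex in order of graph-geodesic distance (Dijkstra over mesh edges,
ties broken by vertex index) until the cumulative vertex area reaches the
target, 54 mm² by default — the area of the approximately circular
patches used for the precentral leg representation. ROI means are
area-weighted, which reduces to the plain mean on uniform meshes and is
robust to mesh irregularity. Anatomical placement of the seed vertex is a
manual step in practice and is parameterized here, not automated.

## Group statistics

Bilateral asymmetry of a per-hemisphere measurement is
100·|L−R|/((L+R)/2): symmetric, scale-invariant, bounded in [0, 200).
Groups are compared with the Kruskal-Wallis H test using midranks and the
tie-correction factor. For pooled N ≤ 12 the p-value is exact: all
C(N, n₁) assignments of the pooled values are enumerated and the p-value
is the proportion with H ≥ H_observed; otherwise H is referred to χ²(1).
The χ² approximation is rough at n = 4 + 4 (deviations from the exact
p above 0.1 occur) — that is precisely why the exact mode is the default
at small N. Tabled values are rounded half-up at the table's precision,
the convention that reproduces the majority of the reference cohort's
printed cells; a minority of printed cells cannot be reproduced from the
printed one-decimal hemisphere values under any rounding, consistent with
their having been computed from unrounded data, and the tests assert a
≤ 3-point bound for those instead of equality.

Power analysis uses the two-sided two-sample t-test model:
`detectable_difference` solves the noncentral-t power equation for the
effect size at α = 0.05, power 0.8 by default, and `required_sample_size`
inverts it for n. The model choice matters — a rank-test power analysis
would give different numbers — so the routine reports its own values
rather than claiming to match any particular published figure.

## Phantoms: what they emulate and what they do not

`make_phantom` builds four nested classes from a signed depth-below-pial
coordinate: CSF (depth < 0), GM (0 ≤ depth < d), mGM (d ≤ depth < t), WM
(depth ≥ t), with d = 1.5 mm and t = 4.5 mm by default — the motor cortex
is the thickest cortex at about 4.5 mm, which also motivates the ≤ 6 mm
plausibility bound. Geometries: parallel slab (thickness maps exactly
constant), concentric shells (constant thickness under curvature), and a
sinusoidally folded sheet whose deeper boundaries are true offset surfaces
of the pial sheet (built from a Euclidean distance transform), valid while
the fold's curvature radius λ²/(4π²A) exceeds t (defaults A = 1.5 mm,
λ = 20 mm give 6.8 mm > 4.5 mm). Planar/spherical interfaces are snapped
midway between voxel centers, so boundary quantization is at most half a
voxel per boundary.

Channel intensities are per-class means (T1w defaults 0.2/0.55/0.75/1.0
for CSF/GM/mGM/WM, flat 1.0 FLASH — the contrast *ordering* is the
physical content; the magnitudes are arbitrary and configurable since the
protocol publishes no quantitative contrast figures) times one shared
multiplicative bias field, plus independent noise per repeat and channel.
The bias field is 1 + amplitude·(Gaussian bump) with fixed off-center
placement and width 0.35 of the field of view, strictly positive for
amplitude < 1, peaking at 1 + amplitude inside the volume. Noise is
additive Gaussian by default (adequate at the SNR regimes tested); a
Rician mode exists for low-SNR magnitude data. Identical seeds give
bit-identical phantoms.

What the phantoms deliberately lack: partial-volume mixing at boundaries,
anatomical folding complexity, registration error between repeats,
subcortical structures, and any pulse-sequence physics. Passing the
recovery tests therefore shows the *measurement chain* is correct at known
geometry and contrast; it does not certify performance on real brains,
where segmentation quality is the binding constraint.

`make_cohort` draws each subject's asymmetry from N(asym_mean, asym_sd)
truncated to [0, 180), applies it symmetrically around a hemispheric mid
value jittered between subjects (SD 0.4 mm, matching the spread of the
reference tables), and signs it by the group's left/right means (random
sign if they are equal). Group defaults encode the reference-cohort
regime: myelinated asymmetry 17 ± 10 % (controls) and 17 ± 5 %
(amputees), cortical asymmetry 8 ± 6 % and 15 ± 6 %.

## Numerical choices and problem sizes

- Distance fields: exact Euclidean transforms; half-voxel interface shift
  uses half the mean spacing (exact for isotropic grids, the intended use).
- FCM voxels with intensity exactly equal to a centroid get the one-hot
  membership limit; coincident centroids split the unit membership evenly.
- Island-removal size ties keep the lowest component id (deterministic).
- ROI growth tie-breaks by vertex index (deterministic).
- Exact-permutation comparisons use H ≥ H_obs − 1e-12 to absorb rounding.
- Validation phantoms are 48×40×40 (slab) and 36³ (shell) voxels at
  0.7 mm — large enough that each class spans many voxels and ROI discs of
  54 mm² fit with margin, while the whole test suite runs in seconds.

## Known limitations

- Thickness accuracy is quantization-limited to about half a voxel per
  boundary; sub-voxel boundary models (partial-volume-aware level sets)
  are not implemented.
- The WM-blade rule and island reassignment resolve label conflicts with
  simple, deterministic policies; pathological membership fields could
  still yield non-nested boundaries, which are warned about, not repaired.
- Graph geodesics overestimate surface distance on lattice-like meshes
  (up to ~20 % along directions not represented by edges), so grown ROIs
  are approximately, not perfectly, circular.
- The exact Kruskal-Wallis mode enumerates C(N, n₁) assignments and is
  practical only for small N; the χ² approximation used beyond N = 12 is
  asymptotic.
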
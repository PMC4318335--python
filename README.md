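# myeloarch

Intracortical myelin morphometry from myelin-sensitive MRI: measure the
thickness of the well-myelinated deep cortex (*myelinated thickness*) and
the total cortical thickness, and compare their bilateral asymmetry between
subject groups.

## The problem

In primary motor cortex the bands of Baillarger merge, so the deep cortical
layers are continuously, heavily myelinated and appear bright on optimized
T1-weighted MRI. The thickness *m* of this well-myelinated zone is a
sensitive structural marker of the underlying myelinated axons (for
example, of the Betz-cell output pathway disrupted by limb amputation).
`myeloarch` implements the full measurement chain for researchers studying
cortical plasticity:

1. **Ratio image.** Summed T1w repeats are divided by the (median-filtered)
   summed proton-density FLASH repeats. Both channels share the same
   receive-field profile, so the multiplicative bias cancels:
   `t1w/flash = s(x)·b(x) / (p·b(x)) = s(x)/p`.
2. **Segmentation.** Fuzzy c-means clusters the masked ratio image into
   CSF, unmyelinated gray matter (GM), myelinated gray matter (mGM) and
   white matter (WM); memberships are thresholded to labels (WM uses a low
   0.1 level plus a connectivity rule to keep thin gyral WM blades), and
   per-class islands are removed.
3. **Thickness maps.** Signed distance (level-set) functions φ_p, φ_m, φ_w
   for the pial, outer-myelin and outer-white boundaries give, on the
   cortical ribbon,

       t = φ_p − φ_w        (cortical thickness)
       d = φ_p − φ_m        (superficial unmyelinated depth)
       m = t − d            (myelinated thickness)

4. **Surface ROIs.** The pial boundary is triangulated; thickness maps are
   projected onto vertices and averaged over geodesically grown circular
   ROIs (default area 54 mm²).
5. **Group statistics.** Per-subject percent bilateral asymmetry
   `100·|L−R| / ((L+R)/2)` is compared between groups with a
   Kruskal-Wallis test (exact permutation at small N), with power analysis
   for the minimal detectable difference under a two-sample t-test model.

Because subject scans of this kind are rarely shareable, the package
includes a phantom generator (slab, spherical shell, folded sheet) that
produces two-channel volumes with known nested tissue geometry, shared
bias, noise, and exact ground-truth t/d/m maps, plus a cohort generator
with controlled asymmetry. A reference cohort of four lower-limb amputees
and four matched controls (precentral leg-area ROI means) ships with the
statistics module.

## Worked example

```sh
myeloarch phantom --geometry slab --t 4.5 --d 1.5 --seed 1 -o ph/
myeloarch preprocess --t1w ph/t1w_rep1.nii.gz --t1w ph/t1w_rep2.nii.gz \
    --flash ph/flash_rep1.nii.gz --flash ph/flash_rep2.nii.gz -o ratio.nii.gz
myeloarch segment ratio.nii.gz -o seg/
myeloarch thickness seg/labels.nii.gz -o thick/
myeloarch roi seg/labels.nii.gz --map thick/thickness_t.nii.gz --area 54
```

prints

```
wrote ratio image to ratio.nii.gz (0 voxels guarded)
wrote labels and memberships to seg (centroids: [0.2  0.55 0.75 1.  ])
ribbon t median 4.20 mm, m median 2.80 mm -> thick
ROI (seed 779, 111 vertices, 54.4 mm^2): mean = 4.200 mm
```

The slab was built with t = 4.5 mm and d = 1.5 mm; the recovered ROI mean
of 4.20 mm is within half a voxel (0.35 mm at 0.7 mm resolution) of
ground truth, the expected quantization of boundary placement on the voxel
grid. The group-statistics path on the bundled reference cohort:

```sh
myeloarch stats --example --metric myelinated_thickness
```

```
control: asymmetry 16.9 +/- 9.7 % (n=4)
amputee: asymmetry 17.1 +/- 4.5 % (n=4)
Kruskal-Wallis H=0.083, p=0.8857 (exact_permutation)
minimal detectable asymmetry difference at power 0.8: 18.0 points
```

i.e. the myelinated-thickness asymmetry of amputees (17 ± 5 %) is
indistinguishable from controls (17 ± 10 %) at this sample size, and only
a ~18-point group difference would have been detectable at power 0.8.

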
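# ldpgen

Geostatistical discrimination of white-matter lesion patterns from binary
3D MRI lesion masks.

Multiple sclerosis produces highly variable spatial patterns of white-matter
lesions, and comparing raw 3D masks across patients or timepoints is hard.
`ldpgen` reduces each lesion mask to two interpretable geostatistical
coordinates and plots them: the **Lesion Pattern Discrimination Plot (LDP)**.
It is aimed at neuroimaging researchers who already have lesion masks (or
lesion-probability maps) spatially normalized to the Montreal Normal Brain
template, in NIfTI-1 or Analyze-7.5 format.

## Method

For a binary mask `z(x)` (1 = lesion, 0 = background) the directional
empirical variogram along each grid axis is

    γ(h) = 1 / (2 n(h)) · Σᵢ (z(xᵢ) − z(xᵢ + h))²

computed over all n(h) voxel pairs separated by exactly h = 1..max_lag voxel
steps along that axis (default max_lag keeps lag distances within 15 mm).
An exponential variogram model

    γ(h) = c · (1 − exp(−3|h| / a))

is fitted per direction by unweighted nonlinear least squares, giving a range
`a` (mm; spatial continuity — larger for bigger, smoother lesions) and a sill
`c` (a proxy of total lesion load). The three directional pairs are condensed
to the LDP coordinates

    ā = ln(mean(aₓ, a_y, a_z)),   c̄ = ln(mean(cₓ, c_y, c_z))

(the log of the arithmetic mean, not the mean of logs). Per-direction
log-pairs give the *Component LDP*, which exposes anisotropy, e.g. lesions
stretched along the z axis.

## Worked example

Generate three synthetic lesion scenes (mild → severe ladder) and run the
batch pipeline:

```sh
python - <<'EOF'
from ldpgen.fixtures import LesionSceneSpec, ellipsoid_scene, write_scene_nifti
specs = [
    LesionSceneSpec(shape=(40,40,40), n_lesions=4,  radius_mm=(2.0,2.0,2.0), seed=21),
    LesionSceneSpec(shape=(40,40,40), n_lesions=10, radius_mm=(2.5,2.5,2.5), seed=22),
    LesionSceneSpec(shape=(40,40,40), n_lesions=20, radius_mm=(3.0,3.0,3.0), seed=23),
]
for i, s in enumerate(specs, 1):
    write_scene_nifti(ellipsoid_scene(s), f"scene{i}.nii")
EOF
ldpgen --inputs scene1.nii scene2.nii scene3.nii \
       --var-out MNI.var --ldp-out MNI_LDP.png --component-out MNI_LDP_xyz.png
```

This prints

```
processed 3/3 input file(s)
  scene1.nii: id 1
  scene2.nii: id 2
  scene3.nii: id 3
variogram table: MNI.var
MS-LDP: MNI_LDP.png
Component MS-LDP: MNI_LDP_xyz.png
```

and `MNI.var` contains one row of log-scale coordinates per input:

```
ID	ln(avg(a[xyz]))	ln(avg(C[xyz]))	ln(aX)	ln(CX)	ln(aY)	ln(CY)	ln(az)	ln(CZ)	File
1	1.58328	-6.32345	1.52590	-6.28166	1.58314	-6.28136	1.63768	-6.41301	scene1.nii
2	1.93074	-4.57529	1.99252	-4.46780	1.88577	-4.58166	1.91078	-4.68860	scene2.nii
3	2.00286	-3.41368	1.89092	-3.50875	2.16233	-3.31707	1.93351	-3.42447	scene3.nii
```

Reading the numbers: from scene 1 to scene 3 the lesion ladder grows both in
lesion size and in total load, so `ln(avg(a))` climbs from 1.58 to 2.00 (more
spatial continuity) and `ln(avg(C))` from −6.32 to −3.41 (more lesion load).
The run also writes one variogram plot per input
(`scene1.nii_variograms.png`, …: empirical points, fitted curves and (a, c)
markers per direction, red/green/blue = x/y/z) plus the LDP and Component
LDP scatter plots. Probability maps are binarized with `--threshold`
(default 0.5, strict `>`); `--max-lag`, `--guess-a`, `--guess-c`,
`--plot-size` and a `key=value` config file expose the remaining knobs.

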
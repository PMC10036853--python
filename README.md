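# osteomorph

Automated shape modelling and morphometry of paediatric lower-limb bones
(pelvis, femur, tibia/fibula) from segmented surface meshes.

Manual measurement of bone geometry from MRI segmentations is slow and
observer-dependent. `osteomorph` automates the whole chain used in
subject-specific musculoskeletal modelling:

1. **Template correspondence** — a per-bone template mesh is fitted to each
   segmented surface (rigid/affine ICP initialization, then iterative
   Gaussian radial-basis-function warping on a coarse-to-fine kernel-width
   schedule), so every bone in a dataset shares nodal topology.
2. **Statistical shape model** — after centre-of-mass and Procrustes
   alignment, PCA over the corresponded node coordinates yields the mean
   mesh and principal components of shape variation.
3. **Automatic landmarks & ISB frames** — anatomical landmarks are
   propagated from template anchors and refined from sphere/cylinder fits
   to labelled surface patches; right-handed anatomical frames
   (x anterior, y proximal, z to the subject's right) follow the
   International Society of Biomechanics convention.
4. **Morphometry** — the standard clinical measures are computed per bone:

   | measure | definition |
   |---|---|
   | anteversion | neck axis (head-sphere centre ← neck-cylinder centre) vs. posterior condylar axis, transverse plane, signed, positive anterior |
   | neck-shaft angle | neck axis vs. distally-directed shaft axis, unprojected 3-D angle |
   | femoral mechanical angle | knee axis (most distal condyle points) vs. mechanical y-axis, coronal plane |
   | tibial torsion | posterior tibial condylar axis vs. malleolar axis, transverse plane, signed, positive external |
   | tibial mechanical angle | tibial condylar knee axis vs. mechanical y-axis, coronal plane |

   plus ten linear measures (ASIS/PSIS width, pelvis depth, hip-centre
   distance, femoral head diameter, femoral/tibial length, epicondylar,
   condylar and malleolar width) and vessel radius/length from centerline
   polylines and lumen surfaces.

Because no imaging data ships with the package, every stage is validated
against a **synthetic bone generator**: implicit unions of spheres and
capsules polygonized by marching cubes, whose neck-shaft angle,
anteversion, torsion, widths and lengths are set *exactly* by
construction. The generator is first-class, tested code — it defines the
study conditions all accuracy claims refer to.

## Worked example

```python
import osteomorph as om

# a synthetic femur with exactly known geometry
model = om.generate_femur(om.FemurSpec(
    femoral_length=380, neck_shaft_angle_true=130, anteversion_true=15), seed=1)

report = om.measure_bone(model.mesh, "femur", "right")
print(f"anteversion        {report.angular['anteversion']:.2f} deg")
print(f"neck-shaft angle   {report.angular['neck_shaft']:.2f} deg")
print(f"femoral length     {report.linear['femoral_length']:.1f} mm")
print(f"fit RMS            {report.provenance['correspondence']['final_rms']:.3f} mm")
```

prints

```
anteversion        15.10 deg
neck-shaft angle   130.02 deg
femoral length     380.0 mm
fit RMS            0.201 mm
```

i.e. the pipeline recovers the generator's true anteversion (15°) within
0.1°, the neck-shaft angle (130°) within 0.05°, and the femoral length
(380 mm) within 0.05 mm, with a template-fitting residual of 0.2 mm RMS.

The same workflow is available from the shell:

```bash
osteomorph synth --bone femur --n 5 --seed 1 --out work/
osteomorph measure --mesh work/dataset/femur_000.ply --bone femur \
    --side right --out report.json --csv report.csv
osteomorph run --config pipeline.yaml      # batch: synth -> fit -> SSM -> measure
```

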
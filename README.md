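# skinfuse

Markerless fusion of pre-acquired CT/MR volumes with real-time ultrasound
hinges on one geometric problem: putting the volumetric image into the
reference frame of the US probe without gluing physical markers to the
patient. `skinfuse` implements the software core of such a system:

1. **Skin segmentation** — given a CT/MR volume and a skin *iso-value*
   (the intensity threshold separating air from tissue; a Hounsfield value
   on CT), each slice is segmented by growing the background region from
   the slice corners over 4-connected pixels. Growth stops at the first
   pixel whose intensity is at or above the iso-value, so the body is
   segmented *by exclusion*: a per-voxel "mock-up" grid marks background
   (0), body edge (1) and unreached interior (2), internal air pockets
   included in the body. Marching cubes on the binarised grid yields a
   watertight skin mesh in world millimetres.
2. **Rigid co-registration** — the segmented skin surface X₁ is aligned to
   the surface X₂ acquired by a depth camera (which shares the tracking
   frame with the US probe): front-facing cut by vertex normals, coarse
   PCA orientation, translation pinning one operator-selected *virtual
   landmark*, then two ICP refinement stages on a spherical region of
   interest — an untrimmed stage followed by a trimmed stage that keeps
   the 80% closest correspondences per iteration. The result is a rotation
   matrix and translation vector applied to the volume header.
3. **Error quantification** — the symmetric Hausdorff distance
   `d(X₁,X₂) = max{ max_x min_y ‖x−y‖, max_y min_x ‖x−y‖ }` (k-d tree
   accelerated), per-vertex distance colour maps (0 mm → blue, ≥ 5 mm →
   red), and the target registration error
   `TRE = (1/N) Σ ‖landmarkᵢ_registered − landmarkᵢ_target‖`.
4. **Synthetic phantoms** — CT/MR-like volumes (ellipsoid, cylindrical,
   or abdomen-like bodies; optional bed slab, internal cavity, intensity
   noise) and simulated depth-camera acquisitions (partial frontal
   coverage, resampling, point noise, known ground-truth pose), so every
   pipeline stage can be validated against analytic truth.

Intended users: researchers and engineers working on image-guided
ultrasound, surface-based registration, or multimodal fusion who need a
tested, scriptable reference pipeline with fully synthetic ground truth.

## Worked example

`examples/02_register_camera.py` segments an abdomen-like phantom,
simulates a depth camera displaced by a known 15° / 40 mm rigid pose with
0.5 mm point noise and 60% frontal coverage, and registers the two
surfaces:

```
camera surface: 2000 points, true rotation 15.0 deg
per-stage RMS (mm): [2.345, 0.516, 0.428]
ICP iterations per stage: [5, 4]
pose recovery error: 0.106 deg rotation, 0.115 mm translation
```

The per-stage RMS shows the pipeline tightening from the landmark
initialisation (2.3 mm) through the two ICP stages (0.43 mm, at the level
of the injected noise); the recovered pose differs from the ground truth
by a tenth of a degree and a tenth of a millimetre. The other examples
cover segmentation and subsampling robustness (`01`), error-map rendering
(`03`) and the distance/tilt/landmark-misplacement robustness study (`04`),
which prints a per-scenario TRE table (all scenarios land below 0.5 mm on
the synthetic phantom).

## Command line

Every step is also a `skinfuse` subcommand:

```bash
skinfuse synth phantom --shape abdomen -o vol.nii.gz --truth truth.json --seed 7
skinfuse segment vol.nii.gz --iso -300 -o skin.ply
skinfuse synth camera skin.ply --rotate-deg 10 --translate 15,-5,20 -o cam.ply
skinfuse register skin.ply cam.ply --landmark-skin 0,100,-30 \
        --landmark-camera 14,96,-12 -o result.json
skinfuse error-map skin.ply cam.ply --cap 5 -o skin_coloured.ply
skinfuse run vol.nii.gz cam.ply --iso -300 --landmark-skin ... --landmark-camera ...
```

`result.json` carries the 4×4 homogeneous matrix (row-major), per-stage
RMS, the Hausdorff distance and per-stage iteration counts.

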
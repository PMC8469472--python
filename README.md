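# ado — automated digital odontometry

`ado` is a fully automated measurement pipeline for 3D tooth-crown meshes
(PLY/STL/OBJ), aimed at micro-CT enamel-cap reconstructions. It

1. estimates per-vertex principal/Gaussian curvature by local quadric fits,
2. detects the **occlusal border** (the closed maximal-Gaussian-curvature
   loop encircling the central occlusal depression) and derives the tooth
   coordinate frame from it — vertical axis from the mean border normal,
   mesio-distal axis from the ellipse fitted to the border (calibrated
   against the crown's maximal extent), vestibulo-oral axis completing a
   right-handed frame, iterated to convergence,
3. cuts the crown into *Ns* (default 80) equally spaced transverse contours
   perpendicular to the mesio-distal axis,
4. detects morphological landmarks per contour — cusp tips, deepest
   occlusal point (parallel-tangent or contour-curvature mode), lateral
   maximal-convexity points and, on enamel-cap band contours, the two
   shared cervical enamel edges that split each contour into enamel and
   dentine sectors,
5. measures per-section odontometric parameters (widths, occlusal depth,
   tip-line angle, contour lengths, areas, cervical shortest distances),
   aggregates them over the stack (maxima with section indices, averages
   with marginal-section exclusion) and emits the dentine-as-percent-of-
   enamel comparison table.

Because real scan data are not redistributable, the package ships a
synthetic-tooth module (`ado.synthetic`) that generates watertight two-cusp
crown fixtures — outer "enamel" surface, inner "dentine" surface and the
welded enamel-cap shell — with analytic ground-truth landmarks and
dimensions. All tests run against these fixtures.

## CLI

```sh
ado synth --preset molar-shell --out fixtures/    # synthetic fixtures + ground truth
ado convert crown.stl crown.ply
ado repair crown.ply fixed.ply --fill-holes --smooth 2 --faces 20000
ado curvature fixed.ply --radius 1.5 --out curvature.csv
ado orient fixed.ply --percentile 90 --out frame.json
ado section fixed.ply --ns 80 --out contours.csv
ado landmarks fixed.ply --mode euclidean
ado measure fixed.ply --ns 80
ado report fixed.ply
ado run fixed.ply --ns 80 --out results/ --svg    # full pipeline
```

`ado run` writes every stage's artifact (frame.json, contours.csv,
landmarks.csv, sections.csv, report.json, optional per-section SVG) so runs
can be audited. Configuration is a flat `key = value` file
(`--config pipeline.cfg`) with CLI overrides; per-section landmark
overrides are supported via the `landmark_overrides` config entry. Runs are
deterministic: identical inputs give byte-identical outputs.

## Library

```python
from ado import (BicuspidSpec, generate_bicuspid, estimate_curvature,
                 iterate_orientation, generate_planes, cut_surface,
                 PipelineConfig, run_pipeline)

fix = generate_bicuspid(BicuspidSpec())
result = run_pipeline(PipelineConfig(ns=80, output_dir="out"), None, surface=fix.shell)
print(result.ratios)   # dentine/enamel percentage table
```

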
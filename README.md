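# lenstomo

Quantitative analysis of electron tomograms of lens fiber cells, built
for the question of how αA-crystallin is organized on the lens
cytoskeleton.  In conical tomograms of immunogold-labeled fiber cells,
antibody/gold conjugates (~3 nm and ~7 nm nominal diameter) mark
αA-crystallin positions; the spatial statistics of the gold — and of the
protein densities in unlabeled cells — reveal that monomers decorate
thin (2–3 nm) cytoskeletal filaments at a ~7 nm repeat, dimers at twice
or three times that repeat, with ~15 nm "bead" clusters and recurring
geometric motifs (files, isosceles triangles, squares, tetrahedra,
pyramids).

The package implements the full measurement chain as a library, a CLI
(`lenstomo`), and a synthetic-tomogram generator with exact ground truth
so that every stage can be verified without the original tomograms:

1. **Volume I/O** — MRC/CCP4 density maps (8-bit, 0–255 intensities,
   default 0.8 nm voxels), TSV particle/connection tables.
2. **Segmentation** — split the tomogram into a gold map and the
   "reference space" at an intensity threshold; partition foreground
   into particles by marker-based 3D watershed; measure volume `V`,
   equivalent-sphere diameter `d = (6V/π)^{1/3}`, peak intensity and the
   intensity-weighted mass center.
3. **Classification** — labeled mode: *yellow* if `d > 4 nm` OR peak
   `> 200`, else *blue* if `d > 2 nm` OR peak `> 150` (yellow rule
   first); unlabeled mode: diameter bands (2, 3.5) / (3.5, 7) nm and
   *aggregates* above 7 nm, with geometric (corner-octant) and
   connectivity-based aggregate exclusion.
4. **Connection networks** — all particle pairs closer than the
   class-pair cutoff (blue–blue 10 nm, blue–yellow 28 nm labeled /
   24 nm unlabeled, yellow–yellow 32 nm) become Euclidean connections.
5. **Spacing models** — 1–2 component Gaussian fits to connection
   distances, reported as center ± HWHM (`HWHM = σ√(2 ln 2)`), via
   histogram least squares, truncated-mixture maximum likelihood (with
   an optional random-pair `r²` background), or a window-refined peak
   fit.
6. **Motifs & mass** — files, triangles, squares, tetrahedra and
   pyramids in the connection graph; molecular mass from particle
   volume at the protein density 0.0013 nm³/Da.

## Worked example

Simulate a labeled scene (monomer decoration at 7.5 nm, single gold
population) and run the labeled pipeline end to end:

```python
from lenstomo import (SceneParams, build_scene, rasterize, PipelineConfig,
                      run_pipeline, ClassificationRules)
from lenstomo.spacing import hwhm_to_sigma

params = SceneParams(seed=11, box_size=120, n_filaments=8,
                     decoration_mode="monomer", base_spacing=7.5,
                     spacing_jitter_sd=hwhm_to_sigma(3.5),
                     gold_small_fraction=1.0, gold_label_fraction=0.9,
                     bead_fraction=0.0)
truth = build_scene(params)
vol = rasterize(truth, params)

config = PipelineConfig.labeled(seed=1,
                                rules=ClassificationRules.labeled_diameter_only(),
                                fit_method="windowed_peak")
report = run_pipeline(config, vol=vol)
```

prints (via the report fields):

```
scene: 107 decoration sites, 97 gold conjugates
        blue: n=73, diameter 3.0 +/- 0.4 nm
      yellow: n=12, diameter 4.5 +/- 0.3 nm
unclassified: n=1, diameter 2.0 +/- 0.0 nm
blue-blue: 60 connections, Gaussian center 8.06 nm (HWHM 2.12 nm)
```

The generator placed decoration sites at a 7.5 nm repeat; after
rasterization at ~2 nm resolution with noise, segmentation, diameter
classification and network construction, the fitted blue–blue spacing
center recovers 8.06 nm — within a nanometre of the generative repeat.
(Synthetic gold saturates the 8-bit range, so the example classifies by
the diameter rule alone; the intensity-OR rules are the defaults for
real maps.)

The same analysis is available from the shell:

```sh
lenstomo simulate --seed 11 --out-volume scene.mrc
lenstomo run-all --mode labeled --in scene.mrc --seed 1 --out results/
```

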
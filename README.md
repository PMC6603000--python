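# rosellapipe

Automated staging of autophagy and mitophagy from dual-channel ratiometric
(Rosella reporter) confocal z-stacks, plus lysosome sizing from lysotracker
stacks — with a synthetic field simulator so the whole pipeline can be
exercised and validated without microscope data.

## The problem

The Rosella reporter fuses pH-stable DsRed with pH-quenchable pHluorin.
Fused to LC3 it labels the autophagy pathway: phagophores and
autophagosomes are bright in both channels, while delivery to the acidic
lysosome quenches the green signal, so autolysosomes appear red-only.
Fused to the mitochondrial ATP5C1 subunit, the same logic marks mitophagy
events as red-retaining, green-quenched bodies derived from the
mitochondrial network.  Imaging fields of live cells (5 z-planes for
Rosella-LC3, 11 for ATP5C1-Rosella, 0.2152 µm pixels, 400 nm z-steps)
therefore encode the pathway state in vesicle morphology and the green:red
ratio.

`rosellapipe` implements the complete image-analysis platform around that
idea:

* **Preprocessing** — flatfield correction, a Gaussian-approximation PSF
  model, and Richardson–Lucy deconvolution (10 iterations).
* **Channel masks** — DsRed vesicles via difference-of-Gaussians band-pass
  (20/1 − 20/7 px, > 400), top-hat (disk 25, > 1200) with an overlap-based
  substitution rule, watershed splitting and a confirmatory second
  band-pass; pHluorin vesicles via a large-vesicle band-pass (100/1 −
  100/5, > 1000) OR'd with Laplacian-of-Gaussian edges (20/1, < −2000);
  an autolysosome rescue mask from the top-hat of the complemented
  green:red ratio image.
* **Hollow-vesicle (autophagosome) detection** — Butterworth high-pass
  (cutoff 10, order 5) + Euler-number topology selection of one-hole
  components, a circle Hough route on the raw green channel validated by
  intensity statistics (MAD > 20, red 0.9-quantile < 300), and a shape
  filter on size (50–10,000 voxels) and two sphericity indices.
* **Progressive-exclusion classification** into phagophore, autophagosome,
  early autolysosome and late autolysosome, and per-field statistics:
  autophagic vacuoles (autophagosomes + early + late autolysosomes) and
  the autophagy rate-constant (phagophores / autophagic vacuoles).
* **Mitophagy** — mitochondrial segmentation (DoG 50/1 − 50/2, > 12),
  ratio-seeded event detection (mean ratio < 0.6) grown inside a wider
  band-pass limit by morphological reconstruction, and the
  autophagy-resource split between mitochondrial and non-mitochondrial
  autophagy.
* **Lysotracker assay** — vesicle segmentation (DoG/LoG OR rule) and
  major-axis sizing on the z-maximum projection.
* **Simulator** — renders dual-channel fields with per-class channel
  signatures, PSF blur, vignette and Poisson + read noise, together with
  voxel-level ground truth.

## Worked example

```python
from rosellapipe import run_autophagy_field
from rosellapipe.simulate import SceneSpec, render_scene

spec = SceneSpec(shape=(5, 256, 256), seed=1,
                 n_phagophore=9, n_autophagosome=4,
                 n_early_autolysosome=4, n_late_autolysosome=14)
stack, truth = render_scene(spec)
result = run_autophagy_field(stack)
print(result.summary.counts)
print(round(result.summary.autophagy_rate, 3), result.summary.autophagic_vacuoles)
```

prints

```
{'phagophore': 9, 'autophagosome': 4, 'early_autolysosome': 4, 'late_autolysosome': 14, 'unclassified': 0}
0.409 22
```

— all 31 rendered vesicles are found and staged correctly, and the field's
autophagy rate-constant is 9 phagophores / 22 autophagic vacuoles = 0.41.

The same workflows are available from the shell:

```bash
rosellapipe simulate --config basal --n-fields 3 --seed 1 --out fields/
rosellapipe autophagy --in fields/ --out staged/        # vesicles.csv, fields.csv
rosellapipe mitophagy --in mito_fields/ --out mito/     # mitophagy_fields.csv
rosellapipe lysotracker --in lyso_fields/ --out lyso/   # lysosomes.csv
rosellapipe report --fields staged/fields.csv --out report/
```

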
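# aggrequant

Quantification of protein aggregation in fluorescence microscopy, built for
aggrephagy studies: cells accumulating p62 bodies or aggregate-prone cargo
such as the ALS-associated SOD1(A4V)/SOD1(G93A) mutants, imaged statically
or by time-lapse, together with the behavioral and survival readouts that
typically accompany such experiments.

## The core statistic

For one cell and one fluorescence channel, let `m` and `s` be the mean and
(sample) standard deviation of intensity over all pixels of the cell. The
pixels whose intensity strictly exceeds

```
t = m + k·s          (k = 3 by default)
```

are taken as the regions of aggregates (p62 bodies, SOD1 clusters). The
**clustering index** is

```
CI = Σ_{i ∈ selected} I_i / m
```

— the summed fluorescence of the selected bright regions divided by the
whole-cell mean. It is dimensionless, zero for a cell with no pixels above
threshold, and invariant under multiplicative rescaling of the image
(camera gain, exposure, first-order photobleaching). The same statistic
computed per frame of a movie on a cargo channel is the **aggregation
index**, giving per-cell aggregation trajectories.

Around this core the package provides:

* `aggregate_quant` operations (`quantify_cell`, `select_aggregate_pixels`,
  `label_puncta`): per-cell thresholding, puncta counting/sizing, index;
* `coloc`: masked per-cell Pearson colocalization of channel pairs;
* `pla`: proximity-ligation-assay scoring — nuclei segmentation (Otsu),
  single-scale blob detection of PLA dots, dots per nucleus;
* `timelapse`: per-frame aggregation indexes and group mean ± SEM curves;
* `behavior`: tadpole touch-escape trials classified as normal / reduced /
  no response from (t, x, y) tracks and well geometry, best-of-three
  scoring, contingency tables;
* `survival_stats`: Kaplan–Meier survival from bleb/burst event times,
  plus two-sided Mann–Whitney, Fisher's exact, and one-way ANOVA with
  Bonferroni pairwise comparisons;
* `synth`: generators for every input above with ground truth, so the
  whole pipeline is testable without any real recordings.

## Worked example

```python
from aggrequant import quantify_cell
from aggrequant.synth import SceneSpec, generate_cell_image

img, mask, truth = generate_cell_image(SceneSpec(seed=7))   # 5 puncta, SNR 10
res = quantify_cell(img.channel("GFP"), mask, 1)
print(f"cell 1: mean={res.cell_mean:.2f} sd={res.cell_sd:.2f} "
      f"threshold={res.threshold:.2f}")
print(f"  clustering index={res.clustering_index:.2f}  "
      f"n_puncta={res.n_puncta}  areas={res.punctum_areas}")
```

prints

```
cell 1: mean=101.17 sd=7.38 threshold=123.33
  clustering index=132.07  n_puncta=5  areas=[20, 22, 18, 19, 20]
```

The generated cell has background 100 AU, noise σ = 5 AU, and five
Gaussian puncta of amplitude 50 AU; the mean + 3·SD threshold lands at
123.3 AU, so only the punctum cores are selected. All five ground-truth
puncta are recovered, each as a ~20-pixel component, and the summed
selected fluorescence is ~132 times the whole-cell mean intensity. A cell
with purely diffuse signal scores an index of 0.

The same operations are available from a shell:

```
aggrequant simulate scene --seed 7 --out-dir fixtures/
aggrequant quantify --image fixtures/scene.tif --mask fixtures/scene_mask.tif \
    --channels GFP --channel GFP --out results.csv
```

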
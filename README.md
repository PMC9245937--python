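# synapcover

Quantitation of **inhibitory synaptic coverage** of cortical neurons from
two-channel confocal images, with fully synthetic ground-truth generators
for validation.

In post-mortem studies of multiple sclerosis (MS) cortex, inhibitory
(GABAergic) presynaptic terminals are visualized as GAD 65/67+ puncta
ringing the perikarya of layer-5 pyramidal neurons, which are delineated
with a neurofilament counterstain. The coverage statistic is

```
C′ = N_s / A(d)
```

where *N_s* is the number of GAD+ puncta overlapping the neuronal
membrane (the segmented boundary dilated by a band half-width) and
*A(d)* is the area of the segmented neuron in µm² (interior plus
delineated boundary). Counting puncta rather than summing their area
sidesteps the ill-defined synapse boundary. Neuron size is the same
interior + boundary area; degraded images are removed by four explicit
quality-control rules (poor contrast, multiple processes captured,
incorrect neuron, two neurons in one image).

Because the underlying tissue data are not public, the package ships
simulators that plant exact ground truth:

- `simulate` — renders confocal-like image stacks (red: neurofilament
  soma, green: membrane puncta at an exact planted count, blue: nucleus),
  the four QC-degenerate image types, and brightfield DAB/haematoxylin
  images with an exact positive-pixel count;
- `cohort` — draws per-case cohort tables (markers, lymphocytes, neuron
  density, covariates) from a Gaussian copula so that any target Spearman
  correlation can be planted per genotype stratum.

The analysis half mirrors standard neuropathology statistics: Spearman
rank correlations (exact permutation p for small tie-free samples),
covariate-adjusted OLS with standardized β (controlling for age, sex,
post-mortem interval, optionally fibrinogen burden), genotype-stratified
correlations, and group contrasts reported as mean ± SEM with percent
differences. DAB immunohistochemistry is quantified by colour
deconvolution into haematoxylin/DAB optical densities and reported as
millions of positive pixels per mm².

## Worked example

```python
from synapcover import (PipelineConfig, render_neuron_image, quantify_image)

cfg = PipelineConfig(pixel_size_um=0.2)
stack, truth = render_neuron_image(
    soma_area_um2=450, coverage=0.348, pixel_size=0.2, seed=1)
result = quantify_image(stack, cfg)
print(f"planted {truth.n_membrane_puncta} puncta on {truth.soma_area_um2:.0f} µm²"
      f" (coverage {truth.planted_coverage:.3f})")
print(f"recovered N_s={result.n_synapses}, A(d)={result.area_ad_um2:.1f} µm², "
      f"C'={result.coverage:.3f} puncta/µm², QC={result.qc_status}")
```

prints

```
planted 157 puncta on 450 µm² (coverage 0.349)
recovered N_s=154, A(d)=449.7 µm², C'=0.342 puncta/µm², QC=pass
```

i.e. the pipeline segments a 450 µm² soma to within a fraction of a
percent and recovers 154 of 157 planted membrane puncta (a ~2–3 %
underestimate of C′, dominated by diffraction-limited punctum pairs that
merge at 0.2 µm/pixel sampling).

The same flow is available from a shell:

```bash
synapcover simulate-images --n-cases 3 --neurons-per-case 10 \
    --coverage 0.32 --soma-area 450 --pixel-size 0.2 --seed 1 --out-dir run/
synapcover quantify --images-dir run/images --out-dir run/
synapcover simulate-cohort --seed 1 --out run/cohort.csv
synapcover analyze --cohort run/cohort.csv --per-case run/per_case.csv --out-dir run/
synapcover run --config config.yaml --out-dir run/   # all stages + manifest
```

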
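# berryforage

Tools for quantifying **selective berry foraging by GPS-collared brown bears**
(*Ursus arctos*) during hyperphagia, the pre-hibernation feeding period when
bilberry (*Vaccinium myrtillus*), lingonberry (*V. vitis-idaea*) and crowberry
(*Empetrum* spp.) dominate the diet in boreal production forests.

The package covers the full analysis chain:

1. **Trajectory classification** — 30-min GPS fix streams are scanned for
   maximal runs of at least three consecutive fixes whose every step distance
   lies in 25–300 m (slow, continuous movement characteristic of berry
   foraging); failed fixes invalidate the neighbouring steps; trajectories
   near known attractants (slaughter dumps, oat fields) are excluded within a
   200-m buffer.
2. **Plot protocol** — 1-m² berry quadrats are placed by the field rule
   (0–9 m offset from the last digit of the Y coordinate, cardinal direction
   from the last digit of X, mirrored away from foraging signs), annotated
   with habitat / elevation / NDVI / slope / aspect from raster layers, and
   pooled with uniformly random *available* plots into a used–available
   table.
3. **Hurdle mixed models** — berry counts are zero-inflated and
   overdispersed, so occurrence and abundance are modelled separately: a
   binomial GLMM (logit link) for presence, and a **zero-truncated
   negative-binomial GLMM** (log link, variance μ + μ²/θ) for counts on the
   occupied plots, each with a bear-id random intercept integrated out by
   adaptive Gauss–Hermite quadrature. Model selection is stepwise backward by
   likelihood-ratio tests (α = 0.05, interactions before their main effects);
   post-hoc habitat contrasts use single-step max-|z| familywise adjustment;
   a species × day × habitat count model tests the seasonal shift; Gaussian
   LMMs explain sugar content (TSS, %Brix).
4. **Synthetic studies with known truth** — a landscape / berry-field /
   movement simulator generates every input the pipeline consumes, with all
   generating coefficients recorded, so classification semantics, estimator
   bias, interval coverage and the emergence of the selection pattern are all
   testable without field data.

The GLMM engine, the truncated-NB likelihood, the selection and contrast
machinery are implemented in this package; design matrices come from patsy
and standard numerics from numpy/scipy/pandas.

## Worked example

```python
import numpy as np
from berryforage import RunConfig, assemble_dataset, make_scenario
from berryforage.pipeline import run_berry_selection

scn = make_scenario(seed=3)                      # 7 bears, 28 days, known truth
rng = np.random.default_rng(3)
table = assemble_dataset(scn.foraging_plots, scn.random_plots, rng)
res = run_berry_selection(table, "bilberry", RunConfig(seed=3), rng)
print(res.abundance.coef_table().round(3))
```

prints the final zero-truncated NB abundance model, e.g.

```
                        estimate     se      z      p
Intercept                  1.678  0.326  5.152  0.000
habitat[clearcut]          0.854  0.251  3.400  0.001
habitat[mature_forest]     0.385  0.224  1.720  0.085
habitat[young_forest]      0.345  0.225  1.535  0.125
plottype                   0.712  0.092  7.716  0.000
elevation                  0.004  0.001  5.319  0.000
```

`plottype` is the used-vs-available indicator (random = 0, bear = 1):
exp(0.712) ≈ 2.0, i.e. plots where bears actually foraged held about twice
as many ripe bilberries as random plots *after* adjusting for habitat and
terrain — selection for berry-rich patches beyond what the mapped covariates
explain. Running the same analysis for lingonberry drops `plottype` from the
abundance model: bears in this system select bilberry patches, not
lingonberry patches, matching the species-specific pattern the models are
built to detect.

The `examples/` directory has one short script per capability
(classification, simulation, hurdle selection, seasonal shift, sugar models).
A thin CLI mirrors the pipeline stages:
`berryforage simulate | classify | sample | fit | report`.

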
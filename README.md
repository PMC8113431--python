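# petdenoise

Post-reconstruction enhancement of whole-body [18F]FDG PET images with a 3D
denoising convolutional network, together with the full quantitative and
statistical evaluation battery, exercised end to end on synthetic phantoms.

PET image noise rises as acquisition time per bed position falls. The idea
implemented here: because list-mode acquisition lets one reconstruct
arbitrary sub-intervals of a frame, a single long acquisition yields
aligned pairs of short-time (noisy) and long-time (clean) reconstructions
of the same anatomy. A residual 3D CNN — 10 same-padded 3×3×3 convolution
layers, 68 filters, batch normalization on interior layers, ReLU after all
but the last, no pooling — is trained on 5-slice block pairs with MSE loss
and SGD to predict the noise map, which is subtracted from the input. Two
networks are trained, one for 1-min and one for 1.5-min inputs, and applied
to whole volumes by sliding 5-slice windows.

Evaluation follows the clinical playbook: per-lesion SUVmax and SUVpeak
(mean in a 1 cm³ sphere), liver noise as the coefficient of variation
COV = SD/mean over three 6-cm ROIs on alternating slices, Bland–Altman
limits of agreement, and — across the five image sets (4 min; 1.5 min ±
CNN; 1 min ± CNN) — Friedman omnibus tests with all ten pairwise Wilcoxon
signed-rank tests at the Bonferroni threshold 0.05/10 = 0.005.

Because no patient data ship with the package, a first-class synthetic
module generates whole-body-like phantoms (uniform liver, spherical
hotspots of known uptake, Poisson counting noise, exact multinomial
list-mode splitting, and a β-regularization resolution surrogate) so the
whole pipeline runs from nothing on one CPU.

## Worked example

```python
from petdenoise.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(n_test_subjects=10, seed=1))

cov = (result.metrics[result.metrics.lesion.isna()]
       .pivot(index="subject", columns="image_set", values="cov"))
print(cov.mean().round(4))
```

prints the mean liver COV per image set over the 10 synthetic subjects:

```
image_set
1 min          0.1259
1 min CNN      0.0909
1.5 min        0.1057
1.5 min CNN    0.1018
4 min          0.0740
dtype: float64
```

Noise falls with longer acquisition (1 min > 1.5 min > 4 min), and each
CNN-enhanced set is less noisy than the set it was derived from. On the
same run the mean relative change of lesion SUVmax between 1.5 min CNN and
1.5 min is −2.2% (SUVpeak −1.6%): quantification is preserved while noise
drops. The 1-min network removes more noise but lowers SUVmax slightly more
(−5.8%), the same qualitative trade-off reported clinically. `result.report.pairwise` holds the
ten Wilcoxon rows per metric with the 0.005 significance threshold applied,
and `result.report.summary()` prints the omnibus and pairwise tables.

A CLI mirrors the stages (`petdenoise simulate | prepare | train | denoise
| evaluate | compare | run-all`); see `petdenoise --help`.

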
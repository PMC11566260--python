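# fgscontrast

Quantitative comparison of paired-modality fluorescence images for
fluorescence-guided surgery research.

## The problem

In fluorescence-guided surgery, a targeted dye makes tumor tissue glow under
a dedicated camera. Whether a newer imaging window (e.g. shortwave-infrared,
SWIR, 1000–1700 nm) actually outperforms the established near-infrared
window (NIR, 700–900 nm) on *clinical* tissue cannot be judged by eye: the
two cameras see the same tissue slice with different geometry, blur, noise
and background, so the comparison needs registration plus contrast metrics
that are robust to those differences. `fgscontrast` implements that
comparison pipeline for researchers evaluating imaging systems against a
histopathology ground truth, together with the phantom computations used to
characterize the instruments themselves.

## Metrics

With `MFI` the mean fluorescence intensity over a region of interest and
`σ` a population standard deviation:

* **TBR** — tumor-to-background ratio over a slice:
  `TBR = MFI_tumor / MFI_background`
* **aCNR** — adapted contrast-to-noise ratio, with a doubled background SD
  for noise robustness:
  `aCNR = (MFI_tumor − MFI_background) / (2 σ_background)`
* **SNR (dB)** — sensitivity relative to a zero-signal control well:
  `SNR = 20 · log10((MFI_signal − MFI_control) / σ_control)`,
  with detection requiring `SNR > 9.5 dB` (the 3σ rule, since
  `20 · log10(3) = 9.54 dB`).

The key structural idea is line-based border analysis: a line drawn through
the tumor perpendicular to the pathology border is widened to 11 pixels,
collapsed back to one pixel with a Gaussian-weighted mean, and converted to
per-position TBR and aCNR profiles. The position where the aCNR profile
falls through **1** — intensity dropping below background mean plus two
background SDs — estimates the tumor border; its distance to the pathology
border measures each modality's border-localization accuracy. Pixel-level
agreement between the modalities is summarized by OLS r², Bland–Altman bias
(±2σ limits of agreement) and the tumor/background intensity-overlap
percentage. Study-level results are reported nonparametrically: median
(IQR) per modality and paired Wilcoxon signed-rank p-values.

Because clinical image sets of this kind are not generally public, the
package ships a first-class synthetic-data generator (`fgscontrast.synth`)
producing paired-modality scenes with known ground truth: tumor/background
contrast, modality-specific blur, sensor noise, an optional autofluorescent
background field (the SWIR failure mode), and a known similarity-transform
misalignment whose inverse is the exact registration oracle.

## Worked example

```python
import fgscontrast as fc

manifest = fc.make_synthetic_study("study_dir", n_slices=5, seed=0)
result = fc.run_study(manifest)
cols = ["parameter", "median_a", "median_b", "p_value", "n"]
print(result.comparison[cols].round(4).to_string(index=False))
print("crossing agreement:", result.agreement)
```

prints

```
                                    parameter  median_a  median_b  p_value  n
                       TBR whole tissue slice    1.4134    1.2445   0.0625  5
                      aCNR whole tissue slice    0.5803    1.5588   0.0625  5
          Tumor fluorescence intensity (a.u.) 1417.8236 1246.7627      NaN  5
     Background fluorescence intensity (a.u.) 1003.2776 1000.7584      NaN  5
                                TBR over line    1.2793    1.1691   0.0000 20
                               aCNR over line    0.9822    2.4472   0.0000 20
                                     AUC aCNR   87.3142  204.1025   0.0000 20
Absolute distance tumor border to aCNR=1 (mm)    0.1216    0.0517   0.0014 20
          Overlap pixels tumor/background (%)   99.7843   99.5784   0.1875  5

crossing agreement: {'positive_pct': 100.0, 'negative_pct': None, 'n_lines': 20}
```

(The full table also carries `q1_*`/`q3_*` IQR columns per modality.)
Reading it: modality A was generated with a true TBR of 1.43 and
modality B with 1.25 — the slice medians recover both. Modality B's higher
whole-slice and per-line aCNR reflects its lower noise floor plus the mild
noise attenuation of resampling it into A's frame during registration. Both
modalities localize the aCNR = 1 crossing within about one pixel
(0.1 mm) of the true border; `p_value` is the paired Wilcoxon test, and the
intensity rows carry no p-value because raw camera units are not comparable
across systems. The negative crossing agreement is undefined here because
the reference modality found a crossing on every line.

The same pipeline runs from the shell:

```bash
fgscontrast synth --out study_dir --n-slices 5 --seed 0
fgscontrast run --manifest study_dir/manifest.csv --out results_dir
fgscontrast phantom fwhm --image tube.tif --pitch 0.05
fgscontrast phantom sensitivity --csv wells.csv
fgscontrast phantom spectral --lamp lamp.csv --out correction.csv
```

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator's scope and limits, numerical conventions (population vs sample
SDs, interpolation, tie-breaking of multiple aCNR crossings, degenerate
inputs) and known limitations.
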
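# dermibc — the clock-sweep melanoma radar and paired reader-study scoring

Dermoscopy can separate early melanoma from clinically atypical nevi, but
deep-learning aids are opaque. An *imaging-biomarker cue* (IBC) takes the
opposite route: a single, human-interpretable image statistic, shown to the
clinician as an annotated overlay. `dermibc` implements one such cue — the
**clock-sweep melanoma radar** — together with the signal-detection
machinery needed to evaluate whether showing the cue changes clinicians'
diagnostic accuracy in a paired reader study.

## The statistic

Imagine a clock face superimposed on the lesion, noon at the top, sweeping
clockwise. For each angle θ the package averages the image brightness along
the clock arm from the lesion centroid to the peripheral margin, giving an
angular profile m(θ). The cue is

```
statistic = Δ / mean,   Δ = max_θ m(θ) − min_θ m(θ),   mean = ⟨m(θ)⟩_θ
```

a dimensionless measure of angular brightness irregularity: 0 for a
perfectly even lesion, larger for lesions with one dark or bright sector.
Three clock hands annotate the overlay: darkest angle (blue), brightest
angle (green), angle of maximum brightness variation (red), plus the
numeric Δ/mean bottom-right and an optional externally supplied ensemble
risk score ("Risk = x") top-left.

## Reader-study evaluation

Each reader classifies every image twice — without and with the cue —
against gold-standard pathology, melanoma positive. Per reader and
condition the package reports sensitivity, specificity and the
equal-variance Gaussian discriminability

```
d′ = z(hit rate) − z(false-alarm rate)
```

(with the 1/(2n) correction at extreme rates), compares conditions with
matched-sample t-tests (df = readers − 1), and renders the paired ROC
points (red = without cue, green = with cue). A published benchmark
study of ten readers × 78 images ships with the package
(`dermibc.reference`), including the reconstruction of its confusion
counts from the printed percentages.

## Worked example

```python
>>> from dermibc import (LesionSpec, generate_lesion_image, segment_lesion,
...                      radial_profile, sweep_statistic)
>>> spec = LesionSpec(angular_modulation=(0.2, 0.0))   # A = 0.2, so Δ/mean = 0.4
>>> image, truth = generate_lesion_image(spec)
>>> mask = segment_lesion(image)
>>> result = sweep_statistic(radial_profile(image, mask))
>>> round(result.statistic, 4)
0.3963
>>> truth.delta_over_mean
0.4
```

The measured 0.3963 recovers the analytic 0.4 to within 1% — the residual
comes from bilinear interpolation near the centroid, where a pixel spans
many clock angles. Scoring the benchmark study:

```python
>>> from dermibc.reference import reconstruct_response_table
>>> from dermibc import build_study_report
>>> report = build_study_report(reconstruct_response_table())
>>> report.loc["Mean", ["dprime_without", "dprime_with", "dprime_increase"]]
dprime_without     0.94
dprime_with        1.41
dprime_increase    0.47
Name: Mean, dtype: float64
```

Mean discriminability rises from 0.94 to 1.41 when readers see the cue — a
gain of 0.47, roughly half a d′ unit of extra separation between melanoma
and nevus evidence.

The same stages are scriptable from a shell:

```
ibc generate --out work/      # synthetic lesions + simulated responses
ibc sweep work/lesion_000.png # clock-sweep result as JSON
ibc render work/lesion_000.png --risk 0.17
ibc score work/responses.csv --out report.csv --fig roc.png
ibc demo                      # the whole pipeline end-to-end
```

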
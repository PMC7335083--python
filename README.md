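# laryq

Laryngoscopy image quantization: a tested Python implementation of an
end-to-end pipeline for objective analysis of laryngeal endoscopy frames —
sharp-frame selection, illumination compensation, automatic segmentation of
the glottis / vocal cords / arytenoid cartilage, hue and texture feature
extraction, and reflux (LPR) detection and severity grading.

Because clinical endoscopy data is not redistributable, the package ships a
first-class synthetic **phantom** module that renders laryngeal frames with
known ground-truth masks, frame stacks with blur / motion / non-throat
distractors, and labelled feature cohorts, so every stage is verifiable
end to end.

## Pipeline stages

1. **screening** — four autofocus scores (variance, sum-modulus-difference,
   Sobel gradient, Laplacian energy); non-throat frames are dropped by red
   chromatic fraction (< 0.4), blurred frames by below-mean variance, and
   the sharpest remaining frame is selected (SMD by default).
2. **compensation** — full-range BT.601 RGB↔YCbCr; the luma histogram is
   shifted so every frame has mean Y = 125, leaving chroma untouched.
3. **segmentation** — glottis by μ−σ dark thresholding plus structure rules
   (area / centroid zone / bbox aspect); arytenoid by bright thresholding,
   erosion and a contracting active contour; vocal cords by glottis
   transection, valley search, and a greedy snake with entropy-difference
   adaptive stopping (iteration window 13–41). Accuracy is scored by the
   Dice similarity coefficient.
4. **features** — 36 features: six chromatic means (R, G, B, H, Cb, Cr) and
   four GLCM texture statistics (energy, contrast, correlation,
   homogeneity) over the arytenoid and both cords, plus cord/arytenoid
   ratios; ranked by the two-class Fisher criterion.
5. **classify** — LPR detection with an RBF SVM under balanced 10-fold CV
   (positive class = non-LPR); severity grading of RSI-binned classes
   (13–20 / 21–30 / 31–45) with a 5-4-3 momentum back-propagation network
   under stratified 10-fold CV.

## CLI

```sh
laryq phantom --n 20 --seed 7 --out samples/      # synthetic fixtures
laryq run --input frames/ --out results/ --seed 0 # full pipeline -> JSON
laryq features --image f.png --glottis g.png --left-vc l.png \
    --right-vc r.png --arytenoid a.png            # one feature CSV row
laryq train-lpr --cohort cohort.csv --seed 0      # Fisher + SVM CV
laryq train-severity --cohort cohort.csv --seed 0 # BPNN severity CV
laryq evaluate --pred m1.png --truth m2.png       # Dice of two masks
```

Cohort CSVs carry the 36 feature columns plus `label` (`LPR` / `non-LPR`)
and `rsi`; `laryq phantom` writes frames as PNG and masks as 0/255 PNG.

## Library example

```python
from laryq.phantom import PhantomParams, make_phantom
from laryq.compensation import histogram_shift
from laryq import segmentation, features

sample = make_phantom(PhantomParams(seed=1))
image = histogram_shift(sample.image)
regions = segmentation.segment_regions(image)
vector = features.extract_features(image, regions)   # 36 named features
print(segmentation.dice(regions.glottis, sample.truth.glottis))
```
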
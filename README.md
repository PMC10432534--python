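# matmotion

Automated screening of infant **fidgety movements** (FMs) from
pressure-sensing-mat recordings. Fidgety movements are an age-specific
pattern of spontaneous infant motility (~9–20 weeks post-term) whose
absence is a strong early marker of neurodevelopmental risk; assessing
them normally requires trained human observers scoring video. A pressure
mat — 1024 sensors on a 32×32 grid under the supine infant — is a cheap,
privacy-preserving alternative sensing modality, and this package
implements and compares classifiers that decide, for each 5-second
recording snippet (500 frames at 100 Hz), whether fidgety movements are
present (`FMplus`) or absent (`FMminus`).

The pipeline:

- **Encode** — crop each frame to the active 29×26 area (754 sensors),
  split into shoulder/head (12×26) and hip (17×26) regions, and reduce
  each region to its centre of pressure and mean pressure per frame,

  x = Σᵢ i·p(i,j) / Σᵢⱼ p(i,j),  y = Σⱼ j·p(i,j) / Σᵢⱼ p(i,j),
  p = Σᵢⱼ p(i,j) / (m·n),

  then smooth (5-frame moving average) and jointly min-max normalise:
  each snippet becomes six signals × 500 steps.
- **Features** — mean and SD of each signal and (optionally) of its time
  derivative: 12 or 24 statistical features.
- **Models** — SVMs (RBF/polynomial, 25-point C×γ grid) and feed-forward
  networks on the features; 1-D convolutional networks and LSTMs that
  learn features from the raw 500×6 signals (NumPy engine: Adam, binary
  cross-entropy, batch 4, validation stop with patience 10, restart
  selection by validation loss).
- **Evaluate** — infant-grouped 5-fold cross-validation (no infant in
  both train and test of a fold), sensitivity / specificity / balanced
  accuracy BA = (TPR+TNR)/2 per fold, t-based 95% CIs and pairwise
  two-sample t-tests across variants.

Because the study's recordings are an external deposit, the package ships
a **synthetic cohort generator**: two Gaussian contact blobs (shoulders,
hips) oscillate on the grid with class-conditional motion — slow/large
for FM-absent (0.3–1.0 Hz, 2–4 cells), faster/smaller for FM-present
(1.5–4.0 Hz, 0.5–1.5 cells) — with per-infant body geometry and exact
ground-truth trajectories for validation. See `docs/methods.md` for the
model, parameter tables, and what the generator does and does not emulate.

## Worked example

```python
import matmotion as mm
from matmotion.pipeline import build_dataset
from matmotion.models import MODEL_SPECS, TrainingConfig

cfg = mm.CohortConfig(n_infants=10, snippets_per_infant=6, rng_seed=7)
dataset, _ = build_dataset(cfg)          # simulate + encode + featurise
folds = mm.make_folds(dataset.manifest, n_folds=5, seed=7)
res = mm.cross_validate(MODEL_SPECS["S2.P1"], dataset, folds, master_seed=7)
print([round(r.ba, 3) for r in res])
print(mm.summarize([r.ba for r in res]))
```

prints

```
[1.0, 1.0, 1.0, 1.0, 1.0]
(1.0, (1.0, 1.0))
```

— per-fold balanced accuracies of the derivative-feature SVM on a small
synthetic cohort, then their mean with the 95% CI. (On this cohort the
classes are spectrally disjoint by construction, and derivative SDs
expose the frequency contrast directly, so the SVM with derivative
features is perfect; the 12-feature SVM without derivatives is clearly
worse — the full comparison is in the analysis scripts.)

## The analysis

Numbered drivers under `analysis/` reproduce the study's comparison on
the synthetic cohort (run from the repository root, in order):

```sh
python analysis/01_simulate.py     # 45 infants x 20 snippets -> results/data/
python analysis/02_encode.py       # 500x32x32 -> 500x6 signals
python analysis/03_features.py     # 12- and 24-feature tables
python analysis/04_crossval.py     # grouped 5-fold CV: S1.RBF, S2.P1, F1.3, C3F2
python analysis/05_report.py       # summary, t-tests, bar chart
```

There is also a `matmotion` CLI with the same stages
(`simulate`, `encode`, `features`, `evaluate`, `report`, `run-all`).

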
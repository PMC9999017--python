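# stirqmri

Quantitative muscle MRI (qMRI) biomarkers — per-muscle **fat fraction**
(FF, percentage points) and **water T2** (wT2, ms) — normally require
dedicated multi-echo sequences. This package asks how far a conventional
short-tau inversion recovery (STIR) image can be pushed instead: it
extracts radiomic features from 2D calf STIR-like slices with labelled
muscle ROIs (Soleus, medial/lateral Gastrocnemius, Tibialis Anterior,
Extensor Digitorum Longus, Peroneus Longus) and predicts FF and wT2 with
seven regression models under 5-fold cross-validation, comparing three
feature workflows:

* **WF1** — a LIFEx-compatible catalog of 56 radiomic features
  (25 first-order, 26 second-order from gray-level co-occurrence,
  size-zone and run-length matrices, 5 shape), reduced by PCA to 6
  components;
* **WF2** — the same features, but selected by minimizing the
  *information imbalance* of the feature subset A with respect to the
  target B, estimated on N subjects as

  Δ(A→B) = (2/N) · ⟨ rank_B( nn_A(i) ) ⟩_i ,

  the mean rank in B of each point's nearest neighbor in A (Δ = 2/N when
  A's neighborhoods perfectly predict B's);
* **WF3** — two bespoke STIR features from healthy-control (HC)
  reference limits: per-muscle upper limit UL_i = μ_i + 2σ_i of pooled
  healthy muscle intensity and a global lower limit LL = mode of the
  pooled subcutaneous-fat histogram. The fat infiltration grade
  **FFG** (fraction of ROI pixels < LL) predicts FF and the muscle edema
  grade **MEG** (fraction > UL_i) predicts wT2.

Models: linear, ridge and lasso regression, decision tree, random
forest, k-nearest-neighbor, RBF support-vector regression. Performance
is the fold-mean of the mean absolute error MAE = (1/N)Σ|y − ŷ|,
reported per muscle as "mean (SD)", plus coefficient-of-variation and
Pearson/Spearman screens of the error against cohort variability.

Because the patient data behind such studies are restricted, the package
ships a seeded **phantom generator**: an HC cohort with a single muscle
intensity law and a subcutaneous-fat ring (with a small bright "vessel"
admixture), and an FSHD-like cohort whose muscle ROIs mix suppressed-fat,
muscle and edema pixels as connected blobs, with ground-truth FF/wT2 tied
to the latent mixture fractions by a linear-plus-Gaussian link. Every
stage is therefore testable offline with known truth.

## Worked example

```python
import numpy as np
import stirqmri as sq
from stirqmri import regress, wf3

hc   = sq.generate_hc_cohort(sq.PhantomParams(seed=7))      # 6 subjects
fshd = sq.generate_fshd_cohort(sq.PhantomParams(seed=1234)) # 25 subjects

limits = wf3.compute_reference_limits(hc)
print("LL =", limits.LL, " UL[S] =", round(limits.UL["S"], 2))

tables = wf3.build_wf3_tables(fshd, limits)
maes = []
for muscle in sq.MUSCLES:
    t = tables[muscle]["FF"]
    res = regress.cross_validate(t[["FFG"]].to_numpy(),
                                 t["FF_pp"].to_numpy(),
                                 regress.ModelSpec("KNN"), k=5, seed=1)
    maes.append(res.mean_mae)
print("WF3+KNN fat-fraction MAE: %.2f pp" % np.mean(maes))
```

prints

```
LL = 30.0  UL[S] = 119.98
WF3+KNN fat-fraction MAE: 4.23 pp
```

`LL = 30.0` recovers the generator's fat-intensity mode and
`UL ≈ 120` its muscle law μ + 2σ = 100 + 2·10; the 4.2 pp error sits
close to the irreducible label noise (3 pp Gaussian, E|ε| ≈ 2.4 pp),
i.e. the single FFG covariate recovers most of the usable signal.

The same study runs from the shell:

```bash
stirqmri simulate --n-fshd 25 --n-hc 6 --seed 1234 -o data/
stirqmri run --wf 1 2 3 -i data/ -o results/ --seed 1 --no-normalize
```

which writes per-workflow MAE tables (`wf3_FF_mae.csv`, rows = muscles,
columns = models, cells = "mean (sd)"), the muscle-wise CV table and the
correlation screen.

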
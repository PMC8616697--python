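# flicmseg

Brain-tissue segmentation of 2-D MRI slices with **fuzzy local-information
C-means (FLICM)** clustering, wrapped in an end-to-end pipeline: Canny-based
skull stripping, tissue clustering into white matter (WM), gray matter (GM)
and cerebrospinal fluid (CSF), level-set initialization diagnostics, and
Fourier-descriptor identification of the H-shaped ventricular CSF region.
A synthetic brain-phantom generator with ground-truth labels makes the
whole method testable and lets the noise-robustness comparison against
plain fuzzy C-means (FCM) be reproduced end to end without patient data.

The package is aimed at medical-image-analysis practitioners who want a
transparent, dependency-light reference implementation of FLICM and its
evaluation suite (Jaccard, Dice, PSNR, SSIM, pixel accuracy).

## The model

FCM assigns each pixel $x_i$ a graded membership $\mu_{ij} \in [0,1]$ to
each of $K$ cluster centers $v_j$, minimizing
$\sum_i\sum_j \mu_{ij}^m \lVert x_i - v_j\rVert^2$ with fuzzifier $m > 1$.
FLICM augments the distance with a parameter-free local spatial term

$$J = \sum_i \sum_j \mu_{ij}^m\left(\lVert x_i - v_j\rVert^2 + B_{ij}\right),
\qquad
B_{ij} = \sum_{r \in N_i,\, r \neq i} \frac{1}{1 + c_{ir}}
(1-\mu_{rj})^m \lVert x_r - v_j\rVert^2,$$

where $N_i$ is the 3×3 neighborhood of pixel $i$ and $c_{ir}$ the Euclidean
distance between the pixel coordinates. The factor $B_{ij}$ pulls each
pixel's membership toward its neighbors', which suppresses isolated
noise-induced misclassifications without any tuning parameter. Updates
alternate

$$\mu_{ij} = \left[\sum_k \left(\frac{\lVert x_i-v_j\rVert^2 + B_{ij}}
{\lVert x_i-v_k\rVert^2 + B_{ik}}\right)^{1/(m-1)}\right]^{-1},
\qquad
v_j = \frac{\sum_i \mu_{ij}^m x_i}{\sum_i \mu_{ij}^m},$$

until the largest center shift falls below tolerance; the label map is the
per-pixel argmax. Setting `use_local_term=False` forces $B = 0$ and
recovers classical FCM (used as the comparison baseline throughout).

See `docs/methods.md` for the level-set, Canny, Fourier-descriptor and
metric definitions, the synthetic phantom design, and all numerical
choices.

## Worked example

```python
import numpy as np
from flicmseg import FLICM, PipelineConfig, run_pipeline
from flicmseg import phantom as ph

spec = ph.PhantomSpec(geometry_seed=0)
clean, truth = ph.generate_phantom(spec)
noisy = ph.add_noise(clean, ph.NoiseSpec(kind="gaussian", level=15, seed=1))

# statsmodels-style model object: fit FLICM inside the true brain mask
brain = np.isin(truth.labels, (ph.WM, ph.GM, ph.CSF))
res = FLICM(noisy, n_clusters=3, mask=brain).fit()
print(res.summary())
```

```
FLICM results
==============================================
clusters:        3
fuzzifier m:     2
iterations:      21 (converged)
final objective: 5.71557e+06
 cluster       center     pixels
       0      61.3063       1266
       1     125.2806       3516
       2     189.1835       3858
  masked                    7744
```

The three centers land on the phantom's CSF/GM/WM class means (60, 125,
190) despite the σ=15 noise, and the cluster sizes match the tissue areas.
The full pipeline (denoise → skull strip → FLICM → H-region matching) plus
evaluation against the ground truth:

```python
out = run_pipeline(noisy, PipelineConfig(), truth=truth)
for name, scores in out.report.per_class.items():
    print(f"{name:>14}: Jaccard {scores['jaccard']:.4f}  Dice {scores['dice']:.4f}")
print(f"pixel accuracy {out.report.pixel_accuracy:.4f}, "
      f"PSNR {out.report.psnr:.2f} dB, SSIM {out.report.ssim:.4f}")
print(f"H-region match distance {out.h_distance:.4f}, "
      f"level-set beta {out.level_stats.beta:.4f}")
```

```
  white_matter: Jaccard 0.9866  Dice 0.9932
   gray_matter: Jaccard 0.9795  Dice 0.9896
           csf: Jaccard 0.9851  Dice 0.9925
pixel accuracy 0.9916, PSNR 23.98 dB, SSIM 0.7686
H-region match distance 0.0370, level-set beta 0.1907
```

All three tissues are recovered with Jaccard ≈ 0.98–0.99 from a heavily
noised slice; the H-shaped ventricular region is identified with a
descriptor distance far below the 0.25 acceptance threshold (PSNR/SSIM here
compare the *noisy input* against its reconstruction, hence the moderate
values). On the noiseless phantom all per-class Jaccards are 1.0.

## Command line

`flicmseg` exposes subcommands `phantom`, `segment`, `edges`,
`levelset-stats`, `h-region`, `evaluate`, `experiment` and `run`; every
subcommand is byte-deterministic for a fixed config and seed. For example:

```bash
flicmseg phantom --size 128 --seed 0 --noise-level 15 --out slice.png
flicmseg segment --k 3 --in slice.png --out-labels labels.png --trace trace.csv
flicmseg experiment --seed 1 --out robustness.csv
```

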
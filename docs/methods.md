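# Methods

This note documents the models and procedures implemented in `flicmseg`,
the synthetic data they are validated on, and the numerical and design
choices made where the method description left the design open.

## Clustering: FCM and FLICM

Pixels are clustered on intensity alone (2-D slices, scalar features).
The FLICM objective adds a local spatial term to the FCM objective:

    J = Σ_i Σ_j μ_ij^m ( ‖x_i − v_j‖² + B_ij ),
    B_ij = Σ_{r ∈ N_i, r ≠ i} [1/(1 + c_ir)] (1 − μ_rj)^m ‖x_r − v_j‖²

with `N_i` the 3×3 window around pixel i (half-width configurable),
`c_ir` the Euclidean distance between the two pixel *coordinates*, and the
center pixel excluded from the sum (its data term is already counted).
The membership weight carries the exponent m; at m = 1 this reduces to the
unexponentiated form sometimes written for the factor, and m defaults to
the standard 2.0 everywhere (objective, factor, both updates). A single
fuzzifier symbol is used throughout; the cluster count K is a separate
parameter.

Iteration order: compute B from the previous memberships and centers,
update memberships, update centers; stop when max_j |Δv_j| < tol
(default 1e-5) or after max_iter (default 100; hitting the cap records a
warning in the trace and returns the final state). Initial memberships are
one plain (B = 0) membership step from the initial centers, so an FCM and
a FLICM run started from the same centers share their initialization
exactly — this is what "identical initialization" means in the comparison
experiments. Defuzzification is per-pixel argmax with ties broken toward
the lowest cluster index (determinism).

Center initialization places centers at the (j + ½)/K intensity quantiles
of the (masked) image. If those quantiles collide (possible for heavily
skewed histograms, e.g. a piecewise-constant image whose smallest class
holds less than 1/K of the pixels), the quantiles of the *unique*
intensity values are used instead: duplicate initial centers would receive
identical updates forever and silently reduce K.

Degenerate cases: a pixel exactly at a center with B = 0 gets crisp
membership split equally among the zero-distance clusters; a cluster whose
total weight underflows keeps its previous center and emits
`EmptyClusterWarning`.

The FCM reduction (B ≡ 0) is a true alternating minimization, so its
objective trace is non-increasing — asserted in tests against an
independent double-loop reference implementation. FLICM's updates are the
standard heuristic and do **not** provably minimize J; the objective trace
is reported diagnostically only.

Known behavior worth stating plainly: the local factor makes a pixel
sitting on a sharp interface between two classes whose means straddle a
third, intermediate class mean prefer that intermediate class (the
two-sided neighborhood penalty is smaller than the one-sided penalty of
either extreme class). With T1-like means (CSF 60, GM 125, WM 190) a
direct CSF|WM border would therefore acquire a one-pixel GM rim even on
noiseless data. Anatomically, the lateral ventricles are bordered by deep
gray matter (caudate nucleus, thalamus), so the phantom draws a GM lining
around the ventricular CSF (below) and the configuration does not arise in
the intended geometry; on real slices with direct CSF|WM contact the rim
is a known limitation of the algorithm family.

## Synthetic phantom

The generator emulates one axial T1-like slice as piecewise-constant
tissue classes: elliptical head (axes 0.42·W and 0.46·H, jittered ±10%
from the geometry seed, capped so the head always fits the frame with a
4-px margin), a skull ring (3 px), a cortical GM band (≈ 0.08·min(H,W)),
WM interior, and a centered H-shaped CSF region (two vertical bars joined
by a crossbar, dimensions scaling with the frame) standing in for the
lateral-ventricle pattern, lined by a 2-px paraventricular GM band (deep
gray nuclei). An optional disk-shaped CSF decoy (also GM-lined) supports
the shape-identification experiments. Default class means on the 8-bit
scale: background 0, skull 230, WM 190, GM 125, CSF 60 — T1 ordering, all
pairwise gaps ≥ 30, so noiseless phantoms are exactly separable by
thresholding.

Noise is injected separately and reproducibly: additive Gaussian with
standard deviation `level` on the 0–255 scale, clipped to [0, peak], or
salt-and-pepper with corruption density `level`. The default experiment
ladders are σ ∈ {0, 5, 10, 15, 20} and density ∈ {0, 0.01, 0.02, 0.05,
0.10}, spanning visually negligible to severe degradation.

What the phantom does *not* model: bias fields, partial-volume averaging,
Rician noise statistics, 3-D geometry, or anatomical texture. Passing
tests on the phantom therefore demonstrates the algorithmic properties
(noise robustness, exact recovery under separability, shape-based
identification) — not clinical-grade performance on real MRI.

## Pipeline

`run_pipeline` chains denoise → skull strip → FLICM (K = 3 inside the
brain mask) → level-set statistics on the CSF membership →
Fourier-descriptor H-region identification. Fitted clusters map to tissues
by center intensity (darkest = CSF, brightest = WM), matching the T1
ordering.

Denoising is deliberately adaptive. The 3×3 median removes impulse noise
exactly but erodes convex corners of thin structures (the H bars), so it
runs only when impulse corruption is detected (> 0.2 % of pixels saturated
at the peak, or at zero inside the filled body); Gaussian smoothing
(σ = 0.8 px) likewise displaces curved boundaries by ~½ px, so it is
skipped when the wavelet-MAD noise estimate is below one intensity unit.
On a clean image the denoise stage is therefore the identity, which is
what makes exact noiseless recovery possible.

Skull stripping finds the outer head boundary with Canny (σ = 1.4),
closes it morphologically (disk radius 3), fills it to a head mask, erodes
past the ring (radius = skull thickness + 3) for a trusted interior, and
then decides the remaining boundary band pixel-by-pixel with adaptive
intensity gates: an Otsu split between the band's tissue and skull modes
(applied only when the band's 95th percentile exceeds the interior's 99th
— i.e. only when a bright ring is actually present) and a low gate halfway
between the background median and the interior's 1st percentile. The gates
read the *pre-smoothing* image: Gaussian smoothing smears a bright halo
off the 230-intensity ring into both neighbors, which would otherwise
overlap the tissue range and defeat any threshold. The final mask is the
gated band's component connected to the interior, hole-filled.

`run_noise_experiment` isolates the algorithmic comparison: for each
(noise level, replicate) a fresh phantom is corrupted and both FCM and
FLICM cluster the *raw noisy* intensities inside the ground-truth brain
mask from shared quantile-initialized centers. No denoising or stripping
is applied there, so the recorded differences are attributable to the
clustering algorithms alone; preprocessing robustness is exercised
separately through `run_pipeline`. Per-class Jaccard/Dice are recorded per
run along with an aggregate row carrying pixel accuracy over the brain
mask, PSNR (mean squared error over the brain mask between the clean slice
and the piecewise-constant reconstruction from the fitted centers) and
SSIM (reconstruction embedded in the clean frame). At zero noise the
reconstruction can be exact, in which case PSNR is reported as +inf. The
CSV uses a fixed column order and 6 significant digits, making reruns
byte-identical. At very low noise (σ ≤ 10) FCM is already near-perfect and
FLICM's slight boundary smoothing can cost ~0.1–0.2 % Jaccard; the
robustness ordering is substantive from σ = 15 upward, where FCM's
interior error rate grows to several percent.

## Level set

The level-set field is initialized from a target map (CSF membership in
the pipeline) as the binary step φ = −4ε(0.5 − B), B = (region ≥ t0),
t0 = 0.5, ε = 1.5 px. Area is the exact Heaviside count Σ H(φ). The length
functional Σ δ_ε(φ̃)|∇φ̃| is evaluated on the signed-distance
reinitialization φ̃ of the interior (half-pixel offset so the discretized
cosine Dirac δ_ε(t) = (1+cos(πt/ε))/(2ε) integrates to ~1 per unit
boundary length): on the raw ±2ε step any compact Dirac vanishes
identically, so reinitialization is required for the functional to be
meaningful. β = Len/Are is reported as a diagnostic of the initial
contour's scale (β ≈ 2/r for a disk of radius r, verified to 15 %); no
evolution PDE is run — only the initialization and its statistics are in
scope.

## Edges

The Canny chain uses a discretized unit-sum Gaussian (radius 4σ,
reflective borders, separable passes), the forward-averaged 2×2 difference
stencils for E_x and E_y (values assigned to the top-left pixel of each
2×2 block, giving an (H−1)×(W−1) gradient grid), magnitude √(E_x²+E_y²)
and full-quadrant direction atan2(E_y, E_x). Non-maximum suppression
quantizes the gradient direction into four sectors and keeps ridge pixels;
hysteresis keeps weak edges (≥ low) only in 8-connected components that
contain a strong edge (≥ high). Defaults: σ = 1.4; low/high default to
0.1/0.2 of the maximum gradient magnitude when not given absolutely.

The classical 1-D filter-design functionals — edge response ∫G(−x)H(x)dx,
noise response σ√(∫H²), localization |∫G′H′|/(σ√(∫H′²)) and zero-crossing
spacing π√(∫H′²/∫H″²) — are provided as diagnostics of a supplied sampled
kernel (trapezoidal quadrature, finite-difference derivatives, symmetric
grid required). They are not used as an optimization target.

## Shape descriptors and H-region identification

Region boundaries are traced with Moore-neighbor tracing (clockwise scan,
termination when the walk state repeats), yielding an ordered closed
8-connected pixel sequence; orientation is normalized to positive shoelace
area whenever the contour encloses area (a one-pixel-thin region traces
out-and-back with zero area and is returned as such). The descriptor is
the DFT of s(k) = x(k) + j·y(k), λ(u) = (1/N)Σ s(k)e^{−j2πuk/N}; λ(0) is
the centroid. Normalization drops λ(0), divides by |λ(1)| and keeps
magnitudes only, giving translation/scale/rotation/start-point invariance.
Matching compares harmonic orders ±1…±8 (16 magnitudes) by Euclidean
distance; low-order harmonics carry the gross shape, so the letter-H
ventricle pattern and a disk are separated by an order of magnitude in
distance. The default acceptance threshold is 0.25; if no candidate CSF
component passes, the threshold is relaxed by 5 % steps up to 10 times and
an empty mask with the best distance is returned on final failure. The
default template is the descriptor of the generator's reference H mask,
computed at call time.

## Metrics

Jaccard |A∩B|/|A∪B| and Dice 2|A∩B|/(|A|+|B|) on per-class masks (two
empty masks agree perfectly; Dice = 2J/(1+J) holds identically). PSNR =
10·log₁₀(M²/MSE) with M the declared peak (255 for 8-bit); identical
images report +inf. SSIM is the mean over 7×7 uniform sliding windows
(valid-mode) of the luminance·contrast·structure product with the standard
constants c1 = (0.01M)², c2 = (0.03M)², c3 = c2/2; population (ddof = 0)
window moments; images smaller than the window fall back to one global
window. The implementation is cross-checked in the tests against
scikit-image's SSIM/PSNR with matching settings. Pixel accuracy is the
fraction of identically labeled pixels after label matching; predicted
labels are matched to truth by optimal assignment on the confusion matrix
(Hungarian algorithm). Whether PSNR/SSIM should compare segmentations or
denoised-vs-clean images is ambiguous in the method description; both
pairings are supported and the experiment tables state which is used
(reconstruction vs clean).

## Problem sizes

Default experiments run 128×128 phantoms, 10 replicates per noise level,
two algorithms over the five-level gaussian ladder — about 100 model fits,
well under a minute on one CPU. These sizes were chosen to keep the full
statistical comparison comfortably interactive while leaving the replicate
standard errors an order of magnitude below the effects being measured.

## Known limitations

- Scalar-intensity features only; no multichannel or texture features.
- The FLICM boundary rim at extreme-class interfaces described above.
- Skull stripping assumes a single head with a closed, detectable outer
  boundary and a ring brighter than brain tissue; it raises a diagnostic
  error (with the edge map attached) rather than guessing when the
  boundary cannot be closed.
- Descriptor matching assumes the target region survives segmentation as
  one 8-connected component of at least ~8 pixels.
- The β statistic is reported but drives nothing: no level-set evolution
  equation is in scope.
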
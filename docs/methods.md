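# Methods

`netage` studies how well chronological age can be predicted from the
gray-matter content of individual cortical networks. It implements the full
chain — synthetic cohort generation, network masking, gray-matter-volume
(GMV) correlation analysis, a 3D CNN age regressor, linear-kernel GPR and
RVR comparators, and the evaluation pipeline — as testable, seeded code.
This note records the models, their assumptions, and the design choices
that were genuinely open.

## Synthetic cohorts

The generator emulates the *output* of a VBM preprocessing chain
(segmentation, DARTEL-style normalization, modulation, smoothing), not the
chain itself: non-negative, smooth, modulated-density-like volumes on a
shared voxel grid. Per subject,

```
raw(v) = b + sum_k [ -beta * (age - age_mid) + e_k ] * 1[v in mask_k] + eps(v)
vol    = clip( G_sigma * raw, 0 )
```

with baseline `b` (default 0.6 density units), per-voxel aging slope
`beta` (default 0.003 / yr inside a network), a per-subject,
network-coherent intensity shift `e_k ~ N(0, s_k^2)`, iid voxel noise
`eps ~ N(0, 0.1^2)`, and isotropic Gaussian smoothing (`sigma` = 1 voxel,
standing in for the study-scale 8-mm FWHM kernel). Ages are uniform on
[18, 90] years; sexes Bernoulli(0.5).

**Exact calibration.** The scientific contract is that network-k GMV (the
masked voxel sum) correlates with age at a prescribed Pearson r. For a
linear signal, `r = -slope*sd(age) / sqrt(slope^2 sd(age)^2 + sd_noise^2)`,
so the required total GMV noise is `sd_noise = slope*sd(age)*sqrt(1/r^2-1)`.
Because smoothing is linear, its effect on the masked sum is computed
exactly from the smoothed mask indicator `w = G_sigma(1_mask)`: any pattern
added uniformly inside the mask scales by `c = sum(w[mask])`, and iid voxel
noise contributes `voxel_sd * ||w||`. The coherent noise sd is then solved
in closed form, `s_k = sqrt(sd_noise^2 - voxel_sd^2 ||w||^2) / c` (a
calibration error is raised if voxel noise alone already exceeds the
budget). Masks are separated by a 3-voxel margin so cross-network smoothing
leakage is negligible; clipping at zero is rare at the default intensity
scale. Empirically the calibration lands within ±0.01–0.02 of the target
at n ≈ 1500 and within the 3-standard-error Fisher-z band the tests
enforce.

A target of exactly 0 means "no age coupling": zero slope and zero
coherent noise, leaving only voxel noise.

The generator does **not** emulate cortical geometry, MNI registration,
scanner/site effects, non-uniform pooled age distributions, or non-linear
trajectories. Tests passing on these cohorts therefore demonstrate that the
estimators recover a linear age signal under calibrated noise — not that
they would reach any particular accuracy on real multi-site MRI.

**Masks.** Network parcels are solid boxes placed in disjoint lattice cells
(near-cubic cell layout, seeded jitter in size and position, ≥ 8 voxels
each), standing in for a seven-network cortical parcellation. Overlapping
placement is available but off by default.

## Parcellation and correlation analysis

A network image is the voxelwise product of the subject's gray-matter map
with the binary network mask (full grid retained, zeros outside). Network
GMV is the plain voxel sum; `v* = (v - min)/(max - min)` is produced for
reporting only, since Pearson r is invariant to that affine map — the
correlation itself is computed on raw v. Images and masks must share one
grid; no resampling is implemented (a dimension check raises instead).

## 3D CNN age regressor

Five stacks of `conv3x3x3(s1,p1) -> ReLU -> conv3x3x3 -> batch norm ->
ReLU -> maxpool2x2x2(s2)`, channels starting at `base_channels` (8 at full
scale) and doubling per stack, then three fully connected layers ending in
one scalar. He fan-in initialization with zero biases; BN starts at
identity. Training is mini-batch SGD (batch 16) with momentum 0.9, weight
decay 5e-4 (on conv/FC weights only), MAE loss, and a step learning-rate
schedule `lr(e) = lr0 * 0.1^floor(e/10)`; a single one-time decay is
available as `lr_decay_mode="once"`. The final partial batch is used;
shuffling is reseeded per epoch from the run seed, so training is
bit-reproducible.

After the last epoch the batch-norm running statistics are recalibrated
with one pass over the training set (per-batch means/variances averaged
and written into the running buffers). The exponential moving average
tracked during SGD lags the final weights at short epoch counts, which
otherwise can leave inference-mode predictions with a large constant
offset even when the subject ranking (test r) is good. The pipeline
additionally gates each CNN cell on its inference-mode *training* MAE:
if it fails to beat 0.85 × the trivial train-mean predictor, the cell is
retrained from a deterministically shifted seed (`CnnSettings.restarts`,
default 1 attempt, i.e. no restart, raised in the multi-network runs).
Both mechanisms use training data only.

The engine itself (`netage.nn`) is a small numpy implementation with
explicit forward/backward passes. Volumes are carried channels-last and
convolutions are evaluated as 27-offset stencils, each offset a BLAS
matmul against a shifted view of the padded input — on one CPU core this
is memory-traffic-bound, and avoiding a materialized im2col matrix is what
makes desk-scale training practical (~50 ms per 32³ sample per
forward+backward pass). Max-pool backward routes gradients through an
equality mask; an exact tie would split the gradient across tied voxels, a
valid subgradient that does not occur on continuous activations. All
backward passes are verified against central finite differences in
float64.

FC hidden widths are configurable (128/64 at full scale, 64/32 or smaller
at desk scale); a VGG-style 4096 would be unjustified for a scalar output.
The full-scale profile (121×145×121, 8 base channels, 200 epochs) is
configuration-reachable; all tests run a desk profile (grids ≤ 32³, 4 base
channels, ≤ 30 epochs, learning rate 0.01 at criterion scale and 0.005 for
the multi-network ranking runs, where the tiny masks make 0.01
occasionally unstable).

## Kernel comparators

Each subject's network image is flattened (C order) into a row of a
subjects × voxels feature matrix; the similarity matrix is the Gram matrix
`K = F F^T`. Columns outside the mask are zero and may be dropped without
changing K. The API returns raw dot products; the pipeline applies trace
normalization (mean diagonal 1) once per network — GPR predictions are
invariant to that scaling and it keeps the RVR precision matrix inside
float64 conditioning.

**GPR.** Constant mean fixed to the training mean; prior `f ~ N(0,
theta2*K)` plus iid noise `sigma2`. K is eigendecomposed once, so each
marginal-likelihood evaluation and its analytic gradient is O(n²);
(theta2, sigma2) are optimized in log space by L-BFGS-B from three starts
— `(s/kappa, 0.1 s)`, `(s/kappa, s)`, `(0.1 s/kappa, 0.5 s)` with `s =
var(y)` and `kappa = mean diag K` — within ±30 log units. Jitter
`1e-8 * trace(K)/n` stabilizes near-singular kernels; eigenvalues below
`-1e-10 * trace(K)` raise a PSD error. At fixed hyperparameters the
predictive mean is exactly kernel ridge with penalty `sigma2/theta2`.

*Kernel centering.* Gray-matter images share a large baseline component,
so K has one dominant "constant image" eigendirection. With a single
shared signal variance the evidence cannot simultaneously damp that
direction and amplify the age axis, and on small cohorts (n ≈ 40) the
optimum collapses to the mean predictor. `GprOptions.center_kernel`
double-centers K in feature space (train-mean removal); it is off in the
API default (keeping the plain ridge equivalence exact) and on in the
pipeline configuration, mirroring what neuroimaging kernel toolboxes do.

**RVR.** Tipping-style sparse Bayesian regression on the design
`[1 | K_train]`, iterating Sigma/mu/gamma/alpha/sigma² re-estimation with
pruning at `alpha > 1e12`, convergence at max |Δ log alpha| < 1e-6, alpha
initialized at 1 and sigma² at 0.1 var(y). The log evidence is tracked per
iteration through the Woodbury identity and is non-decreasing across
accepted steps. All-zero targets prune everything; the empty model
predicts 0, the correct limit (rather than an error). Cholesky
factorizations carry an escalating diagonal-relative jitter because the
precision matrix inherits the kernel's squared condition number.

Train/test hygiene: although the study describes one pooled similarity
matrix, models are fitted on the train × train block only and predict from
the test × train block, so test subjects never influence training.

## Evaluation pipeline

The cohort is split uniformly at random, re-drawing (up to 100 times)
until a Welch t-test on age and a chi-square test on sex both give
p > 0.05 — matching is *confirmed by failing to reject*; the best-balanced
split is returned with a flag if no draw passes. The default test fraction
mirrors 151/1454.

Per (network, method) cell the pipeline trains on the training split,
predicts the held-out subjects, and reports MAE, RMSE, Pearson r, and two
R² variants: the squared correlation (primary column) and the coefficient
of determination `1 - SS_res/SS_tot`, which additionally penalizes bias
and can be negative. Constant predictions leave r/R² as NaN while
MAE/RMSE remain valid. Cell failures are isolated: a diverged fit records
a traceback and the remaining cells still run. One master seed derives
(via `SeedSequence`) the cohort, mask, split and CNN seeds, making
`run_experiment` bit-reproducible end to end.

## Problem sizes used in tests

Calibration checks run n = 1454 subjects on a 24×28×24 grid (20 seeds).
The CNN recovery check uses the 32³ / 4-base-channel / 400-train profile
with 12 epochs. The network-ranking runs use GPR/RVR on the full
seven-network cohort (n = 380, 20³ grids, 10 seeds, strict pairwise
strong-vs-weak comparison) and the CNN on a five-network cohort — one
network per distinct correlation target in the comparison — at 16³ over
3 seeds, comparing group-mean MAEs: at this scale per-network CNN
training variance (~1–2 yr) exceeds the ~2.5 yr gap between adjacent
networks, so the group contrast is the statistically stable analogue.
These sizes were chosen as the smallest at which the estimators' behavior
is clear; the full-scale configuration remains available through the same
APIs.

## Known limitations

- The box-parcel geometry makes masks more compact than real cortical
  networks; voxel counts per network are far below the study scale.
- The uniform age distribution overweights the extremes relative to real
  pooled cohorts.
- The CNN desk profile's absolute MAEs are not comparable to full-scale
  results; only relative statements (vs. baselines, across networks) are
  meaningful at this scale.
- GPR evidence optimization can legitimately prefer the mean predictor on
  very small cohorts with uncentered kernels (see above); the pipeline
  default avoids this.
- RVR's surviving basis count grows with near-orthogonal kernels; sparsity
  in the strict few-vector sense appears only when bases are correlated.
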
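# Methods

`batmri` re-implements, as a tested pipeline, a quantitative-MRI analysis of
human supraclavicular brown adipose tissue (BAT) under cold exposure:
chemical-shift (Dixon) water–fat reconstruction to fat-fraction (FF) and T2*
maps, FF-threshold-dependent estimation of BAT volume, conversion of FF maps
to lean/fat mass and metabolizable energy, and voxel-wise joint-histogram and
cluster analysis. Because no suitable in-vivo dataset is bundled, every stage
is exercised end-to-end on a synthetic digital phantom whose construction is
described below.

## Signal model and reconstruction

The acquisition is a six-point chemical-shift encoded gradient echo
(defaults: 3 T, TE1 = 1.98 ms, ΔTE = 1.75 ms). Per voxel the complex signal
at echo time *t* is

    s(t) = (W + F · Σₘ aₘ e^{i2πfₘt}) · e^{i2πψt} · e^{−t/T2*}

with water/fat amplitudes (W, F), off-resonance ψ (Hz), mono-exponential T2*
decay, and a known multi-peak fat spectrum (fₘ, aₘ). The default spectrum is
the standard six-peak triglyceride model (methyl 0.90 ppm through olefinic
5.29 ppm, relative amplitudes 0.088 / 0.700 / 0.120 / 0.006 / 0.039 / 0.047,
water at 4.70 ppm); it is stored as plain overridable data because spectra
differ between sites and field strengths.

Fitting uses **variable projection**: for candidate (ψ, R2\* = 1/T2\*) the
amplitudes enter linearly and are solved in closed form from the 2-column
complex normal equations; the nonlinear search runs only over (ψ, R2\*).
Because the residual is near-periodic in ψ, a wrong ψ branch swaps water and
fat. The field map is therefore estimated first at low resolution
(block-averaged echoes, default factor 2 in-plane) by an exhaustive 1-D grid
search over ψ ∈ ±1/(2ΔTE) at 2 Hz steps (residual minimized over a coarse
R2\* set), and the spatially smooth branch is propagated by **region
growing**: voxels are visited in decreasing signal-magnitude order from the
strongest seed, and each adopts the candidate residual minimum closest to
the median ψ of its already-solved 6-neighbours. The upsampled field
initializes a damped Gauss–Newton refinement of (ψ, R2\*) at full
resolution, vectorized over voxels, with the fat fraction computed from
magnitude amplitudes, FF = |F| / (|F| + |W|). Voxels with vanishing signal
or a singular linear subproblem are flagged `fit_ok = False` and carry
`ff = nan`, never a silent zero.

On a noiseless 32×32×8 phantom the round trip (truth → echoes → maps)
recovers FF and T2* to machine precision with no water–fat swaps; the
acceptance suite asserts the much looser contract of 0.005 max-abs FF error
and 0.5 ms T2* RMSE. At SNR 50 the FF bias stays below 0.01. Not modelled
(as in the analysis this reproduces): eddy currents, bipolar readouts, coil
combination, and T1 bias from the short-TR excitation.

## Threshold-dependent global analysis

FF is a fraction in memory and percent at every interface. A threshold
range [L, U] selects voxels with L ≤ FF ≤ U (inclusive; configurable).
Two selection modes exist and the distinction matters:

* **independent** (default): each time point's voxel set is thresholded on
  its own map. Voxels whose FF drops below L after cooling leave the
  post-cooling set but remain in the thermoneutral one. This is the mode
  used for Vol_BAT, FF_Glob and T2*_Glob, and it is what makes the apparent
  |ΔFF_Glob| *shrink* as the lower threshold rises: the biggest losers are
  censored from the post-cooling mean.
* **joint**: only voxels passing the threshold at both time points
  contribute; used for the voxel-paired local analysis and available as an
  option in the sweep.

Transformed (floating-point) ROIs contribute fractional voxel weights by
default; a binarized mode reproduces integer counting. For a voxel present
at both time points the joint weight is the minimum of the two fractional
weights (the conservative overlap).

Estimated volume is `n_voxels × voxel_volume / 1000` mL with a default
voxel volume of 0.548 μL. Volume histograms use half-open 0.5% bins with
the top bin closed, so the bars over any sub-range sum exactly to the
segmented volume of that range.

The **threshold sweep** evaluates the cohort-mean post-minus-pre change of
volume, FF, T2* or energy at every (lower, upper) pair on a step lattice
(default 1%, fine enough to resolve single-percent extrema). Rather than
re-scanning the volumes per pair, each subject is aggregated once into
FF-bin tables (1-D marginals per time point; 2-D (pre-bin, post-bin) tables
for the joint mode) and every pair is answered from cumulative sums. This
is exact for thresholds on the bin lattice — the only thresholds the sweep
visits — and the test suite pins the fast path against brute-force
per-voxel loops. Pairs with lower ≥ upper or lower < 30% are flagged
invalid, mirroring the analysis convention that 10–30% FF voxels (depot
boundaries, partial-volume with muscle) are excluded.

Paired statistics are Shapiro–Wilk on the differences plus a two-sided
paired t-test, significance at p < 0.05 with no multiple-comparison
correction (deliberately, matching the original analysis). Zero-variance
differences are reported as degenerate (p = 1 when all differences are
exactly zero, NA otherwise) instead of a spurious p ≈ 0.

## Mass and energy framework

A voxel of volume v at fat fraction FF holds FF·v μL lipid and (1−FF)·v μL
lean tissue. Defaults: lipid 0.92 mg/μL and 9.4×10⁻³ kcal/μL; lean tissue
1.06 mg/μL and 1.0×10⁻³ kcal/μL. At FF 50% and 1 μL these give 0.460 mg
fat and 0.530 mg lean. (Published per-voxel worked values of 0.455/0.540 mg
are mutually inconsistent with these same densities; this implementation
follows the stated constants, and keeps all constants in a config object so
they can be audited or overridden — never hard-coded at call sites.) Since
energy is linear in FF, a depot with mean FF ≥ 0.3 necessarily stores ≥ 80%
of its energy as lipid under these constants; the suite asserts this
dominance property. Signal FF is used directly as a volume fraction with no
proton-density or T1 correction — a documented limitation.

## Voxel-wise local analysis

Thermoneutral maps and ROI are pulled to post-cooling coordinates through a
dense displacement field (mm, pulling convention on the target grid;
registration itself is out of scope and any toolbox-produced field in the
declared NIfTI layout is accepted). Both time points are then smoothed with
a 3×3 **in-plane** moving mean with edge replication — read as 2-D because
the source analysis states two dimensions; a 3×3×3 mode sits behind a flag —
and differenced per voxel into a paired table (FF_pre, FF_post, ΔFF,
T2*_pre, T2*_post, ΔT2*).

Joint histograms are plain half-open 2-D counts (default 1% FF × 1 ms T2*
bins) whose marginals conserve the voxel count exactly. Clustering is
k-means over user-selected table columns, z-scored first because FF and T2*
live on incommensurate scales. The cluster number is chosen by the
explained-variance elbow rule: explained variance = between-cluster sum of
squares / total sum of squares, and k_selected is the smallest k reaching
the 95% cutoff. Each k gets 10 seeded restarts plus a warm start that
splits the previous k's worst-fit point, which keeps the explained-variance
curve non-decreasing; a zero-variance point cloud yields k = 1. Seeds and
restart counts are recorded in the run report.

## The synthetic phantom

The phantom emulates the features of the supraclavicular depot that drive
the analyses, not anatomy:

* **Texture.** A thresholded sum of seeded Gaussian blobs juxtaposes
  low-lipid (FF ≈ 0.34–0.48) and high-lipid (FF ≈ 0.60–0.92) lobules
  (lightly smoothed for partial-volume blending), giving a bimodal depot
  with mean FF ≈ 0.6 and roughly a third of its volume above FF 70% —
  matching the reported depot statistics. A one-voxel boundary rim carries
  FF ≈ 0.10–0.38, emulating the partial-volume voxels adjacent to muscle
  that motivated the 30% lower threshold.
* **T2\*.** Monotone in FF from ~10 ms at FF 0.3 to ~22 ms at FF 1.0 plus
  smooth spatial noise, reproducing the reported low-FF/high-FF contrast.
* **Field map.** A smooth low-order polynomial surface, ~±60 Hz.
* **Control region.** A disjoint subcutaneous-like region at FF 0.75–0.93
  receives no cold effect and serves as the negative control.
* **Cold response.** Post-cooling FF = FF − loss·σ((FF−τ)/w) +
  gain·σ(−(FF−τ)/w) + ε, clipped to [0, 1] and applied inside the depot ROI
  only, with ε ~ N(0, noise_sd²) modelling the strong voxel-level
  heterogeneity of the real response; T2* shifts by +1 ms.

Default cold-effect parameters are loss = 0.05, gain = 0.07, τ = 0.34,
w = 0.03, noise_sd = 0.035. They were calibrated once, against the
qualitative pattern the pipeline must reproduce, and then frozen: losses
set in just above 34% FF (where the reported threshold sweep finds its
extremum) and saturate quickly; gains are confined to the leanest tissue,
so rim voxels rise across the 30% boundary after cooling and feed the
observed volume gain in the 30–40% bin; the voxel-level noise term
produces the censoring at high lower thresholds that compresses
|ΔFF_Glob|. With these defaults the seeded nine-subject cohort shows
ΔFF_Glob of about −4.2 / −3.2 / −1.6 percent points at lower thresholds
30 / 50 / 70% (shrinking, as reported), |ΔVol_BAT| growing over the same
thresholds, an energy change that is negative at 70–100% but positive at
30–70% (the sign inversion that makes threshold choice consequential), a
null FF change in the subcutaneous control, and fewer than 1% of voxels
clipped. These directions hold across cohort seeds.

What the phantom does **not** emulate — and hence what passing tests do not
show about real data: anatomy and coil geometry, motion and respiration,
T1 bias, partial-volume structure beyond the one-voxel rim, non-Gaussian or
spatially correlated noise, and any physiological coupling between T2* and
perfusion. Conclusions about algorithm correctness transfer; conclusions
about in-vivo effect sizes do not.

## Numerical choices and problem sizes

* Field-map grid: 2 Hz over ±1/(2ΔTE) ≈ ±286 Hz; well under the water–fat
  spacing (~434 Hz at 3 T).
* Gauss–Newton: finite-difference Jacobian (1e-2 steps), per-voxel
  Levenberg damping, ≤ 40 iterations, R2* clipped to [0.5, 2000] s⁻¹.
* Degenerate voxels (zero signal, singular subproblem) are flagged, not
  imputed; empty segmentations warn and return zero tables.
* Test and acceptance problem sizes — 32×32×8 phantoms for reconstruction
  round trips, 64×64×16 nine-subject cohorts for the direction suite —
  keep the full suite in the tens of seconds while leaving every code path
  exercised at realistic heterogeneity.

## Known limitations

* The worked per-voxel masses in the source analysis disagree with its own
  density constants by ~1%; we follow the constants (see above).
* The acquired-resolution voxel (1.1 mm isotropic → 1.331 μL) differs from
  the analysis voxel volume (0.548 μL, presumably after reconstruction
  interpolation); `voxel_volume` is therefore a free parameter everywhere
  and the default simply mirrors the analysis value.
* The sweep's interior upper bounds are half-open at bin edges (exact only
  on the threshold lattice); single-range calls use fully inclusive bounds.
* k-means with restarts is a heuristic; the explained-variance curve is
  guaranteed non-decreasing only because the warm start keeps the best fit
  per k.
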
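# Methods

## Water-exchange relaxation models

Tissue water is modelled as discrete pools exchanging magnetization at
finite rates. With mole fractions `p` (summing to 1), diagonal relaxation
matrix `R` and exchange generator `K`, the longitudinal magnetization
(in equilibrium units) obeys `dm/dt = -R (m - p) - K m`. Back-exchange
rates are fixed by detailed balance (`k_oi = k_io p_i / p_o`,
`k_ob = k_bo p_b / p_o`), so `K p = 0` and equilibrium is stationary; only
the efflux rates are free parameters. All closed forms used by the fitters
(2×2 eigen-solution for the biexponential IR signal, matrix-exponential
propagator, SPGR steady state) are validated in the test suite against
independent brute-force oracles: dense eigendecomposition, Runge–Kutta
integration, and explicit RF pulse-train simulation.

Assumptions baked into the signal equations:

* **IR-TSE readout is purely longitudinal.** The echo time (3 ms) is far
  below tissue T2, so echo-train T2 weighting is neglected. Inversion
  efficiency defaults to 1.0 (ideal 180°) and is exposed as an argument.
* **Per-frame SPGR steady state with quasi-static contrast.** Frame
  spacing (4.5 s) is three orders of magnitude above TR, so each dynamic
  frame samples the pulse-train steady state at that frame's
  contrast-modified relaxation rates, evaluated at the frame midpoint.
  This shortcut is contract-tested against stepping the full
  Bloch–McConnell system every TR through an entire scan (< 1e-4
  relative).
* **Perfect spoiling; no transverse exchange; no B1 inhomogeneity.**
* The contrast agent is strictly extracellular: it raises `R1_b` and
  `R1_o` linearly (`R1 += r1·[CA]`) and never touches `R1_i`.

## Contrast kinetics

The arterial input defaults to a population biexponential response
(amplitudes 3.99/4.78 mM·kg/mmol, decays 0.144/0.0111 min⁻¹) scaled
linearly by dose and superposed over bolus arrivals; a measured AIF can be
supplied as CSV `(time_s, concentration_mM)`. Extracellular tissue
concentration follows the standard Tofts convolution expressed per unit
extracellular volume, with plasma concentration `C_b/(1-hct)`
(hct default 0.45). Relaxivity defaults to 4.0 s⁻¹mM⁻¹; the experiments
being emulated span 0.5 T–7 T, so both are configuration, not physics.
The contrast distribution volume is tied to the extracellular water
fraction (`v_o = p_o`) during fitting — water fraction and CA distribution
volume describe the same space, and the tie removes one poorly
identifiable degree of freedom.

## Fitting

All fitters are bounded trust-region least squares with a deterministic
multi-start ladder (five starts log-spaced in k_io over 0.5–20 s⁻¹); ties
are broken toward the smaller exchange rate. Repeated runs are
bit-identical. Bounds bracket all reported glioma values with headroom:
k_io, k_bo ∈ [0, 50] s⁻¹, K^trans ∈ [0, 1] min⁻¹, p_b ∈ [0.005, 0.2],
p_o ∈ [0.05, 0.6].

* **2SX:** joint fit across the 0 and 5 mM IR tables with shared
  `{p_i, k_io, R1_i}` and per-concentration `R1_o`. The slow-exchange
  regime has a pool-label-swapped mirror minimum, so the start ladder
  crosses each k_io start with both (R1_i, R1_o) orderings.
* **3S2X:** the time course is baseline-normalized (no free scale);
  `p_i = 1 - p_b - p_o` is enforced. `R1_i` is held fixed (default
  0.55 s⁻¹) because five free physiological parameters already saturate
  the identifiability of one ROI course; the blood/extracellular baseline
  rates are then set from the measured pre-contrast T1 by fast-exchange
  consistency: `p_b R1_b0 + p_o R1_o0 + p_i R1_i = 1/T1(0)` with
  `R1_b0 = R1_o0`. A course with < 0.1% enhancement is flagged
  `non_identifiable` instead of fitted.
* **Goodness of fit** is reported as the Pearson correlation between
  fitted and observed signal. Least squares is unweighted (ROI-averaged
  magnitude data have high SNR); Rician statistics appear only in the
  simulators.
* **DESPOT1** T1 mapping is the exact two-point linearized solution;
  slopes outside (0, 1) raise for scalars and become NaN in maps.
* **Logistic growth** `Y = A/(B e^(-rT) + c)` is fit in the reduced
  parametrization `(plateau, shape, rate)` because (A, B, c) carry a joint
  scaling degeneracy; passing `fix_A` restores the original scale. The
  rate ladder starts at 0 with ties toward the smaller rate, so constant
  counts resolve to zero growth.

## ROI geometry

The tumor slice is partitioned into six concentric donut-shaped
elliptical ROIs derived from the minimum axis-aligned enclosing rectangle
(center `(X_R, Y_R)`, length `L_R`, width `W_R`). Ellipse m has semi-axes
`a_m = (L_R/2) q^(m-1)`, `b_m = (W_R/2) q^(m-1)` with q = 0.75 —
a geometric shrink, chosen as the simplest law consistent with concentric
similarity and six curves; a linear-shrink alternative
(`1 - (1-q)(m-1)`, sensible for q near 1) sits behind the `shrink`
switch. Rotated minimal rectangles were rejected for determinism.
Conventions: 0-based pixel indices, pixel-center coordinates, x = column.
Biopsy specimens are cylinders (default 2 mm × 10 mm) rasterized by
voxel-center membership in world (mm) coordinates. ROI averaging always
precedes fitting.

## Synthetic data

The generators are pure functions of (configuration, seed) and emulate
the study conditions:

* **Growth cycle:** counts follow `Y = 3.13/(4.56 e^(-0.04 T) + 0.61)`
  (10⁵ cells/dish vs hours) with multiplicative lognormal noise; Ki67⁺
  peaks in the Log phase (phase means 8.4/13.7/6.7% for Lag/Log/Sta);
  k_io couples linearly to Ki67⁺ with slope ≈ 31 s⁻¹ per unit fraction,
  intercept ≈ 2.5 s⁻¹ (matching the phase means 5.0/6.8/4.6 s⁻¹).
* **IR cell-pellet tables:** forward 2SX signal at delays log-spaced per
  contrast level (0 and 5 mM; the 5 mM bath delays are shorter), Gaussian
  noise at the stated SNR.
* **DCE phantom:** elliptical tumor (grid ≥ 32×32) with a radial logistic
  Ki67⁺ ramp from a quiet core (5%) to a proliferative rim (35%) — the
  exact spatial law is a design choice; k_io follows the map-scale
  coupling `k_io = 24 s⁻¹ × Ki67⁺ + 0.20 s⁻¹`; per-voxel three-pool
  forward signals on the human protocol (4.5 s frames, FA 10°, bolus at
  frame 8) or the rat protocol (220 frames, dual bolus at frames 20/120);
  Rician noise at SNR 50 by default.
* **Biopsy cohort:** 79 biopsies over 34 patients, patient-clustered
  log-spread k_io spanning ~0.1–10 s⁻¹, Ki67⁺ = 0.055·k_io + 0.005 plus
  Gaussian noise (sd 0.05). Nuisance MRI features carry weak couplings to
  Ki67⁺ imposed exactly in-sample (noise orthogonalized), preserving the
  in vivo sign pattern (K^trans, DWI, p_b positive; k_bo, ADC negative)
  with every |r| < 0.4 at any seed.
* **Stain fields:** non-overlapping nucleus disks, a stated fraction
  positive in the marker channel, with truth counts returned.

What the generators do **not** emulate: anatomy, motion, B0/B1 artifacts,
partial-volume mixing at tumor borders, inter-scanner variability, and
any nonlinearity in the k_io–Ki67 relationship. Passing tests therefore
demonstrate the correctness and statistical behaviour of the estimation
machinery under the model's own assumptions, not clinical performance.

## Prediction statistics

Cross-validation is row-level five-fold by default (the biopsy dataset is
split almost equally regardless of patient); patient-grouped folds are
available, and row-level mode warns when a patient spans folds. R² and
RMS error are computed on pooled out-of-fold predictions only. The random
forest uses 500 trees with a fixed seed. Voxelwise Ki67⁺ maps use
leave-one-patient-out training and are clipped to [0, 1]. Histogram
entropy min-max normalizes the masked voxels before a 256-bin histogram
(mirroring 8-bit grayscale entropy), making it invariant to affine
intensity rescaling; a constant map has zero entropy and uniform bin
occupancy gives 8 bits.

Percent changes are always reference-relative,
`100 (other - ref)/ref`; treatment-effect comparisons pass the treated
group as reference (e.g. (586.7 − 472.2)/472.2 = 24.2%).

## Numerical choices and problem sizes

* Matrix exponentials of the small exchange-relaxation matrices use a
  batched eigendecomposition (the detailed-balanced generator is similar
  to a symmetric matrix, so eigenvalues are real), vectorized across
  frames.
* Optimizer tolerances are pushed to 1e-15 (xtol/ftol/gtol) for the 2SX
  fitter and 1e-12 for 3S2X; multi-start winners must improve the best
  cost by a relative 1e-9 margin, which implements the smaller-k_io
  tie-break.
* Default problem sizes: 48×48 phantoms with 60–116 frames, 14 inversion
  delays per contrast level, 100-replicate Monte-Carlo runs, and a 5×5
  recovery grid — sizes at which every stage runs in seconds to a couple
  of minutes on a single core while leaving the statistical conclusions
  unchanged.

## Known limitations

* k_io identifiability requires contrast-agent leakage: in low-K^trans
  tissue (the phantom's quiet core), magnitude-noise bias can collapse
  the fitted k_io toward zero even when the noiseless fit is exact. The
  pipeline tests assert rim/core contrast rather than exact ordering
  under noise for this reason.
* The 3S2X fit fixes `R1_i` and ties `v_o = p_o`; both are conventions,
  configurable, and matter if the emulated tissue violates them.
* The ellipse-ring shrink law and the biopsy-cohort coupling constants
  are design choices anchored to reported summary values, not fitted to
  raw data.
* No spatial regularization or Bayesian uncertainty: fits are independent
  per ROI/voxel and report only point estimates with goodness of fit.
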
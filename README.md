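# wexdce

Shutter-speed (water-exchange) DCE-MRI modelling in Python: forward models
and fitters that estimate the transmembrane water-efflux rate **k_io** from
dynamic contrast-enhanced and inversion-recovery MRI, together with the
tumor ROI geometry, synthetic ground-truth generators, and Ki67-prediction
statistics needed to evaluate k_io as an imaging biomarker of glioma
proliferation.

## The problem

Glioma proliferation (the Ki67⁺ cell fraction) is spatially heterogeneous
and can normally only be measured on resected or biopsied tissue.
Proliferating cells upregulate transmembrane water transport (AQP4), so the
steady-state intracellular-to-extracellular water-efflux rate k_io is a
candidate non-invasive surrogate. Conventional DCE-MRI analysis assumes
infinitely fast transmembrane water exchange; the **shutter-speed** family
of models treats the exchange rate as finite — and therefore measurable.

This package is aimed at quantitative-MRI researchers who want to simulate,
fit, and statistically evaluate shutter-speed models without access to the
original scanner data: every pipeline stage runs on synthetic data with
known ground truth.

## Models

Longitudinal magnetization of an n-pool system (mole fractions `p`,
relaxation matrix `R = diag(R1)`, exchange generator `K` with `K p = 0` by
detailed balance) evolves as

    dm/dt = -R (m - p) - K m

**2SX** (cell pellets): intracellular (i) ⇌ extracellular (o), back-rate
`k_oi = k_io p_i / p_o`. The inversion-recovery signal is the
biexponential `S(t)/S(∞) = 1 - 2 [a_L e^(-R1_L t) + a_S e^(-R1_S t)]`
with apparent rates/fractions from the eigen-solution of `R + K`. Fitting
IR curves at 0 and 5 mM extracellular gadolinium jointly (shared
`p_i, k_io, R1_i`) makes k_io identifiable.

**3S2X** (in vivo): blood (b) ⇌ extracellular-extravascular (o) ⇌
intracellular (i), no direct b⇌i exchange. Contrast agent follows Tofts
kinetics (`K^trans`, AIF convolution) and shifts `R1_b`/`R1_o` linearly
with relaxivity; the dynamic SPGR signal per frame is the three-pool
steady state `m_ss = (I - E cos α)⁻¹ (p - E p)`, `E = e^(-(R+K) TR)`.
Five free physiological parameters: `p_b, p_o, K^trans, k_bo, k_io`.

## Worked example

Estimate k_io from a simulated cell-pellet experiment (IR-TSE recovery
curves at 0 and 5 mM contrast, Log-phase truth k_io = 6.8 s⁻¹):

```python
import numpy as np
import wexdce as w

truth = w.TwoSiteParams(p_i=0.7, k_io=6.8, R1_i=0.5, R1_o=0.4)
data = w.generate_ir_dataset(truth, snr=np.inf)
fit = w.fit_2sx(data[data.ca_mM == 0], data[data.ca_mM == 5])
print(f"k_io = {fit.estimates['k_io']:.2f} s^-1, "
      f"p_i = {fit.estimates['p_i']:.3f}, r = {fit.goodness_r:.4f}")
```

```
k_io = 6.80 s^-1, p_i = 0.700, r = 1.0000
```

The fitted efflux rate recovers the generating truth exactly (goodness of
fit r is the Pearson correlation between model and data). On a synthetic
79-biopsy cohort, k_io is the dominant correlate and predictor of Ki67⁺:

```python
table = w.generate_biopsy_table(seed=11)
r, p, ci = w.pearson(table.k_io, table.ki67)
print(f"r(k_io, Ki67+) = {r:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f})")
report, _ = w.cv_predict(table, ["k_io"], model="rf", k_folds=5, seed=11)
print(f"five-fold RF:  R^2 = {report.r_squared:.2f}, "
      f"RMS error = {100 * report.rms_error:.1f}%")
```

```
r(k_io, Ki67+) = 0.97 (95% CI 0.95-0.98)
five-fold RF:  R^2 = 0.91, RMS error = 4.8%
```

See `docs/methods.md` for the model assumptions, parameter defaults and
the design of the synthetic generators.

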
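# Methods

This note records the modelling assumptions, numerical choices, and default
parameters of `coa_surrogate`. Everything here is a package design decision;
problem sizes (sequence capacity, voxel grid, epoch budgets) are choices of
this implementation, selected so the full study runs in minutes on one CPU.

## 1. Synthetic cohort generator (`geometry`)

Each case is a centerline model of the thoracic aorta sampled at a fixed
2 mm arc-length spacing:

* ascending segment (25–40 mm), an elliptical arch joined C¹ at both ends,
  and a descending segment (70–120 mm);
* arch width 40–60 mm; arch **height/width ratio** drawn from 1.15–1.6 for
  gothic arches and 0.6–0.95 for non-gothic ones (the cohort is stratified
  50/50 by default). `classify_arch` uses the strict threshold ratio > 1.0;
* baseline lumen radius 8–12 mm with a Gaussian stenosis
  (severity 0–0.6 = fractional radius reduction, width 5–10 points) in the
  proximal descending aorta;
* three supra-aortic branches at 25/50/75% of the arch span, each taking
  5–10% of the inlet flow; the flow profile is piecewise constant and drops
  immediately distal to each attachment (mass conservation is exact);
* inlet flow 200–400 ml/s; inlet pressure pinned to exactly 120 mmHg.

`measure_arch` recovers height/width from points alone and is invariant to
rigid transformations, so arch labels can be computed on imported geometry.

## 2. Reduced-order physics oracle (`oracle`)

The oracle replaces 3D CFD with a 1D steady model (blood: ρ = 1060 kg/m³,
μ = 3.5 mPa·s; 1 mmHg = 133.322 Pa). Along the centerline:

* **Bernoulli** exchange ½ρ(v² − v₀²) between pressure and kinetic energy
  from the local mean velocity v = Q/(πr²);
* **Poiseuille** dissipation integrated with the trapezoid rule,
  dP/ds = 8 μ Q / (π r⁴);
* **Borda–Carnot** post-stenotic loss: 0.7 · ½ρ · max(v_throat − v, 0)²
  applied downstream of the throat. A "recovery coefficient" of 0.7 can be
  read two ways; we take 0.7 as the *fraction of the ideal dissipation lost*
  (30% pressure recovery), which yields clinically plausible PDs spanning
  the 20 mmHg decision threshold;
* a **gothic-arch** curvature penalty (coefficient 2.0) ramped in when the
  height/width ratio exceeds 1.0, so gothic arches lose more pressure than
  normal ones at matched severity and flow.

Auxiliary channels: WSS = 4 μ v / r (smoothed with a 12-sample moving
average, mirroring ring averaging); a shape–flow descriptor mixing local
curvature and jet intensity; kinetic energy 500 v² mJ/kg; TKE proportional
to the squared jet excess decaying over 30 mm. Optional Gaussian noise is
seeded and off by default; the inlet pressure is re-pinned after noise.

## 3. Feature models (`features1d`, `features3d`)

**1D**: sequences padded to 178 points × 2 mm = 356 mm capacity; longer
geometries raise `CapacityError`. Inputs (7): radius, radius gradient
(central differences, one-sided at the ends — exact for affine profiles),
arc length, curvature, arch-height ratio, flow (ml/s), mean velocity.
Outputs (8): the oracle channels, pressure first. Padding is exactly zero
and excluded from every loss and metric by the validity mask.

**3D**: cross-sectional planes every 4 mm, one per segment (a 100 mm aorta
gives ⌈100/4⌉ = 25 planes; capacity 80 planes = 320 mm), each a 48×48 grid
over a 50 mm field of view after Gaussian decimation from 100×100
(σ = (s−1)/2 ≈ 0.54, reflect boundaries). Decimation is mask-normalised
(filter channel·mask and mask separately, divide) so constants survive and
lumen boundaries do not bleed: plane-averaged 3D pressure matches the 1D
profile within 2%.

## 4. Networks (`nn`, `models`)

Implemented from scratch in NumPy; every layer's backward pass is verified
against central finite differences (tolerance 1e-6).

* **BRNN (1D)**: BiLSTM(200) → Dense(800) + LeakyReLU(0.3) → Dense(8);
  660,008 trainable parameters (2·4·((7+200)·200+200) + (400·800+800) +
  (800·8+8)), i.e. 660,000 rounded to the nearest ten thousand. Forget-gate
  bias initialised to 1; output bias initialised to per-channel target means.
* **U-Net (3D)**: encoder/decoder with skip connections, Conv3D +
  BatchNorm + ReLU blocks, MaxPool/ConvTranspose resampling.
* Training: Adam (lr 1e-3 for the BRNN, 1e-4 for the U-Net), exponential
  decay ×0.96 per epoch, batch sizes 50/8, early stopping with patience 20
  and best-weight restoration, masked-RMSE loss. All randomness flows from
  a single `random_state`; training is bit-reproducible.

## 5. Scaling protocol (pre-registered study)

The loss is a joint masked RMSE over eight channels with wildly different
magnitudes (kinetic energy SD ≈ 773 vs pressure SD ≈ 10 in native units).
We selected the scaling protocol by running a scaling study on the
synthetic cohort and keeping the winner:

| protocol | median pressure RMSE | PD Bland–Altman bias | state |
|---|---|---|---|
| none (native units) | 3.25 mmHg | −2.6 mmHg | converged plateau (240+ epochs) |
| per-channel standardization | 0.62 mmHg | −0.09 mmHg | converged plateau (200 epochs; 0.66/+0.02 already at epoch 60) |

Unscaled training fully converges yet never fits pressure well: the KE
channel dominates the gradient. `BRNNRegressor(scaling="standardize")` is
therefore the protocol for the recovery study. Inputs are scaled *without*
masking so padded timesteps carry one constant token at both fit and
predict time (predict receives no valid lengths); target padding remains
masked out of the loss.

## 6. Evaluation (`evaluation`)

Point-wise RMSE on valid samples; pressure drop = inlet − outlet of the
valid region; V_max read within ±10 points of the stenosis throat;
Bland–Altman with ddof = 1 and ±1.96 SD limits of agreement; paired
comparisons gated by Shapiro–Wilk at α = 0.05 (t-test with mean ± SD
summaries if normal, Wilcoxon with median [IQR] otherwise; identical
vectors short-circuit); treatment classification strictly above 20 mmHg
with sensitivity/specificity (NaN when a class is absent).

## 7. Reproducibility contracts

* Cohorts, training, and experiments are deterministic given seeds.
* HDF5 datasets are written with `track_times=False` and CSV/JSON artifacts
  with fixed ordering, so identical configs reproduce artifacts
  bit-for-bit; `config_hash` excludes `out_dir`.
* Case CSVs round-trip float64 exactly (`float_precision="round_trip"`).

## 8. Limitations

The oracle is a 1D steady reduced-order model, not CFD: no secondary flow,
no pulsatility, and TKE/shape-flow channels are heuristic surrogates. The
synthetic cohort covers idealised planar centerlines with one stenosis.
Results quantify surrogate fidelity *to the oracle*, not to patient data.
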
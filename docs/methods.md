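# Methods

This note documents the models, conventions, numerical choices and known
limitations of `thetaband`, in the order data flows through the package.

## 1. Synthetic EEG model (`simkit`)

Each trial of each subject is a sum of four parts (all in µV):

* **Evoked theta burst** — `a·w_c·exp(−(t−ℓ)²/2σ_b²)·cos(2πf(t−ℓ)+φ)`
  with fixed latency ℓ and fixed phase φ across trials. Defaults: f = 6 Hz,
  ℓ = 200 ms, σ_b = 80 ms, φ = 0.
* **Induced theta burst** — same shape, but latency ℓ + U(−J, J) and phase
  U(0, 2π) drawn per trial. Defaults: f = 6.5 Hz, ℓ = 375 ms, σ_b = 120 ms,
  J = 150 ms.
* **Alpha rhythm** — 10 Hz, continuous, random phase per trial, posterior
  topography; amplitude 1 µV.
* **1/f noise** — white noise spectrally shaped to power ∝ 1/f
  (exponent 1), scaled to RMS 1 µV, independent per channel.

"Evoked" is operationalized as *fixed latency and fixed phase*; "induced"
as *jittered latency and per-trial uniform phase*. The phase-locking flag
in the ground truth is true exactly when jitter is zero and the phase is
fixed.

**Group and subject structure.** Component amplitude is per group, with a
Gaussian between-subject spread (`subject_sd_uv`, default 1 µV; draws
clipped at 0). The defaults inject the qualitative pattern of interest:
posterior evoked theta RL (3.0) > VR (2.5) > PC (2.0) µV, midfrontal
induced theta PC (3.0) > VR = RL (2.1) µV. With subject SD 1, the induced
PC-vs-VR/RL contrast has a true subject-level Cohen's d of 0.9; the
`GroundTruth.true_cohens_d` method exposes this. Theta source frequencies
(6 / 6.5 Hz) are a free choice within the analyzed bands; nothing
downstream depends on the exact values.

**Topography.** Gaussian kernels in great-circle angle on the electrode
sphere, centred on Oz (evoked, alpha) and FCz (induced), width 0.7 rad.
Electrode positions come from a built-in 10-10 table (64 positions,
flat-polar convention mapped to the unit sphere); they are approximate but
geometrically sensible, which is all that cluster averaging and
inverse-distance interpolation require.

**What the generator does not emulate:** spatially correlated noise
(channels are independent — cluster averages therefore have slightly
optimistic SNR), ocular/muscle artifacts, volume-conduction forward
models, non-Gaussian burst shapes, and trial-order effects. The default
generator has *no* first-vs-second-presentation effect, so the
presentation gate triggers only at its false-positive rate; a
`pres_shift`-style effect can be added through the config. A green
pipeline test therefore establishes correctness of the *computations*,
not realism of the cohort.

**Determinism.** Subject seeds derive from `SeedSequence([master, index])`;
cohorts are bit-reproducible functions of their config.

## 2. Preprocessing (`prep`)

Order is fixed and logged: epochize → average reference → deviant-channel
interpolation → detrend + band-pass → time baseline. Windows are half-open
`[start, stop)` in samples, 0-based; t = 0 is stimulus onset.

* **Deviance metric:** the per-channel SD of the concatenated epochs; a
  channel is deviant when its score is more than k = 2 population SDs from
  the population mean. (A voltage-SD score is the standard
  amplitude-based choice; variance or range would flag the same channels
  on this generator.) More than 25 % flagged aborts. Interpolation is the
  inverse-distance-weighted mean of the 4 nearest good channels —
  deliberately simpler than spherical splines, adequate for synthetic
  data; note that interpolating spatially *uncorrelated* channels shrinks
  their variance, so the "interpolated channel looks typical afterwards"
  property only holds for spatially coherent data (as in real EEG).
* **Filter:** linear detrend per trial/channel, then a Hamming-windowed
  sinc band-pass 0.25–30 Hz applied forward–backward (zero phase).
  Nominal transition widths are 0.25 Hz (low) and 7.5 Hz (high), but a
  0.25 Hz transition needs ≈ 6 800 taps at 512 Hz — unrealizable on a
  1024-sample epoch — so the length is capped at one third of the epoch
  (341 taps), giving an effective low-edge transition of ≈ 5 Hz. The
  theta band is unaffected (passband from ≈ 2.8 Hz); DC and drifts are
  removed by the detrend. Filtfilt transients span about one filter
  length at each epoch edge.

## 3. Time-frequency decomposition (`tfr`)

Morlet wavelets `exp(−t²/2σ_t²)·exp(i2πf₀t)` with constant Q: m = f₀/σ_f
= 7, σ_t = m/(2πf₀), truncated at ±3σ_t. The 0.5 Hz grid spacing (199
wavelets for 1–100 Hz) is the *frequency axis resolution*; the spectral
bandwidth of each wavelet is σ_f = f₀/7. Kernels are normalized such that
a unit-amplitude sinusoid at f₀ yields modulus 1.0 — amplitude (µV), not
power, is the analyzed quantity, and the TF baseline is subtractive in
those units.

* **Evoked** maps transform the time-domain trial average. **Induced**
  maps subtract the ERP from every trial, transform each residual trial,
  and average the moduli (never complex averages).
* **Edges:** signals are mirror-padded by the kernel half-length; a
  per-frequency validity mask marks ±3σ_t at the epoch boundaries. On 2 s
  epochs the mask at 4–5 Hz covers the −300…0 ms baseline window
  entirely; the baseline op then warns and uses whatever valid samples
  exist (or all samples when none are valid) — an inherent constraint of
  low-frequency wavelets on short epochs, also present in the original
  design this mirrors.
* **Amplitude recovery is band-limited in time.** A burst of envelope SD
  σ_b measured by a wavelet of width σ_t is attenuated by
  σ_b/√(σ_b²+σ_t²); at 6.5 Hz, σ_t ≈ 171 ms, so the default 120 ms
  induced burst reads ≈ 0.57 of its true peak. The "induced recovers true
  amplitude within 15 %" contract is therefore tested with a
  quasi-stationary burst (σ_b = 500 ms) — for short bursts the transform
  is *proportionally* correct (linear), which is what the group
  statistics need, but not peak-calibrated. This is time-frequency
  uncertainty, not an implementation defect.
* **Numerics.** Convolution is frequency-domain, with frequencies chunked
  by kernel length so short kernels use short FFTs. Double precision is
  exact to 1e-8 against direct time-domain convolution. The per-trial
  induced batch runs in single precision with a band-limited inverse FFT
  (only the occupied spectral bins of the kernel are transformed, at 8x
  oversampling, with linear interpolation of the smooth modulus);
  measured error ≤ 1e-3 relative, far below between-subject variability.
  A 99-subject default run (2–30 Hz bank) completes in ≈ 10 min on one
  CPU.
* The routine pipeline bank is **2–30 Hz**: above 30 Hz the band-pass
  leaves no content, and below 2 Hz a 7-cycle wavelet (±3σ_t ≈ 3.3 s) is
  longer than the 2 s epoch itself, so such wavelets cannot be applied —
  the full 1–100 Hz bank remains available for longer recordings.

## 4. Regional means (`bandstats`)

Arithmetic mean over cluster channels x band frequencies (inclusive on
the 0.5 Hz grid: 4–7.5 Hz → 8 bins, 5–8 Hz → 7 bins) x window samples
(half-open). Clusters use the explicitly documented electrodes; the
central cluster ("Cz and neighbours", membership not individually
documented) is reconstructed as Cz, C1–C4, FC1, FCz, FC2, CP1, CPz, CP2.
Unnamed "neighbouring electrodes" of the other clusters are omitted — they
cannot be reconstructed — with membership configurable.

## 5. Inference (`inferstats`)

* **Split-plot ANOVA** (1 between, 1–2 within factors, balanced designs
  only): between effects tested against subjects-within-groups, each
  within effect against its subject x factor interaction. Effect size is
  partial η² = SS_eff/(SS_eff+SS_err). Mauchly's W and Greenhouse–Geisser
  ε come from the covariance of within-level scores pooled *within
  groups* (the SPSS convention; pingouin centres across all subjects
  instead, which differs in small samples — F, SS, df and η² agree
  exactly). Corrected p (df multiplied by ε) is reported whenever
  Mauchly's p < .05; ε = 1 exactly for 2-level factors.
* **Presentation gate:** the presentation x window x group ANOVA is run
  first; if the presentation main effect or any interaction involving it
  is significant at .05, only first presentations are analyzed further,
  otherwise presentations are averaged.
* **t-tests:** Levene's test (mean-centred, the classic variant) at
  α = .05 selects pooled-Student vs. Welch–Satterthwaite. Cohen's
  d = t·√(1/n₁+1/n₂) for both variants (this reproduces published d
  values for Welch rows as well). BF₁₀ is computed from the t statistic —
  sufficient under the JZS model for pooled designs, and within ~1 % for
  Welch rows at these sample sizes.
* **JZS Bayes factor:** Rouder et al.'s two-sample default Bayes factor,
  Cauchy prior scale √2/2 on the standardized effect; the g-mixture
  integral is evaluated by adaptive quadrature on log g over ±35 (rel.
  tol. 1e-8), checked against a 200 001-point Simpson grid to 1e-6.
  Summary-statistic tests realize data as standard-normal quantiles
  rescaled to the exact printed mean/SD — any statistic depending on the
  data only through (n, mean, SD) is then exact.
* **Power solver:** smallest N with `ncf.sf(F_crit, k−1, N−k, f²·N)` ≥
  target, by monotone search; f² = η²/(1−η²). For η² = .14, α = .05,
  power .95, k = 3 this gives N = 98, verified by Monte-Carlo simulation
  (20 000 replicate ANOVAs) to within 0.01. The solver assumes the
  one-way fixed-effects omnibus test with λ = f²·N independent of the
  group allocation.

## 6. Known limitations

* Designs must be balanced and complete; no missing-cell handling.
* Sphericity corrections implement Greenhouse–Geisser only (no
  Huynh–Feldt).
* The EDF/BDF reader covers continuous single-rate recordings (the
  BioSemi case) — not annotations (EDF+), variable rates, or
  discontinuous records.
* Bayes factors are two-sample JZS only; no Bayesian ANOVA.
* Interpolation quality degrades for edge electrodes (fewer close
  neighbours) and for spatially uncorrelated data (see §2).
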
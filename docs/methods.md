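# Methods

`nirscouple` assesses cerebral autoregulation from simultaneous prefrontal
fNIRS and continuous arterial-blood-pressure (ABP) recordings. This note
documents the models, the defaults, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Signal model and preprocessing

One subject's session consists of four hemoglobin-concentration channels
(O2Hb and HHb, left and right prefrontal cortex, 20 Hz) and one ABP channel
(1000 Hz), nominally 15 min long. Preprocessing:

1. **Motion-artifact correction** (NIRS channels). Samples whose moving
   standard deviation (2 s window) exceeds 4x the series' robust scale
   (1.4826 x MAD) are flagged; each flagged run is extended forward until the
   local level returns to within 2 robust scales of the pre-artifact
   baseline (at most 30 s), so a step-plus-decay transient is covered in
   full. Within each segment a cubic smoothing spline (smoothing chosen by
   generalized cross-validation) is subtracted and the residual re-leveled
   onto a linear bridge between the clean edge levels. Samples outside
   flagged segments are returned bit-identical — a deliberate locality
   guarantee, which also means a genuinely permanent baseline shift is
   smeared across the corrected segment rather than propagated.
2. **Spike suppression** (NIRS channels): centered 5-s moving average,
   window rounded to the nearest odd sample count, shrinking windows at the
   edges (no invented data). The ABP channel is never smoothed at 5 s — that
   would erase the 0.6–2 Hz cardiac oscillation the coupling analysis needs.
3. **Decimation** of ABP to 20 Hz with a polyphase Kaiser-window FIR
   (stopband at the new Nyquist, >= 60 dB) and **alignment** by truncation
   to the common span (minimum 10 min by default).

The tissue oxygenation index TOI = 100·O2Hb/(O2Hb+HHb) is computed on
artifact-corrected but *unsmoothed* concentrations (smoothing is a
phase-analysis concern, not an oxygenation one; the time mean is unaffected
to first order). TOI needs absolute-equivalent concentrations; pure
zero-mean change signals are rejected.

## Phase extraction

Band phases are extracted with the complex Morlet wavelet
psi(u) = pi^(-1/4) exp(i 2 pi u) exp(-u^2/2), scale-to-frequency map
f = 1/s, L2 (1/sqrt(s)) normalization, on a logarithmic grid with 16 voices
per octave, endpoints inclusive. Bands: VLF 0.02–0.07 Hz and LF 0.07–0.2 Hz
for O2Hb, 0.6–2 Hz (cardiac) for ABP. The analytic-sign convention makes
extracted phase increase with time for a physical oscillation.

A band's single phase is the unwrapped argument of the *band-averaged*
complex coefficient, not a tracked ridge: at the low signal-to-noise of VLF
oscillations ridge tracking is fragile, the average is deterministic, and
it treats the band as one oscillatory mode. Samples within the cone of
influence (sqrt(2)·s seconds per edge at the band's lowest frequency) are
excluded; at least 5 cycles of f_lo must survive or the series is rejected
as too short.

## Coupled phase-oscillator inference

The cardiac ABP phase phi_A and a slow O2Hb phase phi_O are modelled as

    dphi_m/dt = sum_k c_k^(m) Phi_k(phi_A, phi_O) + xi_m(t),   m in {A, O},

with {Phi_k} the 2-D Fourier basis up to order K (constant plus
sin/cos(a·phi_A + b·phi_O), canonical representatives, (2K+1)^2 terms) and
xi Gaussian white noise with 2x2 intensity matrix E. K defaults to 2 — it
keeps the 8000-sample windows of a 15-min record well conditioned and is
the standard order in the coupling-function literature.

Windowed Bayesian estimation iterates the stationary conditions of the
Gaussian posterior: noise matrix from weighted residuals, concentration
Xi = Xi_prior + h·sum kron(E^-1, Phi Phi^T), moment vector including the
midpoint drift correction −(h/2)·sum dPhi/dphi_m, then c = Xi^-1·moment,
until the relative change of c falls below 1e-6 (at most 100 iterations).
Phase velocities are forward differences over one sample; basis functions
are evaluated at midpoint phases. With no prior the recursion starts from
zero coefficients and a fully diffuse concentration, in which case the
fixed point coincides with ordinary least squares up to the drift term —
the zero-noise equivalence tests exploit exactly this. Between consecutive
non-overlapping windows the posterior propagates as the next prior with
covariance inflated by prop_const^2·diag(c^2) (prop_const = 0.2), allowing
slow parameter drift. Window lengths: 400 s for VLF pairings, 200 s for LF
(>= 8 cycles of the slow oscillation), falling back to one full-span window
on shorter records. E is regularized by 1e-14 on the diagonal before
inversion; a singular concentration matrix raises a conditioning error
suggesting a longer window or smaller K.

**Coupling strength** CS in a direction is the Euclidean norm of the target
equation's coefficients on every basis term that depends on the source
phase (mixed terms included; constant and self-terms excluded). The norm
(rather than a sum of squares) keeps CS in rad/s and makes the
directionality index CD = (CS_AO − CS_OA)/(CS_AO + CS_OA) a dimensionless
ratio in [−1, 1]. A squared variant is available by flag. The per-subject
scalar is the mean of the windowed CS values. Oscillator labels are fixed:
A = cardiac ABP, O = slow O2Hb; CS_AO is the quantity of clinical interest
(pressure fluctuations passing into cerebral hemodynamics). Coupling
surfaces q(phi_A, phi_O) are evaluated on a uniform grid excluding the
constant term; group surfaces average the evaluated surfaces (identical to
averaging coefficients for this linear basis).

Both CS and CD are invariant to adding constants to either unwrapped phase
(each (a,b) pair carries both sin and cos, so constant shifts rotate within
pairs without changing norms).

## Cohort statistics

Per variable (TOI summaries and the four CS columns): one-sample
Kolmogorov–Smirnov against the fitted normal per group, Levene
(mean-centered) across groups, one-way fixed-effects ANOVA, and the three
pairwise pooled-variance t-tests (NC–MCI, NC–CI, MCI–CI) flagged at the
Bonferroni-corrected level alpha/3 = 0.0167 (Welch variant by flag).
Pearson correlations relate each variable to the MoCA score. ROC analysis
distinguishes MCI from NC using mean TOI (low = positive) and the bilateral
mean CS (high = positive); the operating threshold maximizes Youden's J
(ties broken toward sensitivity — a screening context), and the AUC CI is a
seeded stratified-bootstrap percentile interval (2000 resamples by
default). p-values are reported to 4 decimals in the formatted summary.

## Synthetic cohorts

Because the human recordings are not public, cohorts are simulated with the
statistical structure the analysis assumes. Each subject is a set of
Euler–Maruyama-integrated stochastic phase oscillators at the 20 Hz sample
step: a cardiac oscillator (1.1 Hz, phase-noise intensity 0.05 rad^2/s),
slow ABP oscillators (0.055 and 0.11 Hz, 0.005 rad^2/s), and per
hemisphere a VLF (0.04 Hz) and an LF (0.1 Hz) cerebral oscillator
(0.02 rad^2/s). Two group-scaled coupling pathways drive the cerebral
oscillators:

- **cardiac cross-frequency coupling** (default 0.1·sin(phi_A) rad/s),
  whose scaled norm is stored per subject as ground truth for parameter
  recovery; and
- **pressure-passivity entrainment** by the slow ABP oscillations
  (0.02·sin(phi_s − phi_O) rad/s, below the locking threshold given the
  deliberate detuning), emulating slow pressure waves passing into cerebral
  hemodynamics when autoregulation is impaired.

Waveforms are baseline + amplitude·cos(phase) with ~10 s-correlated
amplitude jitter, white measurement noise, Poisson single-sample spikes
(1/min, sd 3 units) and step-plus-exponential-decay motion transients
(0.3/min, sd 2 units, tau 5 s). ABP (1000 Hz) interpolates the cardiac
phase; HHb is built from the O2Hb clean mean so that the clean-signal TOI
equals a per-side draw from the group profile exactly. Group profiles: TOI
means 65/62/58% (sd 4%) and coupling scales 1.0/1.5/2.0 for NC/MCI/CI;
MoCA scores are drawn at 26.94±1.54, 20.60±3.42, 10.62±3.16, clipped to
[0, 30], rounded, and subjects are assigned to groups by the score banding
(>= 26 NC, 15–25 MCI, <= 14 CI), with a flag when a draw crosses its
intended band. Per-subject randomness derives from (cohort seed, subject
index) through a counter-based seed sequence, so generation is reproducible
and order-independent.

### What the synthetic cohorts do and do not show

Phase-level recovery is exact and well calibrated: inference on the
integrated phases recovers generative coefficients (zero-noise equivalence
with least squares to 1e-6; Spearman >= 0.9 between coupling amplitude and
inferred CS; correct directionality in >= 90% of runs at eps >= 0.2).

The waveform-level composition has a structural limitation worth stating
plainly: a basis term with a != 0 modulates the slow phase velocity at
~a·1.1 Hz, and the band-averaged Morlet phase of a VLF oscillation
suppresses content at 1.1 Hz essentially completely. Measured through the
full waveform -> wavelet -> inference chain, CS_AO is therefore a small
numerical floor that does not respond to the generative cardiac->slow
coupling scale — noise-free experiments recover 0.4 rad/s from the phases
but ~1e-6 from the waveforms. Consequently the end-to-end cohort reproduces
the expected group pattern in TOI but not in measured VLF CS, and the
end-to-end CD is typically negative (the wide cardiac band retains its
noise floor while the narrow VLF band does not). Real recordings contain
broadband physiological noise and richer cross-band structure that the
generator does not model; passing phase-level tests demonstrate the
inference machinery, not that band-limited phases of real signals carry
recoverable cardiac-rate coupling.

Also not modelled: respiratory-band oscillations, Balloon/Windkessel
hemodynamics, EEG, and the device's spatially-resolved-spectroscopy
pathway (the generator emits absolute-equivalent concentrations directly).

## Problem sizes

Default simulations use 15-min records at the instruments' native rates.
The cohort power analysis uses 15 subjects per group over 10 cohort seeds;
recovery experiments use 900-s phase simulations across 5–50 seeds per
condition. These sizes give stable rates while keeping a full run on one
CPU within minutes.
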
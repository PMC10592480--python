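# Methods

This note documents the models, parameters and design choices behind the
package, and what the synthetic-data tests do and do not establish about real
recordings.

## Optical model

Reflectance at wavelength λ attenuates as
`I_norm(t, λ) = exp(−Δμa(t, λ) X_R(λ))` with
`Δμa = ε_HbO(λ) Δ[HbO] + ε_HbR(λ) Δ[HbR]` (modified Beer-Lambert law).
Per sample this is a 2×2 linear system; the implementation precomputes the
inverse of the extinction matrix `[ε·X]` and requires it to be nonsingular.

Fluorescence is attenuated on both legs — excitation (lime, ~565 nm) on the
way in and emission (red, ~600–630 nm) on the way out. Approximating the
excitation-leg absorption by the green-reflectance attenuation and the
emission leg by the red, each raised to a pathlength ratio, gives

    F(t)/F(base) = I_norm_em / (I_norm_red^Pr · I_norm_green^Pg),

with `Pg = X_ex(λ_ex)/X_R(λ_green)` and `Pr = X_em(λ_em)/X_R(λ_red)`.

**Constants.** Extinction coefficients default to a Prahl-style hemoglobin
compilation at 530 nm (ε_HbO ≈ ε_HbR ≈ 3.9·10⁴ cm⁻¹/M, near-isosbestic) and
625 nm (ε_HbO ≈ 741, ε_HbR ≈ 5763 cm⁻¹/M), converted to 1/(µM·mm).
Reflectance pathlengths default to 0.44 mm (green) and 3.7 mm (red) — nominal
cortical values; green photons are absorbed quickly, red photons travel far.
All constants are configuration with YAML override hooks
(`OpticalModel.to_yaml`/`from_yaml`); the algorithms, not the constants, are
the contribution, and none of these values should be read as measured.

**Pathlength-ratio estimation.** `estimate_pathlength_ratios` grid-searches
(Pg, Pr) over [0, 0.6] × [0.5, 2.5] (steps 0.05 / 0.1, matching the plausible
ranges for these ratios) minimizing the mean absolute Pearson correlation of
the corrected fluorescence with Δ[HbO] *and* with Δ[HbR] across pixels.
Residual hemodynamic cross-talk appears as exactly these correlations.
Decorrelating against Δ[HbT] alone is insufficient: when the two chromophores
co-vary, the green and red attenuations are collinear and a whole line of
(Pg, Pr) pairs removes the same Δ[HbT]-projected cross-talk; the two-chromophore
objective contributes two independent constraints and has a point minimum.
The estimator assumes neural activity and hemodynamics are not strongly
correlated at zero lag; on sessions where hemodynamics are driven by the
neural signal itself the objective floor rises and the minimum flattens. For
computational economy the objective is evaluated on a seeded subsample of at
most `max_pixels` (default 512) pixels.

## Preprocessing

Filters are Chebyshev type I (the stated "pass-band ripple" identifies the
family), order 20, 0.2 dB ripple — interpreted as dB, the conventional unit —
designed as second-order sections and applied forward-backward
(`sosfiltfilt`), so the effective magnitude response is the squared single-pass
response and the net phase shift is zero. Low-pass filtering operates on
mean-removed data with the mean restored afterwards: an even-order
Chebyshev-I sits `ripple` dB below unity at DC, and restoring the mean keeps
constants (and baseline levels) exact. Defaults: 6.5 Hz low-pass for neural
signals (heart-rate suppression), 0.25 Hz for hemodynamics (breathing-band
vascular artifacts at 1–4 Hz).

Global pulsation removal divides each frame by
`1 + highpass(global mean fraction)` — heart-rate pulsation is near-uniform
across the field and multiplicative in intensity. PCA denoising is a
truncated SVD of the mean-centered pixel×time matrix (idempotent; component
counts scale with data size — 200/300 components apply at the instrument's
512×512 scale, small synthetic stacks use proportionally fewer). Lags are
applied as integer-frame shift-and-trim with the surviving frame range
returned so companion series can be trimmed identically; 1.5 s at 20 Hz is
exactly 30 frames.

## Parcellation

Correlation-distance k-means is implemented by row-standardizing pixel traces
and running Euclidean k-means on `z/√T`: for z-scored rows,
`‖z_i − z_j‖² = 2T(1 − r_ij)`, so the two objectives coincide. One hemisphere
is clustered first (best of `replicates` seeded restarts); its labels are
reflected across the 2-pixel midline to initialize the contralateral
clustering; left/right centroids are paired by maximal temporal correlation
via the Hungarian algorithm, with exact ties broken by the spatial overlap of
mirrored masks. Cluster-count evaluation fits every pixel trace by NNLS on the
candidate centroid sets and reports residual and explained variance next to
the PCA (optimal linear) bound at matched rank. The consensus map canonically
relabels repeated maps by optimal assignment on label-overlap counts and takes
the per-pixel mode; ties fall to the earliest map in the caller's order
(callers should sort by within-cluster distance). Subgrouping clusters each
hemisphere's rows of the mean correlation map into 6 groups (12 total) and
emits the group-mean reduced map used for cortical projection. Cross-animal
registration is out of scope; maps are per-dataset.

## Correlation dynamics

Windowed correlation maps use 10-s windows (200 samples at 20 Hz); the window
step defaults to 1 frame and is configurable (the analyses here use 5 frames
= 0.25 s; coefficients are effectively continuous at either setting).
Hemodynamic windows are linearly detrended per ROI before correlation.
Zero-variance ROIs within a window get zeroed rows/columns (diagonal kept at
1) with a warning. Map distances operate on the strict upper triangle — the
diagonal is identically 1 and both triangles are redundant — as Frobenius
(Euclidean) distance or Pearson correlation of the vectorized triangles.
Welch PSDs use 4-s Hann segments with 50% overlap; band maps apply an ideal
FFT-domain band-pass to zero-meaned traces.

## Behavioral correlation states

Bout detection thresholds |wheel velocity| at 5% of the session's
99th-percentile speed by default (the acquisition criterion is "a
predetermined level"; this adapts it per session), merges runs separated by
< 1 s, and attaches pre/post rest durations. The five states take 10-s
windows as follows (half-open frame intervals, 0-based):

| state          | window                  | qualifying bouts                    |
|----------------|-------------------------|-------------------------------------|
| onset          | [onset−5 s, onset+5 s)  | duration ≥ 10 s, pre-rest ≥ 60 s    |
| locomotion     | middle 10 s of bout     | duration ≥ 20 s                     |
| offset         | [offset−5 s, offset+5 s)| duration ≥ 20 s, post-rest ≥ 10 s   |
| initial rest   | [offset, offset+10 s)   | duration ≥ 5 s, post-rest ≥ 60 s    |
| sustained rest | [offset+40 s, +50 s)    | same bouts as initial rest          |

The 40-s delay reflects the pupil's return to baseline roughly 40 s after
running stops. The NNLS decomposition operates on strict-upper-triangle
vectors (the unit diagonal would act as a fixed intercept); goodness of fit is
`Σ(d − Σ c_n x_n)² / Σ d²`, defined as 1 for an all-zero map.
Cross-validation partitions bouts (not windows) round-robin into 5 folds;
each moving window is assigned the fold of the temporally nearest bout and is
fit against a basis built only from the other folds' state windows, so no
window is scored against a basis its own bout helped build. If a fold would
strip a state of all training windows, the fit falls back to the full window
set with a warning. Event-aligned coefficient averages interpolate each
bout's coefficient traces onto an event-relative grid (time 0 at the onset or
offset frame) and report mean ± SEM; window-to-time assignment uses window
centers throughout. Rest epochs are sub-threshold periods ≥ 60 s that start
at a locomotion offset (a session-leading rest segment has no
initial→sustained transition to quantify). Pupil-coefficient correlations
average the pupil over each coefficient's 10-s window before correlating,
matching the smoothing the correlation window imposes on the coefficients.

## Statistics

Rank-sum map comparisons test each unique upper-triangle entry two-sided;
the Bonferroni family is the number of unique entries per matrix (4186 for
92 ROIs — the family choice is per-matrix, not per-figure). Exact p-values
(permutation enumeration) are used when both groups have ≤ 10 maps and no
ties, the normal approximation with tie correction otherwise; the z sign
convention is z > 0 ⟺ second group larger. Display maps zero insignificant
entries; raw z values are retained. Epanechnikov KDE bandwidth follows
Silverman's rule scaled for the Epanechnikov kernel,
`h = (40√π/n)^{1/5}·σ`, with σ the robust minimum of SD and IQR/1.349.
Fisher-z comparisons clip |r| = 1 to 1−10⁻¹² before `atanh`.

## Synthetic sessions: what they emulate

The generator's defaults are the emulated study conditions: 20 frames/s per
channel, 10-min sessions, sparse locomotion (≈ 0.55 bouts/min, 12–45 s
durations, gaps ≥ ~66 s so that onset/initial/sustained-rest criteria are
frequently met), 0.1–6 Hz band-limited rest fluctuations, gamma HRF (shape
2.5, scale 0.35 s — only the family is established; these values give a
plausible ~0.5-s peak) delayed 1.5 s, pupil decay τ = 15 s (baseline return
≈ 40 s after offset), heart/breath components at 9 and 2.5 Hz, and parcel
geometry as rectangular tiles per hemisphere with a 2-pixel midline gap
(bilateral mirroring exact by construction; cortical anatomy is not needed to
test the algorithms). Rest fluctuations are band-pass-filtered white Gaussian
noise: a flat in-band spectrum keeps the signal autocorrelation narrow so the
hemodynamic cross-correlation peak reflects the HRF kernel rather than source
color.

The correlation structure is built from latent sources so that each state has
the documented signature: anterior parcels carry 2× rest-fluctuation
amplitude (quiet-rest fine structure; the anterior/posterior amplitude ratio
is a free parameter, not an established value), suppressed to 0.3× during
running; bilateral coupling of the rest fluctuations is itself
state-dependent (anterior pairs r = 0.9 at rest, largely desynchronized while
running; posterior pairs r = 0.5 at rest and more synchronous during running
through a pair-shared running drive); a cortex-wide component whose coupling
follows arousal — strong immediately after running, decaying with the pupil —
and is gated off during bouts separates initial from sustained rest and links
the anterior-posterior axis at high arousal. Hemodynamics convolve the neural
latents with the lagged gamma kernel (amplitude 4 µM per unit latent), add an
oxygenation component independent of blood volume (entering Δ[HbO] and
Δ[HbR] with opposite signs — without it the green and red attenuations are
collinear and (Pg, Pr) is unidentifiable), plus heart/breath sinusoids, and
are gated to zero during the leading 5-s baseline window that the
100-frame baseline selection uses. Bout edges snap to 0.25-s boundaries so
state windows land on coarse moving-window grids.

**What passing tests show — and do not.** The synthetic sessions make the
pipeline's measurement chain verifiable end to end: exact optical round
trips, planted-parcel recovery, cross-validated state-label recovery, and the
directional rest/locomotion effects are guaranteed by the generator's
construction and must be detected by the pipeline. They do not establish that
real cortex has these effect sizes: the generator has no vascular anatomy, no
pixel-level photon noise, no eye blinks, no motion artifacts, and its state
structure is low-dimensional by design. Headline statistics from the animal
dataset (e.g., reciprocity −0.7 ± 0.2 across 182 epochs) are emulated in
direction and rough magnitude, not reproduced.

## Problem sizes used in tests and analyses

Synthetic sessions run at 24×24 pixels with 8 parcels per hemisphere
(10 min) for end-to-end analyses, 60×60 with 46 parcels per hemisphere
(90–120 s of rest) for the full-scale parcellation and spectroscopy checks,
and 20×18 with 4 parcels per hemisphere for estimator unit tests; k-means uses
2–10 restarts in tests (100 restarts is the full-scale setting; the recovered
structure on planted data is insensitive to restarts well before that). The
map-comparison null calibration uses 200 simulations of 10×10 maps at
n = 20/20. These sizes are the package's own test design; all algorithms are
size-agnostic.

## Known limitations

* The fluorescence correction assumes the excitation/emission-leg absorption
  matches the green/red reflectance attenuation up to a fixed exponent; it is
  least accurate where that proportionality fails (e.g., midline vessels).
* The GCaMP (blue-excitation) correction variant is not implemented.
* `estimate_pathlength_ratios` requires hemodynamic variation that is not
  strongly neurally locked at zero lag.
* NNLS state coefficients are identified only up to the basis's linear
  independence on the upper triangle; near-collinear state maps (e.g., very
  similar rest states) broaden the coefficient estimates.
* With few qualifying bouts per session, cross-validated bases average very
  few windows and state discrimination degrades; the defaults ensure 4–5
  windows per state per 10-min session.
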
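"""Ground-truthed synthetic WFOM sessions.

Emulates the statistical structure the downstream analyses assume, so every
stage is testable without instrument data:

* **Behavior** — locomotion bouts on a wheel (smoothed rectangular velocity),
  pupil diameter driven by an arousal variable that rises quickly during
  running and decays exponentially (τ ≈ 15 s, back to baseline ≈ 40 s after
  offset), and whisking elevated around bouts.
* **Cortex** — rectangular bilateral parcels; each parcel carries a shared
  band-limited (0.1-6 Hz) "rest fluctuation" latent with a target bilateral
  correlation, amplified in anterior parcels and suppressed during locomotion;
  posterior (sensory) parcels additionally carry locomotion-locked activation.
  A global component whose coupling strength follows arousal links the
  hemispheres and the anterior/posterior axis more strongly at high arousal,
  which is what makes the initial-rest and sustained-rest correlation states
  distinct and pupil-linked.
* **Hemodynamics** — gamma-HRF convolution of the neural latents, delayed by
  a fixed lag, plus small sinusoidal heart/breath components on the hemoglobin
  concentrations; zero during the leading baseline window.
* **Optics** — the Beer-Lambert forward model renders hemoglobin into green /
  red reflectance and attenuates fluorescence on the excitation and emission
  legs with exponents set by the pathlength ratios Pg, Pr, exactly invertible
  by the spectroscopy module.

All randomness flows from ``SimConfig.seed``; identical configs give
bit-identical sessions. Bout edges are snapped to 0.25-s boundaries so
state-window starts land on coarse moving-window grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.stats import gamma as gamma_dist

from corticostate import states as states_mod
from corticostate.behavior import BehaviorTrace
from corticostate.dynamics import fft_bandpass
from corticostate.session import RawSession
from corticostate.spectroscopy import OpticalModel, beer_lambert_forward

STATE_CODES = {"other": 0, "onset": 1, "locomotion": 2, "offset": 3,
               "initial_rest": 4, "sustained_rest": 5}

_SNAP_FRAMES = 5  # bout edges snap to 0.25 s at 20 Hz


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    frame_rate: float = 20.0  # Hz per LED channel
    duration_s: float = 600.0  # one recording session
    image_shape: tuple[int, int] = (60, 60)
    n_parcels_per_hemisphere: int = 8  # 46 for full-scale emulation
    bout_rate_per_min: float = 0.55
    bout_duration_range_s: tuple[float, float] = (12.0, 45.0)
    rest_fluctuation_band: tuple[float, float] = (0.1, 6.0)
    rest_fluct_gain_anterior: float = 2.0
    locomotion_suppression_factor: float = 0.3
    bilateral_r: float = 0.9  # anterior pairs at rest
    posterior_bilateral_r: float = 0.5  # posterior pairs at rest
    loco_desync: float = 0.8  # fractional loss of rest bilateral coupling while running
    hrf_shape: float = 2.5
    hrf_scale_s: float = 0.35
    hrf_amplitude_uM: float = 4.0
    hrf_lag_s: float = 1.5
    pupil_baseline_px: float = 40.0
    pupil_gain_px: float = 20.0
    pupil_rise_tau_s: float = 2.0
    pupil_decay_tau_s: float = 15.0
    pupil_noise_sd_px: float = 0.2
    artifact_heart_hz: float = 9.0
    artifact_breath_hz: float = 2.5
    artifact_amp_uM: float = 0.3
    fluct_amp: float = 0.04  # fractional fluorescence sd per unit latent
    pixel_noise_sd: float = 0.01  # fractional fluorescence noise per pixel
    hemo_noise_sd_uM: float = 0.05
    global_coupling_low: float = 0.15
    global_coupling_high: float = 1.0
    arousal_amp_drop: float = 0.3  # fractional anterior-amplitude drop at full arousal
    sensory_drive_gain: float = 2.0
    baseline_s: float = 5.0  # leading rest segment with zero hemodynamics
    hemo_from_neural: bool = True  # False: hemodynamics independent of true_F
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0.0 < self.locomotion_suppression_factor < 1.0):
            raise ValueError("locomotion_suppression_factor must be in (0, 1)")
        if self.hrf_lag_s < 0:
            raise ValueError("hrf_lag_s must be nonnegative")
        if not (0.0 <= self.bilateral_r <= 1.0):
            raise ValueError("bilateral_r must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline is supposed to recover."""

    parcel_labels: np.ndarray  # (rows, cols), 0 = midline gap
    bilateral_pairs: list[tuple[int, int]]
    state_schedule: np.ndarray  # per-frame STATE_CODES value
    state_windows: dict[str, list[tuple[int, int]]]
    parcel_timecourses: np.ndarray  # (n_parcels, T) neural latents
    anterior: np.ndarray  # bool per parcel
    arousal: np.ndarray  # a(t) in [0, ~1]
    true_F: np.ndarray  # (pixels, T) F(t)/F(base)
    true_hbo: np.ndarray  # (pixels, T) µM
    true_hbr: np.ndarray  # (pixels, T) µM
    true_Pg: float
    true_Pr: float
    frame_rate: float

    @property
    def true_hbt(self) -> np.ndarray:
        return self.true_hbo + self.true_hbr


def _snap(frame: int) -> int:
    return int(round(frame / _SNAP_FRAMES)) * _SNAP_FRAMES


def simulate_behavior(config: SimConfig) -> tuple[BehaviorTrace, list[dict]]:
    """Wheel velocity, pupil and whisking, plus the planted bout list.

    Bout onsets are separated by gaps long enough that most bouts carry the
    60-s pre/post rest the state definitions require (the emulated sessions
    have sparse running). ``bout_rate_per_min = 0`` gives a still session.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    fr = config.frame_rate
    velocity = np.zeros(n)
    bouts: list[dict] = []

    if config.bout_rate_per_min > 0:
        lo, hi = config.bout_duration_range_s
        mean_dur = (lo + hi) / 2.0
        mean_gap = max(60.0 / config.bout_rate_per_min - mean_dur, 66.0)
        t = max(66.0, mean_gap * rng.uniform(0.9, 1.1))
        while True:
            dur = rng.uniform(lo, hi)
            onset = _snap(int(round(t * fr)))
            offset = _snap(int(round((t + dur) * fr)))
            if offset + int(2 * fr) >= n:
                break
            amp = rng.uniform(8.0, 15.0)
            velocity[onset:offset] = amp * _bout_profile(offset - onset, fr, rng)
            bouts.append({"onset_frame": onset, "offset_frame": offset, "amplitude": amp})
            t = offset / fr + mean_gap * rng.uniform(0.85, 1.15)
        if not bouts:
            warnings.warn("duration too short for one bout at the requested rate",
                          stacklevel=2)

    loco = (velocity > 0).astype(float)
    arousal = _arousal_filter(loco, fr, config.pupil_rise_tau_s, config.pupil_decay_tau_s)
    pupil = (config.pupil_baseline_px + config.pupil_gain_px * arousal
             + config.pupil_noise_sd_px * rng.standard_normal(n))
    whisk_env = np.convolve(loco, _gauss_kernel(fr, sigma_s=1.5), mode="same")
    whisk = 0.5 + 3.0 * np.clip(whisk_env, 0, 1) + np.abs(0.2 * rng.standard_normal(n))
    behavior = BehaviorTrace(wheel_velocity=velocity, pupil_diameter=pupil,
                             whisk_speed=whisk, frame_rate=fr)
    return behavior, bouts


def _bout_profile(n_frames: int, fr: float, rng: np.random.Generator) -> np.ndarray:
    """Rectangular-ish speed profile with raised-cosine edges, min 30% of peak."""
    ramp = min(int(round(0.25 * fr)), max(1, n_frames // 4))
    prof = np.ones(n_frames)
    edge = 0.3 + 0.7 * 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
    prof[:ramp] = edge
    prof[-ramp:] = edge[::-1]
    prof *= 1.0 + 0.05 * rng.standard_normal(n_frames)
    return np.clip(prof, 0.25, None)


def _arousal_filter(drive: np.ndarray, fr: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Asymmetric first-order response: fast rise toward the drive, exponential
    decay with ``tau_decay`` when the drive falls away."""
    dt = 1.0 / fr
    a = np.zeros_like(drive)
    x = 0.0
    for i, u in enumerate(drive):
        tau = tau_rise if u > x else tau_decay
        x += dt * (u - x) / tau
        a[i] = x
    return a


def _gauss_kernel(fr: float, sigma_s: float) -> np.ndarray:
    half = int(round(4 * sigma_s * fr))
    t = np.arange(-half, half + 1) / fr
    k = np.exp(-0.5 * (t / sigma_s) ** 2)
    return k / k.sum()


def make_parcel_geometry(config: SimConfig) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Rectangular parcels per hemisphere with a 2-pixel midline gap.

    Returns (label image with 0 = gap, bilateral pairs (left, right), boolean
    anterior flag per parcel id − 1). Left parcels are 1..n, right n+1..2n;
    the right labels are the exact mirror of the left, so pair i ↔ i + n.
    """
    rows, cols = config.image_shape
    n = config.n_parcels_per_hemisphere
    width = (cols - 2) // 2
    if width < 1 or rows < 1:
        raise ValueError("image too small for two hemispheres and a midline gap")
    nr, nc = _tile_grid(n, rows, width)
    row_edges = np.linspace(0, rows, nr + 1).astype(int)
    col_edges = np.linspace(0, width, nc + 1).astype(int)
    left = np.zeros((rows, width), dtype=int)
    for i in range(nr):
        for j in range(nc):
            left[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = i * nc + j + 1
    labels = np.zeros((rows, cols), dtype=int)
    labels[:, :width] = left
    labels[:, cols - width:] = np.where(left[:, ::-1] > 0, left[:, ::-1] + n, 0)
    pairs = [(i + 1, i + 1 + n) for i in range(n)]
    centroid_row = np.array([np.mean(np.nonzero(left == i + 1)[0]) for i in range(n)])
    anterior_left = centroid_row < rows / 2.0
    anterior = np.concatenate([anterior_left, anterior_left])
    return labels, pairs, anterior


def _tile_grid(n: int, rows: int, width: int) -> tuple[int, int]:
    target = np.log(rows / width)
    best = (n, 1)
    best_cost = np.inf
    for nr in range(1, n + 1):
        if n % nr:
            continue
        nc = n // nr
        if nr > rows or nc > width:
            continue
        cost = abs(np.log(nr / nc) - target)
        if cost < best_cost:
            best, best_cost = (nr, nc), cost
    return best


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...],
                band: tuple[float, float], fr: float) -> np.ndarray:
    """Unit-variance Gaussian noise ideally band-limited to ``band``."""
    x = fft_bandpass(rng.standard_normal(shape), band, fr)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd < 1e-14, 1.0, sd)


def hrf_kernel(config: SimConfig) -> tuple[np.ndarray, float]:
    """Gamma HRF delayed by ``hrf_lag_s``; returns (unit-area kernel, analytic
    peak time = lag + (shape − 1)·scale)."""
    fr = config.frame_rate
    t = np.arange(0, int(round((config.hrf_lag_s + 8 * config.hrf_scale_s * config.hrf_shape)
                                * fr))) / fr
    k = gamma_dist.pdf(t - config.hrf_lag_s, a=config.hrf_shape, scale=config.hrf_scale_s)
    k /= k.sum()
    mode = config.hrf_lag_s + max(config.hrf_shape - 1.0, 0.0) * config.hrf_scale_s
    return k, mode


def simulate_cortex(config: SimConfig, behavior: BehaviorTrace) -> GroundTruth:
    """Parcel-structured neural pixel dynamics plus coupled hemodynamics."""
    if behavior.n_frames != config.n_frames:
        raise ValueError("behavior length does not match config duration")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fr = config.frame_rate
    n_frames = config.n_frames
    labels, pairs, anterior = make_parcel_geometry(config)
    n = config.n_parcels_per_hemisphere
    n_parcels = 2 * n
    band = config.rest_fluctuation_band

    # latent sources: per-pair shared, per-parcel independent, one global, and
    # locomotion-time sources (one shared across cortex, one per parcel)
    s_pair = _band_noise(rng, (n, n_frames), band, fr)
    e_ind = _band_noise(rng, (n_parcels, n_frames), band, fr)
    g_src = _band_noise(rng, (n_frames,), band, fr)
    u_loco = _band_noise(rng, (n_frames,), band, fr)
    pair_loco = _band_noise(rng, (n, n_frames), band, fr)
    e_loco = _band_noise(rng, (n_parcels, n_frames), band, fr)

    loco = (behavior.wheel_velocity > 0).astype(float)
    loco_smooth = np.clip(
        np.convolve(loco, _gauss_kernel(fr, sigma_s=0.5), mode="same"), 0.0, 1.0)

    # bilateral coupling of the rest fluctuations is itself state-dependent:
    # strong in quiet rest (anterior pairs most of all), largely lost during
    # running, when hemispheres fluctuate more independently
    r_pair = np.where(anterior[:n], config.bilateral_r, config.posterior_bilateral_r)
    rest = np.empty((n_parcels, n_frames))
    for j in range(n):
        r_eff = r_pair[j] * (1.0 - config.loco_desync * loco_smooth)
        shared = np.sqrt(r_eff) * s_pair[j]
        rest[j] = shared + np.sqrt(1.0 - r_eff) * e_ind[j]
        rest[j + n] = shared + np.sqrt(1.0 - r_eff) * e_ind[j + n]
    envelope = 1.0 - (1.0 - config.locomotion_suppression_factor) * loco_smooth
    arousal = np.clip(
        (behavior.pupil_diameter - config.pupil_baseline_px) / config.pupil_gain_px, 0.0, 1.2
    )
    # arousal modulates a cortex-wide shared component, but only outside
    # locomotion: this is what separates initial rest (high arousal, stronger
    # anterior-posterior coupling) from sustained rest (low arousal)
    w_g = (config.global_coupling_low
           + (config.global_coupling_high - config.global_coupling_low)
           * np.clip(arousal, 0, 1)) * (1.0 - loco_smooth)

    # anterior rest fluctuations are largest in quiet (low-arousal) rest — the
    # fine anterior structure the parcellation relies on is a quiet-rest feature
    amp = np.where(anterior, config.rest_fluct_gain_anterior, 1.0)[:, None] * (
        1.0 - config.arousal_amp_drop * np.clip(arousal, 0, 1)[None, :]
        * np.where(anterior, 1.0, 0.0)[:, None])
    # locomotion-locked activation: strong in posterior sensory parcels, weak
    # motor-related in anterior ones. A weak cortex-wide running fluctuation
    # raises anterior-posterior coupling during bouts; a pair-shared term keeps
    # sensory activation bilaterally symmetric; per-parcel terms decorrelate
    # the rest
    loco_gain = np.where(anterior, 0.35 * config.sensory_drive_gain,
                         config.sensory_drive_gain)
    pair_full = np.vstack([pair_loco, pair_loco]) * np.where(anterior, 0.0, 1.0)[:, None]
    loco_mod = loco_smooth[None, :] * loco_gain[:, None] * (
        1.0 + 0.35 * u_loco[None, :] + 0.8 * pair_full + 0.5 * e_loco)

    latents = (amp * envelope[None, :] * rest
               + w_g[None, :] * g_src[None, :]
               + loco_mod)

    # neural pixels: parcel latent + independent pixel noise, positive F ratio
    flat = labels.ravel()
    parcel_of_pixel = flat - 1  # -1 = gap
    n_pixels = flat.size
    true_F = np.ones((n_pixels, n_frames))
    in_parcel = parcel_of_pixel >= 0
    true_F[in_parcel] += config.fluct_amp * latents[parcel_of_pixel[in_parcel]]
    true_F += config.pixel_noise_sd * rng.standard_normal((n_pixels, n_frames))
    np.clip(true_F, 0.05, None, out=true_F)

    # hemodynamics: gamma-HRF convolution of the neural latents (lagged), plus
    # heart/breath components, gated off during the leading baseline window
    kernel, _ = hrf_kernel(config)
    if config.hemo_from_neural:
        hemo_drive = latents
    else:
        # vascular fluctuations decoupled from the neural signal (used to
        # exercise the pathlength-ratio estimator, whose objective assumes
        # residual neural/hemodynamic correlation is cross-talk)
        hemo_drive = _band_noise(rng, (n_parcels, n_frames), (0.05, 1.0), fr) * 1.5
    hbt_parcel = config.hrf_amplitude_uM * np.apply_along_axis(
        lambda x: np.convolve(x, kernel)[:n_frames], 1, hemo_drive)
    # oxygenation varies partly independently of blood volume; without this the
    # green and red attenuations are collinear and (Pg, Pr) is unidentifiable
    oxy_indep = 0.25 * config.hrf_amplitude_uM * _band_noise(
        rng, (n_parcels, n_frames), (0.05, 1.0), fr)
    t = np.arange(n_frames) / fr
    phase = rng.uniform(0, 2 * np.pi, size=(2, n_parcels))
    heart = config.artifact_amp_uM * np.sin(
        2 * np.pi * config.artifact_heart_hz * t[None, :] + phase[0][:, None])
    breath = config.artifact_amp_uM * np.sin(
        2 * np.pi * config.artifact_breath_hz * t[None, :] + phase[1][:, None])
    hbo_parcel = 1.4 * hbt_parcel + 0.6 * (heart + breath) + oxy_indep
    hbr_parcel = -0.4 * hbt_parcel + 0.4 * (heart + breath) - oxy_indep

    gate = _baseline_gate(config)
    true_hbo = np.zeros((n_pixels, n_frames))
    true_hbr = np.zeros((n_pixels, n_frames))
    true_hbo[in_parcel] = hbo_parcel[parcel_of_pixel[in_parcel]]
    true_hbr[in_parcel] = hbr_parcel[parcel_of_pixel[in_parcel]]
    true_hbo += config.hemo_noise_sd_uM * rng.standard_normal((n_pixels, n_frames))
    true_hbr += config.hemo_noise_sd_uM * rng.standard_normal((n_pixels, n_frames))
    true_hbo *= gate[None, :]
    true_hbr *= gate[None, :]

    bouts = states_mod.detect_bouts(behavior.wheel_velocity, fr)
    windows = states_mod.extract_state_windows(bouts, fr, n_frames=n_frames)
    schedule = _build_schedule(bouts, windows, n_frames, fr)

    return GroundTruth(
        parcel_labels=labels,
        bilateral_pairs=pairs,
        state_schedule=schedule,
        state_windows=windows,
        parcel_timecourses=latents,
        anterior=anterior,
        arousal=arousal,
        true_F=true_F,
        true_hbo=true_hbo,
        true_hbr=true_hbr,
        true_Pg=0.25,
        true_Pr=1.4,
        frame_rate=fr,
    )


def _baseline_gate(config: SimConfig) -> np.ndarray:
    """0 during the leading baseline window, cosine ramp to 1 over 3 s."""
    n = config.n_frames
    n0 = int(round(config.baseline_s * config.frame_rate))
    ramp = int(round(3.0 * config.frame_rate))
    gate = np.ones(n)
    gate[:n0] = 0.0
    stop = min(n0 + ramp, n)
    gate[n0:stop] = 0.5 * (1 - np.cos(np.pi * np.arange(stop - n0) / ramp))
    return gate


def _build_schedule(bouts, windows, n_frames: int, fr: float) -> np.ndarray:
    half = int(round(5.0 * fr))
    sched = np.zeros(n_frames, dtype=np.int8)
    for b in bouts:
        sched[b.onset_frame + half : max(b.onset_frame + half, b.offset_frame - half)] = \
            STATE_CODES["locomotion"]
    for s, e in windows["onset"]:
        sched[s:e] = STATE_CODES["onset"]
    for s, e in windows["offset"]:
        sched[s : s + half] = STATE_CODES["offset"]  # [off−5 s, off); initial rest owns [off, …)
    for s, e in windows["initial_rest"]:
        sched[s:e] = STATE_CODES["initial_rest"]
    for s, e in windows["sustained_rest"]:
        sched[s:e] = STATE_CODES["sustained_rest"]
    return sched


def render_raw(truth: GroundTruth, optics: OpticalModel, config: SimConfig,
               behavior: BehaviorTrace | None = None) -> RawSession:
    """Beer-Lambert forward rendering of truth into raw optical channels.

    Reflectance channels come from true hemoglobin via the exponential forward
    model; raw fluorescence is baseline × F-ratio × the green/red attenuations
    raised to the true pathlength ratios. A spatially uneven (but temporally
    constant) illumination field multiplies every channel; baseline
    normalization cancels it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    green_att, red_att = beer_lambert_forward(truth.true_hbo, truth.true_hbr, optics)
    if not (np.all(np.isfinite(green_att)) and np.all(np.isfinite(red_att))):
        bad = np.argwhere(~np.isfinite(green_att) | ~np.isfinite(red_att))[0]
        raise ValueError(f"non-finite attenuation at pixel {bad[0]}, frame {bad[1]}")
    n_pixels = truth.true_F.shape[0]
    illum = 1.0 + 0.2 * rng.random(n_pixels)
    fluor = (1000.0 * illum[:, None] * truth.true_F
             * green_att ** truth.true_Pg * red_att ** truth.true_Pr)
    green = 800.0 * illum[:, None] * green_att
    red = 900.0 * illum[:, None] * red_att
    if behavior is None:
        # the session must carry its behavior; rebuild deterministically
        behavior, _ = simulate_behavior(config)
    return RawSession(
        fluor_raw=fluor, green_raw=green, red_raw=red,
        frame_rate=config.frame_rate, behavior=behavior,
        image_shape=config.image_shape,
        baseline_window=(0, min(100, fluor.shape[1])),
    )


def simulate_session(config: SimConfig, optics: OpticalModel | None = None
                     ) -> tuple[RawSession, GroundTruth]:
    """Behavior → cortex → raw optics, all from one seed."""
    if optics is None:
        optics = OpticalModel()
    behavior, _ = simulate_behavior(config)
    truth = simulate_cortex(config, behavior)
    raw = render_raw(truth, optics, config, behavior=behavior)
    return raw, truth


def save_session_hdf5(path, raw: RawSession, truth: GroundTruth, config: SimConfig) -> None:
    """Write RawSession + GroundTruth to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fluor_raw", data=raw.fluor_raw)
        f.create_dataset("green_raw", data=raw.green_raw)
        f.create_dataset("red_raw", data=raw.red_raw)
        tr = f.create_group("truth")
        tr.create_dataset("parcel_labels", data=truth.parcel_labels)
        tr.create_dataset("state_schedule", data=truth.state_schedule)
        tr.create_dataset("true_F", data=truth.true_F)
        tr.create_dataset("true_hbo", data=truth.true_hbo)
        tr.create_dataset("true_hbr", data=truth.true_hbr)
        tr.create_dataset("arousal", data=truth.arousal)
        tr.attrs["true_Pg"] = truth.true_Pg
        tr.attrs["true_Pr"] = truth.true_Pr
        tr.attrs["bilateral_pairs"] = np.array(truth.bilateral_pairs)
        beh = f.create_group("behavior")
        beh.create_dataset("wheel_velocity", data=raw.behavior.wheel_velocity)
        beh.create_dataset("pupil_diameter", data=raw.behavior.pupil_diameter)
        beh.create_dataset("whisk_speed", data=raw.behavior.whisk_speed)
        f.attrs["frame_rate"] = config.frame_rate
        f.attrs["seed"] = config.seed
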
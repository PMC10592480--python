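"""Shared session definition for the analysis drivers.

One reference 10-minute synthetic session (20 frames/s, 24×24 pixels,
8 parcels per hemisphere) is used across the numbered analyses; every driver
regenerates it deterministically from the same seed so the scripts can be run
independently and in any order.
"""

from pathlib import Path

from corticostate import spectroscopy, synthetic_data as sd
from corticostate.preprocess import FilterSpec, zero_phase_filter

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 7


def reference_config() -> sd.SimConfig:
    return sd.SimConfig(duration_s=600.0, image_shape=(24, 24),
                        n_parcels_per_hemisphere=8, seed=SEED)


def reference_session():
    cfg = reference_config()
    raw, truth = sd.simulate_session(cfg)
    return cfg, raw, truth


def corrected_neural_stack(raw, truth):
    """Baseline-normalize, correct for hemoglobin absorption, low-pass 6.5 Hz."""
    fluor_n, green_n, red_n = spectroscopy.normalize_by_baseline(raw)
    dff = spectroscopy.correct_fluorescence(
        fluor_n, green_n, red_n, truth.true_Pg, truth.true_Pr).dff
    return zero_phase_filter(dff, FilterSpec("lowpass", (6.5,)), raw.frame_rate)


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
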
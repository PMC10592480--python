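"""Generate the reference synthetic session and summarize its behavior.

Writes the behavioral traces to results/behavior.csv, the full raw session +
ground truth to scratch/session.h5 (binary, regenerable), and a session
summary (bout count, rest-epoch count, qualifying state windows) to
results/session_summary.json.
"""

import json

from corticostate import states, synthetic_data as sd
from common import RESULTS, SCRATCH, ensure_dirs, reference_session


def main():
    ensure_dirs()
    cfg, raw, truth = reference_session()
    raw.behavior.to_csv(RESULTS / "behavior.csv")
    sd.save_session_hdf5(SCRATCH / "session.h5", raw, truth, cfg)

    bouts = states.detect_bouts(raw.behavior.wheel_velocity, cfg.frame_rate)
    epochs = states.find_rest_epochs(raw.behavior.wheel_velocity, cfg.frame_rate)
    summary = {
        "duration_s": cfg.duration_s,
        "frame_rate_hz": cfg.frame_rate,
        "n_parcels": 2 * cfg.n_parcels_per_hemisphere,
        "n_bouts": len(bouts),
        "bout_durations_s": [round(b.duration_s, 1) for b in bouts],
        "n_rest_epochs_ge_60s": len(epochs),
        "state_window_counts": {k: len(v) for k, v in truth.state_windows.items()},
    }
    (RESULTS / "session_summary.json").write_text(json.dumps(summary, indent=1))
    print("simulated session:", json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
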
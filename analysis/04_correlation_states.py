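"""Moving-window correlation maps and the NNLS behavioral-state decomposition.

Extracts ROI time courses with the planted parcellation, computes 10-s
moving-window correlation maps, builds the five behavioral correlation states
from locomotion bouts, fits every windowed map by cross-validated NNLS, and
scores the state labels against the generator's schedule. Writes the
coefficient time series and onset/offset-aligned averages.
"""

import json

import numpy as np
import pandas as pd

from corticostate import dynamics as dyn, preprocess as pp, states, synthetic_data as sd
from corticostate.parcellation import ParcellationMap
from common import RESULTS, ensure_dirs, reference_session, corrected_neural_stack


def main():
    ensure_dirs()
    cfg, raw, truth = reference_session()
    stack = corrected_neural_stack(raw, truth)
    pmap = ParcellationMap(labels=truth.parcel_labels,
                           n_rois=2 * cfg.n_parcels_per_hemisphere,
                           pairs=truth.bilateral_pairs)
    roi = pp.extract_roi_timecourses(stack, pmap, cfg.frame_rate)

    series = dyn.windowed_correlation(roi, window_s=10.0, step_frames=5)
    bouts = states.detect_bouts(raw.behavior.wheel_velocity, cfg.frame_rate)
    windows = states.extract_state_windows(bouts, cfg.frame_rate, n_frames=raw.n_frames)
    starts = np.array(sorted({s for ws in windows.values() for s, _ in ws}))
    series = dyn.merge_series(
        series, dyn.windowed_correlation(roi, window_s=10.0, starts=starts))
    fit = states.fit_states_nnls(series, bouts=bouts, cv_folds=5, windows=windows)
    fit.to_csv(RESULTS / "state_fit.csv")

    # score argmax state labels on windows fully inside one scheduled state
    sched = truth.state_schedule
    w = series.window_frames
    correct = total = 0
    for i, s in enumerate(series.starts):
        seg = sched[s:s + w]
        if seg[0] == 0 or not np.all(seg == seg[0]):
            continue
        total += 1
        correct += (np.argmax(fit.coefficients[:, i]) + 1 == seg[0])

    rows = []
    for mode in ("onset", "offset"):
        aligned = states.align_coefficients(fit, bouts, mode=mode, span_s=30.0)
        for k, name in enumerate(states.STATE_NAMES):
            for t, m, sem in zip(aligned["time"], aligned["mean"][k], aligned["sem"][k]):
                rows.append({"mode": mode, "state": name, "time_s": t,
                             "mean": m, "sem": sem})
    pd.DataFrame(rows).to_csv(RESULTS / "aligned_coefficients.csv", index=False)

    summary = {
        "n_windows": int(len(series.starts)),
        "mean_fit_residual": float(fit.residual.mean()),
        "state_label_accuracy": round(correct / max(total, 1), 4),
        "n_unambiguous_windows": total,
    }
    (RESULTS / "state_fit_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
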
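"""Rest-state reciprocity and arousal (pupil) associations.

Over rest epochs of at least 60 s: the Pearson correlation between the
initial-rest and sustained-rest NNLS coefficients (reciprocity), the
correlations of each coefficient with pupil diameter, their Epanechnikov
kernel densities, a two-sample KS comparison, and the Bonferroni-corrected
rank-sum comparison of initial- vs sustained-rest correlation maps.
"""

import json

import numpy as np
import pandas as pd

from corticostate import dynamics as dyn, preprocess as pp, states, stats as cstats
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

    epochs = states.find_rest_epochs(raw.behavior.wheel_velocity, cfg.frame_rate)
    reciprocity = states.rest_reciprocity(fit, epochs)
    assoc = states.arousal_association(fit, raw.behavior.pupil_diameter, epochs)

    kde_rows = []
    for state in ("initial_rest", "sustained_rest"):
        grid, dens = assoc[f"kde_{state}"]
        kde_rows += [{"state": state, "r": g, "density": d}
                     for g, d in zip(grid, dens)]
    pd.DataFrame(kde_rows).to_csv(RESULTS / "pupil_r_kde.csv", index=False)

    # initial-rest vs sustained-rest map comparison (rank-sum, Bonferroni)
    def maps_for(state):
        return np.stack([series.map_at_start(s) for s, _ in windows[state]])
    comparison = cstats.ranksum_map_compare(maps_for("initial_rest"),
                                            maps_for("sustained_rest"))

    summary = {
        "n_rest_epochs": len(epochs),
        "reciprocity_r_per_epoch": [round(float(r), 3) for r in reciprocity],
        "reciprocity_mean_r": round(float(np.mean(reciprocity)), 3),
        "mean_r_pupil_initial_rest": round(float(np.mean(assoc["r_initial_rest"])), 3),
        "mean_r_pupil_sustained_rest": round(float(np.mean(assoc["r_sustained_rest"])), 3),
        "ks_statistic": round(float(assoc["ks_statistic"]), 3),
        "ks_p": float(assoc["ks_p"]),
        "n_significant_map_entries": int(comparison.significant_mask.sum() // 2),
    }
    (RESULTS / "rest_arousal_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
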
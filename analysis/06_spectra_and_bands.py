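"""Windowed SD, rest/locomotion spectra, and band-resolved correlation maps.

Quantifies the dynamic signatures of the behavioral states: the 2-s trailing
SD of anterior neural signals (rest vs locomotion), Welch power spectra for
rest vs locomotion segments, correlation maps recomputed in separate frequency
bands, and the Euclidean distances between band maps relative to the slowest
band. Writes results/dynamics_summary.json and results/band_distances.csv.
"""

import json

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from corticostate import dynamics as dyn, preprocess as pp, synthetic_data as sd
from corticostate.parcellation import ParcellationMap
from common import RESULTS, ensure_dirs, reference_session, corrected_neural_stack

BANDS = [(0.02, 0.25), (0.25, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 6.0)]


def main():
    ensure_dirs()
    cfg, raw, truth = reference_session()
    stack = corrected_neural_stack(raw, truth)
    pmap = ParcellationMap(labels=truth.parcel_labels,
                           n_rois=2 * cfg.n_parcels_per_hemisphere,
                           pairs=truth.bilateral_pairs)
    roi = pp.extract_roi_timecourses(stack, pmap, cfg.frame_rate)
    sched = truth.state_schedule
    rest = sched == sd.STATE_CODES["sustained_rest"]
    loco = sched == sd.STATE_CODES["locomotion"]
    ant = np.flatnonzero(truth.anterior)

    # 2-s trailing SD, anterior parcels, rest vs locomotion
    sdser = dyn.windowed_sd(roi, window_s=2.0, causal=True)
    sd_rest = np.nanmean(sdser[np.ix_(ant, rest)], axis=0)
    sd_loco = np.nanmean(sdser[np.ix_(ant, loco)], axis=0)
    sd_rest, sd_loco = sd_rest[~np.isnan(sd_rest)], sd_loco[~np.isnan(sd_loco)]
    sd_test = ranksums(sd_rest[::20], sd_loco[::20])

    # Welch spectra, anterior ROI, rest vs locomotion segments
    def psd_for(selector):
        seg = pp.RoiMatrix(values=roi.values[:, selector], roi_ids=roi.roi_ids,
                           frame_rate=cfg.frame_rate)
        return dyn.band_power(seg, method="welch_psd",
                              bands=[(0.1, 1.0), (1.0, 3.0), (3.0, 6.0)])
    psd_rest, psd_loco = psd_for(rest), psd_for(loco)
    band_power_ratio = {
        f"{lo}-{hi}Hz": float(np.mean([psd_rest["band_means"][(lo, hi)][a]
                                       / psd_loco["band_means"][(lo, hi)][a]
                                       for a in ant]))
        for (lo, hi) in [(0.1, 1.0), (1.0, 3.0), (3.0, 6.0)]
    }

    # band-resolved rest correlation maps and distances to the slowest band
    rest_roi = pp.RoiMatrix(values=roi.values[:, rest], roi_ids=roi.roi_ids,
                            frame_rate=cfg.frame_rate)
    band_maps = dyn.band_filtered_maps(rest_roi, BANDS)
    ref = band_maps[BANDS[0]]
    rows = [{"band": f"{lo}-{hi}", "euclidean_to_lowest": dyn.map_distance(band_maps[(lo, hi)], ref),
             "correlation_to_lowest": dyn.map_distance(band_maps[(lo, hi)], ref, "correlation")}
            for lo, hi in BANDS]
    pd.DataFrame(rows).to_csv(RESULTS / "band_distances.csv", index=False)

    summary = {
        "anterior_sd_median_rest": round(float(np.median(sd_rest)), 4),
        "anterior_sd_median_locomotion": round(float(np.median(sd_loco)), 4),
        "sd_ranksum_p": float(sd_test.pvalue),
        "anterior_band_power_rest_over_locomotion": band_power_ratio,
        "cross_band_map_correlation_4to6_vs_0.02to0.25": round(
            float(dyn.map_distance(band_maps[(4.0, 6.0)], ref, "correlation")), 3),
    }
    (RESULTS / "dynamics_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
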
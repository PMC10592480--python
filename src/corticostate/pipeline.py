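"""End-to-end pipeline orchestration and a thin command-line wrapper.

``run_pipeline`` executes the stages in order on a (usually synthetic) session:

    simulate -> convert/correct -> preprocess -> parcellate -> correlate
             -> fit-states -> stats

Each stage writes its artifacts under the output directory together with the
resolved configuration (JSON, with the config hash and seed), so a rerun with
an identical config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from corticostate import dynamics, parcellation, preprocess, spectroscopy, states, synthetic_data
from corticostate.preprocess import FilterSpec, RoiMatrix

log = logging.getLogger("corticostate")

STAGES = ("simulate", "convert", "preprocess", "parcellate", "correlate", "fit-states", "stats")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for a full run."""

    sim: synthetic_data.SimConfig = dataclasses.field(default_factory=synthetic_data.SimConfig)
    signal: str = "neural_dff"  # neural_dff | hbt | hbo | hbr
    neural_lowpass_hz: float = 6.5
    hemo_lowpass_hz: float = 0.25
    filter_order: int = 20
    filter_ripple_db: float = 0.2
    lag_s: float = 1.5
    window_s: float = 10.0
    step_frames: int = 5
    k_per_hemisphere: int | None = None  # default: the generator's parcel count
    replicates: int = 10
    cv_folds: int = 5
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["image_shape"] = list(d["sim"]["image_shape"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns in-memory artifacts.

    Stages consume the in-memory results of upstream stages; requesting a
    stage whose inputs were not produced raises a ``ValueError`` naming the
    missing producer.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    art: dict = {"config": config}
    stamp = {"config": config.resolved(), "config_hash": config.config_hash(),
             "seed": config.seed, "stages": list(stages)}
    (out / "resolved_config.json").write_text(json.dumps(stamp, indent=1, default=str))

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        _STAGE_FN[stage](config, art, out)
        log.info("stage %-10s %.1fs", stage, time.time() - t0)
    return art


def _need(art: dict, key: str, producer: str) -> None:
    if key not in art:
        raise ValueError(f"missing upstream artifact {key!r}; run stage {producer!r} first")


def _stage_simulate(cfg: PipelineConfig, art: dict, out: Path) -> None:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    raw, truth = synthetic_data.simulate_session(sim)
    art["raw"], art["truth"] = raw, truth
    raw.behavior.to_csv(out / "behavior.csv")


def _stage_convert(cfg: PipelineConfig, art: dict, out: Path) -> None:
    _need(art, "raw", "simulate")
    raw = art["raw"]
    optics = spectroscopy.OpticalModel()
    fluor_n, green_n, red_n = spectroscopy.normalize_by_baseline(raw)
    art["hemo"] = spectroscopy.convert_hemoglobin(green_n, red_n, optics, raw.frame_rate)
    art["fluor"] = spectroscopy.correct_fluorescence(
        fluor_n, green_n, red_n, optics.Pg, optics.Pr, raw.frame_rate)


def _stage_preprocess(cfg: PipelineConfig, art: dict, out: Path) -> None:
    _need(art, "fluor", "convert")
    fr = art["raw"].frame_rate
    lp = FilterSpec("lowpass", (cfg.neural_lowpass_hz,), cfg.filter_order, cfg.filter_ripple_db)
    art["neural_stack"] = preprocess.zero_phase_filter(art["fluor"].dff, lp, fr)
    hemo_lp = FilterSpec("lowpass", (cfg.hemo_lowpass_hz,), cfg.filter_order, cfg.filter_ripple_db)
    art["hbt_stack"] = preprocess.zero_phase_filter(art["hemo"].d_hbt, hemo_lp, fr)


def _stage_parcellate(cfg: PipelineConfig, art: dict, out: Path) -> None:
    _need(art, "neural_stack", "preprocess")
    sim = art["config"].sim
    k = cfg.k_per_hemisphere or sim.n_parcels_per_hemisphere
    rows, cols = sim.image_shape
    width = (cols - 2) // 2
    pmap = parcellation.bilateral_parcellation(
        art["neural_stack"], sim.image_shape, k,
        midline_cols=(width, cols - width),
        replicates=cfg.replicates, seed=cfg.seed,
    )
    art["parcellation"] = pmap
    pmap.save(out / "parcel_labels.txt", out / "parcellation.json")


def _stage_correlate(cfg: PipelineConfig, art: dict, out: Path) -> None:
    _need(art, "parcellation", "parcellate")
    fr = art["raw"].frame_rate
    if cfg.signal == "neural_dff":
        stack, detrend = art["neural_stack"], False
    else:
        stack, detrend = art["hbt_stack"], True
        stack, (lo, hi) = preprocess.apply_lag(stack, -cfg.lag_s, fr)
    roi = preprocess.extract_roi_timecourses(stack, art["parcellation"], fr, cfg.signal)
    art["roi"] = roi
    art["corr_series"] = dynamics.windowed_correlation(
        roi, window_s=cfg.window_s, step_frames=cfg.step_frames, detrend=detrend)


def _stage_fit_states(cfg: PipelineConfig, art: dict, out: Path) -> None:
    _need(art, "corr_series", "correlate")
    raw = art["raw"]
    bouts = states.detect_bouts(raw.behavior.wheel_velocity, raw.frame_rate)
    windows = states.extract_state_windows(bouts, raw.frame_rate, n_frames=raw.n_frames)
    # state windows must exist in the map series: compute them explicitly
    starts = sorted({s for wins in windows.values() for s, _ in wins})
    extra = dynamics.windowed_correlation(
        art["roi"], window_s=cfg.window_s, starts=np.array(starts, dtype=int),
        detrend=cfg.signal != "neural_dff")
    merged = dynamics.merge_series(art["corr_series"], extra)
    fit = states.fit_states_nnls(merged, bouts=bouts, cv_folds=cfg.cv_folds, windows=windows)
    art["bouts"], art["windows"], art["fit"] = bouts, windows, fit
    fit.to_csv(out / "state_fit.csv")


def _stage_stats(cfg: PipelineConfig, art: dict, out: Path) -> None:
    _need(art, "fit", "fit-states")
    raw = art["raw"]
    epochs = states.find_rest_epochs(raw.behavior.wheel_velocity, raw.frame_rate)
    rec = states.rest_reciprocity(art["fit"], epochs)
    assoc = states.arousal_association(art["fit"], raw.behavior.pupil_diameter, epochs)
    summary = {
        "n_rest_epochs": len(epochs),
        "reciprocity_mean_r": float(np.mean(rec)) if len(rec) else None,
        "ks_statistic": assoc.get("ks_statistic"),
        "ks_p": assoc.get("ks_p"),
    }
    art["stats"] = summary
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=1))


_STAGE_FN = {
    "simulate": _stage_simulate,
    "convert": _stage_convert,
    "preprocess": _stage_preprocess,
    "parcellate": _stage_parcellate,
    "correlate": _stage_correlate,
    "fit-states": _stage_fit_states,
    "stats": _stage_stats,
}


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    sim_payload = payload.pop("sim", {})
    if "image_shape" in sim_payload:
        sim_payload["image_shape"] = tuple(sim_payload["image_shape"])
    return PipelineConfig(sim=synthetic_data.SimConfig(**sim_payload), **payload)


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(prog="corticostate",
                                     description="WFOM correlation-state pipeline")
    parser.add_argument("stages", nargs="*", default=list(STAGES),
                        help=f"stages to run, in order (default: all of {', '.join(STAGES)})")
    parser.add_argument("--config", help="YAML pipeline config")
    parser.add_argument("--out", default="pipeline_out", help="output directory")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--signal", choices=["neural_dff", "hbt"], default=None)
    args = parser.parse_args(argv)
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    try:
        if args.config:
            cfg = load_config(args.config)
        else:
            # compact demo geometry; full-scale runs supply a config file
            cfg = PipelineConfig(sim=synthetic_data.SimConfig(
                image_shape=(24, 24), n_parcels_per_hemisphere=8))
        if args.seed is not None:
            cfg.seed = args.seed
        if args.signal is not None:
            cfg.signal = args.signal
        requested = tuple(args.stages)
    except (ValueError, TypeError, OSError) as exc:
        parser.exit(2, f"config error: {exc}\n")
    try:
        run_pipeline(cfg, args.out, stages=requested)
    except ValueError as exc:
        parser.exit(3, f"data error: {exc}\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
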
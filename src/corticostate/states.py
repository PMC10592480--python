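"""Locomotion bouts, behavioral correlation states, and NNLS decomposition.

Five behavioral correlation states are defined from wheel-encoder locomotion
bouts; each is the average 10-s-window correlation map over windows meeting
that state's bout-duration and surrounding-rest criteria:

=================  ==========================================================
state              window & qualifying bouts
=================  ==========================================================
onset              [onset−5 s, onset+5 s); bouts ≥ 10 s with ≥ 60 s pre-rest
locomotion         middle 10 s of the bout; bouts ≥ 20 s
offset             [offset−5 s, offset+5 s); bouts ≥ 20 s with ≥ 10 s post-rest
initial_rest       [offset, offset+10 s); bouts ≥ 5 s with ≥ 60 s post-rest
sustained_rest     [offset+40 s, offset+50 s); same bouts as initial_rest
=================  ==========================================================

Every real-time 10-s-window correlation map d(t) is then modeled as a
nonnegative linear combination of the five state maps x_1..x_5,
``d(t) ≈ Σ_n c_n(t) x_n`` with c ≥ 0 (NNLS on strict-upper-triangle vectors),
and goodness of fit ``Σ(d − Σ c_n x_n)² / Σ d²``. Cross-validation partitions
bouts (not windows) into folds so a window is never fit against a basis its
own bout helped build.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from corticostate import stats as cstats
from corticostate.dynamics import CorrelationMapSeries, upper_triangle

STATE_NAMES = ("onset", "locomotion", "offset", "initial_rest", "sustained_rest")


@dataclass
class LocomotionBout:
    """Supra-threshold wheel-velocity episode, half-open [onset, offset)."""

    onset_frame: int
    offset_frame: int
    frame_rate: float
    pre_rest_s: float = np.inf
    post_rest_s: float = np.inf

    def __post_init__(self) -> None:
        if self.offset_frame <= self.onset_frame:
            raise ValueError("offset must follow onset")

    @property
    def duration_s(self) -> float:
        return (self.offset_frame - self.onset_frame) / self.frame_rate


@dataclass
class RestEpoch:
    """Continuous sub-threshold period of at least ``min_duration_s``."""

    start_frame: int
    end_frame: int
    frame_rate: float

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.frame_rate


@dataclass
class StateBasis:
    """Five state correlation maps in STATE_NAMES order."""

    maps: np.ndarray  # (5, r, r)
    n_windows_per_state: dict[str, int]
    source_windows: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def design_matrix(self) -> np.ndarray:
        """Upper-triangle basis vectors as columns, (n_entries, 5)."""
        return upper_triangle(self.maps).T


@dataclass
class StateFit:
    """Per-window NNLS coefficients (5 × time) and fit residuals."""

    coefficients: np.ndarray  # (5, n_windows), nonnegative
    residual: np.ndarray  # (n_windows,)
    centers: np.ndarray  # frame index of each window center
    frame_rate: float
    window_frames: int = 200

    def coefficient(self, state: str) -> np.ndarray:
        return self.coefficients[STATE_NAMES.index(state)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.coefficients.T, columns=list(STATE_NAMES))
        df.insert(0, "center_frame", self.centers)
        df["residual"] = self.residual
        df.to_csv(path, index=False)


def detect_bouts(
    wheel_velocity: np.ndarray,
    frame_rate: float,
    threshold: float | None = None,
    min_gap_s: float = 1.0,
) -> list[LocomotionBout]:
    """Locomotion bouts as supra-threshold runs with short gaps merged.

    ``threshold`` defaults to 5% of the 99th-percentile speed (the encoder
    criterion is "a predetermined level"; this adapts it per session). Runs
    separated by less than ``min_gap_s`` are merged. Pre/post rest durations
    are measured to neighboring bouts or the record edges.
    """
    v = np.abs(np.asarray(wheel_velocity, dtype=float))
    if threshold is None:
        p99 = np.percentile(v, 99)
        threshold = 0.05 * p99 if p99 > 0 else np.inf
    active = v > threshold
    if not active.any():
        return []
    edges = np.diff(active.astype(int))
    starts = (np.flatnonzero(edges == 1) + 1).tolist()
    stops = (np.flatnonzero(edges == -1) + 1).tolist()
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        stops.append(len(v))
    runs = list(zip(starts, stops))
    merged = [list(runs[0])]
    min_gap = int(round(min_gap_s * frame_rate))
    for s, e in runs[1:]:
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    bouts = []
    for i, (s, e) in enumerate(merged):
        pre = (s - (merged[i - 1][1] if i > 0 else 0)) / frame_rate
        post = ((merged[i + 1][0] if i < len(merged) - 1 else len(v)) - e) / frame_rate
        bouts.append(LocomotionBout(onset_frame=s, offset_frame=e, frame_rate=frame_rate,
                                    pre_rest_s=pre, post_rest_s=post))
    return bouts


def extract_state_windows(
    bouts: list[LocomotionBout],
    frame_rate: float,
    n_frames: int | None = None,
    window_s: float = 10.0,
) -> dict[str, list[tuple[int, int]]]:
    """Per-state 10-s window frame ranges satisfying the bout criteria.

    Returns ``state -> [(start, stop), ...]`` (half-open frame intervals). A
    bout may contribute to several states. Windows extending past the record
    (when ``n_frames`` is given) or before frame 0 are dropped.
    """
    w = int(round(window_s * frame_rate))
    half = w // 2
    out: dict[str, list[tuple[int, int]]] = {s: [] for s in STATE_NAMES}

    def add(state: str, start: int) -> None:
        if start < 0:
            return
        if n_frames is not None and start + w > n_frames:
            return
        out[state].append((start, start + w))

    for b in bouts:
        on, off = b.onset_frame, b.offset_frame
        if b.duration_s >= 10.0 and b.pre_rest_s >= 60.0:
            add("onset", on - half)
        if b.duration_s >= 20.0:
            mid = on + (off - on) // 2
            add("locomotion", mid - half)
        if b.duration_s >= 20.0 and b.post_rest_s >= 10.0:
            add("offset", off - half)
        if b.duration_s >= 5.0 and b.post_rest_s >= 60.0:
            add("initial_rest", off)
            add("sustained_rest", off + int(round(40.0 * frame_rate)))
    return out


def find_rest_epochs(
    wheel_velocity: np.ndarray,
    frame_rate: float,
    threshold: float | None = None,
    min_duration_s: float = 60.0,
    require_preceding_bout: bool = True,
) -> list[RestEpoch]:
    """Continuous sub-threshold periods of at least ``min_duration_s``.

    By default only periods that start at a locomotion offset count: the rest
    states are defined relative to locomotion cessation, so a session-leading
    rest segment with no prior bout carries no initial→sustained transition.
    """
    bouts = detect_bouts(wheel_velocity, frame_rate, threshold=threshold)
    n = len(wheel_velocity)
    bounds = [0] + [f for b in bouts for f in (b.onset_frame, b.offset_frame)] + [n]
    epochs = []
    for i, (s, e) in enumerate(zip(bounds[::2], bounds[1::2])):
        if require_preceding_bout and i == 0:
            continue
        if e > s:
            ep = RestEpoch(start_frame=s, end_frame=e, frame_rate=frame_rate)
            if ep.duration_s >= min_duration_s:
                epochs.append(ep)
    return epochs


def build_state_basis(
    corr_series: CorrelationMapSeries, windows: dict[str, list[tuple[int, int]]]
) -> StateBasis:
    """Elementwise mean correlation map per state over its windows."""
    maps = []
    counts = {}
    for state in STATE_NAMES:
        wins = windows.get(state, [])
        if not wins:
            raise ValueError(f"state {state!r} has no qualifying windows")
        state_maps = [corr_series.map_at_start(s) for s, _ in wins]
        maps.append(np.mean(state_maps, axis=0))
        counts[state] = len(wins)
    return StateBasis(maps=np.stack(maps), n_windows_per_state=counts,
                      source_windows={s: list(windows.get(s, [])) for s in STATE_NAMES})


def _nnls_fit(d: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Nonnegative LS of one upper-triangle vector onto basis columns.

    Residual is ``Σ(d − Xc)² / Σd²``; an all-zero map gets c = 0, residual 1.
    """
    denom = float(np.sum(d**2))
    if denom < 1e-30:
        return np.zeros(X.shape[1]), 1.0
    c, _ = nnls(X, d)
    resid = float(np.sum((d - X @ c) ** 2) / denom)
    return c, resid


def fit_states_nnls(
    corr_series: CorrelationMapSeries,
    basis: StateBasis | None = None,
    bouts: list[LocomotionBout] | None = None,
    cv_folds: int = 5,
    windows: dict[str, list[tuple[int, int]]] | None = None,
) -> StateFit:
    """NNLS decomposition of every windowed map onto the five state maps.

    Two modes:

    * ``basis`` given, ``cv_folds <= 1``: every map is fit against that basis.
    * ``bouts`` (and optionally precomputed ``windows``) given with
      ``cv_folds > 1``: bouts are partitioned round-robin into folds; each
      moving window is assigned the fold of the temporally nearest bout and is
      fit against a basis built from the other folds' state windows only.
    """
    d_all = upper_triangle(corr_series.maps)  # (n_windows, n_entries)
    n_win = d_all.shape[0]
    coef = np.zeros((len(STATE_NAMES), n_win))
    resid = np.zeros(n_win)

    if cv_folds <= 1 or bouts is None:
        if basis is None:
            raise ValueError("need a StateBasis when not cross-validating")
        X = basis.design_matrix()
        _check_independent(X)
        for i in range(n_win):
            coef[:, i], resid[i] = _nnls_fit(d_all[i], X)
        return StateFit(coefficients=coef, residual=resid, centers=corr_series.centers,
                        frame_rate=corr_series.frame_rate,
                        window_frames=corr_series.window_frames)

    if windows is None:
        windows = extract_state_windows(bouts, corr_series.frame_rate)
    fold_of_bout = np.arange(len(bouts)) % cv_folds
    bout_mid = np.array([(b.onset_frame + b.offset_frame) / 2 for b in bouts])
    # map each state window back to its source bout (the nearest one)
    win_fold: dict[tuple[int, int], int] = {}
    for state, wins in windows.items():
        for s, e in wins:
            centre = (s + e) / 2
            win_fold[(s, e)] = int(fold_of_bout[np.argmin(np.abs(bout_mid - centre))])
    centers = corr_series.centers
    window_fold = np.array(
        [int(fold_of_bout[np.argmin(np.abs(bout_mid - c))]) for c in centers]
    )
    for fold in range(cv_folds):
        train_windows = {
            state: [w for w in wins if win_fold[w] != fold]
            for state, wins in windows.items()
        }
        if any(len(v) == 0 for v in train_windows.values()):
            # a fold holding every window of some state: fall back to all windows
            warnings.warn("fold left a state without training windows; using all windows",
                          stacklevel=2)
            train_windows = windows
        fold_basis = build_state_basis(corr_series, train_windows)
        X = fold_basis.design_matrix()
        _check_independent(X)
        for i in np.flatnonzero(window_fold == fold):
            coef[:, i], resid[i] = _nnls_fit(d_all[i], X)
    return StateFit(coefficients=coef, residual=resid, centers=centers,
                    frame_rate=corr_series.frame_rate,
                    window_frames=corr_series.window_frames)


def _check_independent(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("basis maps are linearly dependent on the upper triangle")


def align_coefficients(
    fit: StateFit,
    bouts: list[LocomotionBout],
    mode: str = "onset",
    span_s: float = 30.0,
    grid_step_s: float = 0.5,
) -> dict:
    """Event-aligned mean ± SEM coefficient traces.

    Coefficient time courses are interpolated onto an event-relative grid
    (time 0 at the bout onset or offset frame) spanning ±``span_s`` and
    averaged across bouts. Returns {'time', 'mean', 'sem', 'n'} with mean/sem
    shaped (5, n_grid).
    """
    if mode not in ("onset", "offset"):
        raise ValueError("mode must be 'onset' or 'offset'")
    if not bouts:
        raise ValueError("need >= 1 bout")
    grid = np.arange(-span_s, span_s + 1e-9, grid_step_s)
    t = fit.centers / fit.frame_rate
    traces = []
    for b in bouts:
        ev = (b.onset_frame if mode == "onset" else b.offset_frame) / fit.frame_rate
        rel = t - ev
        if rel.min() > -span_s or rel.max() < span_s:
            continue  # bout too close to the record edge for the full span
        traces.append(np.stack([np.interp(grid, rel, fit.coefficients[k])
                                for k in range(len(STATE_NAMES))]))
    if not traces:
        raise ValueError("no bout admits the requested span")
    arr = np.stack(traces)  # (n_bouts, 5, n_grid)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros_like(mean)
    return {"time": grid, "mean": mean, "sem": sem, "n": arr.shape[0]}


def rest_reciprocity(fit: StateFit, rest_epochs: list[RestEpoch]) -> np.ndarray:
    """Pearson r between initial- and sustained-rest coefficients per epoch.

    Epochs shorter than 60 s are excluded; epochs where either coefficient is
    constant are skipped with a warning. Returns the per-epoch r values.
    """
    c4 = fit.coefficient("initial_rest")
    c5 = fit.coefficient("sustained_rest")
    rs = []
    for ep in rest_epochs:
        if ep.duration_s < 60.0:
            continue
        sel = (fit.centers >= ep.start_frame) & (fit.centers < ep.end_frame)
        if sel.sum() < 3:
            continue
        a, b = c4[sel], c5[sel]
        if a.std() < 1e-12 or b.std() < 1e-12:
            warnings.warn("constant coefficient in epoch; skipped", stacklevel=2)
            continue
        rs.append(pearsonr(a, b).statistic)
    return np.asarray(rs)


def arousal_association(
    fit: StateFit,
    pupil: np.ndarray,
    rest_epochs: list[RestEpoch],
) -> dict:
    """Pupil-coefficient correlations per rest state, their KDEs, and a KS test.

    For each rest epoch, the Pearson r between the pupil diameter (sampled at
    the fit's window centers) and each resting-state coefficient. Returns the
    two r distributions, their Epanechnikov KDEs, and the two-sample KS
    statistic/p comparing them.
    """
    pupil = np.asarray(pupil, dtype=float)
    # average the pupil over each coefficient's window, matching the 10-s
    # smoothing the correlation windows impose on the coefficients
    half = fit.window_frames // 2
    pupil_at_centers = np.array([
        np.nanmean(pupil[max(c - half, 0): c - half + fit.window_frames])
        for c in fit.centers
    ])
    out = {"r_initial_rest": [], "r_sustained_rest": []}
    for ep in rest_epochs:
        if ep.duration_s < 60.0:
            continue
        sel = (fit.centers >= ep.start_frame) & (fit.centers < ep.end_frame)
        if sel.sum() < 3:
            continue
        p = pupil_at_centers[sel]
        if p.std() < 1e-12:
            warnings.warn("constant pupil in epoch; skipped", stacklevel=2)
            continue
        for state, key in (("initial_rest", "r_initial_rest"),
                           ("sustained_rest", "r_sustained_rest")):
            c = fit.coefficient(state)[sel]
            if c.std() < 1e-12:
                continue
            out[key].append(pearsonr(c, p).statistic)
    r_init = np.asarray(out["r_initial_rest"])
    r_sust = np.asarray(out["r_sustained_rest"])
    result = {"r_initial_rest": r_init, "r_sustained_rest": r_sust}
    if len(r_init) >= 2 and len(r_sust) >= 2:
        result["kde_initial_rest"] = cstats.epanechnikov_kde(r_init)
        result["kde_sustained_rest"] = cstats.epanechnikov_kde(r_sust)
        k, p = cstats.ks_two_sample(r_init, r_sust)
        result["ks_statistic"] = k
        result["ks_p"] = p
    return result
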
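"""Summary statistics of nascent-transcription time traces.

Everything the inference and reporting layers need from a trace lives
here: autocorrelation statistics (decay half-life, lag-1 value), slope-
threshold burst segmentation, induction response times, time-integrated
RNA output, responder classification, the intrinsic/extrinsic noise
decomposition, and sister-allele output correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import median_filter

from .promoter_sim import SignalProfile, DEFAULT_PROFILE, TraceDataset

__all__ = [
    "AcfSummary",
    "BurstAnnotation",
    "NoiseDecomposition",
    "AlleleCorrelation",
    "autocorrelation",
    "acf_matrix",
    "acf_half_life",
    "extract_bursts",
    "response_time",
    "total_rna_output",
    "classify_responder",
    "noise_decomposition",
    "allele_output_correlation",
]


@dataclass
class AcfSummary:
    """Sample autocorrelation of one trace at lags ``0..max_lag``."""

    acf: np.ndarray  # acf[0] == 1
    half_life: float  # minutes; censored at max_lag * dt if never below 0.5
    lag1: float


@dataclass
class BurstAnnotation:
    """Alternating ON/OFF segmentation of a trace, in minutes."""

    on_intervals: list  # [(start, end), ...]
    off_intervals: list
    burst_sizes: np.ndarray  # RNA per ON interval
    initiation_rates: np.ndarray  # RNA/min per ON interval

    @property
    def on_durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.on_intervals])

    @property
    def off_durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.off_intervals])


@dataclass
class NoiseDecomposition:
    """Law-of-total-variance split of population variability."""

    cv2_total: float
    cv2_int: float
    cv2_ext: float
    mean_rna: float


@dataclass
class AlleleCorrelation:
    """Sister-allele total-output correlation with bootstrap uncertainty."""

    pcc: float
    boot_mean: float
    boot_sd: float
    per_cell_trace_pcc: np.ndarray  # within-cell per-timepoint PCCs
    outputs: np.ndarray  # (n_cells, 2) total RNA per allele


# ---------------------------------------------------------------------------
# autocorrelation


def acf_matrix(X: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample ACF (lag 0..max_lag) of each row of ``X`` via FFT.

    Rows with zero variance get the degenerate ACF [1, 0, 0, ...], the
    signature of a pure-background trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if n < 2:
        raise ValueError("traces must have at least 2 points")
    Xc = X - X.mean(axis=1, keepdims=True)
    nfft = sp_fft.next_fast_len(2 * n)
    F = sp_fft.rfft(Xc, nfft, axis=1)
    acov = sp_fft.irfft(F * np.conj(F), nfft, axis=1)[:, : max_lag + 1] / n
    var = acov[:, 0].copy()
    bad = var <= 0
    var[bad] = 1.0
    acf = acov / var[:, None]
    acf[bad] = 0.0
    acf[:, 0] = 1.0
    return acf


def acf_half_life(acf: np.ndarray, frame_interval: float) -> np.ndarray:
    """First lag (linearly interpolated, in minutes) where the ACF drops below 0.5.

    Censored at ``max_lag * frame_interval`` for traces that never decay
    below 0.5 within the computed lags.
    """
    A = np.atleast_2d(acf)
    n, L = A.shape[0], A.shape[1] - 1
    below = A[:, 1:] < 0.5
    first = np.argmax(below, axis=1)  # 0 if none True
    any_below = below.any(axis=1)
    lag = first + 1
    prev = A[np.arange(n), lag - 1]
    cur = A[np.arange(n), lag]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (prev - 0.5) / (prev - cur)
    hl = (lag - 1 + frac) * frame_interval
    hl[~any_below] = L * frame_interval
    return hl if acf.ndim == 2 else hl[0]


def autocorrelation(trace, max_lag: int = 50, frame_interval: float | None = None) -> AcfSummary:
    """Mean-subtracted, variance-normalized sample ACF of one trace.

    ``trace`` may be a CellTrace or a 1-D array (then ``frame_interval`` is
    required).  Raises on constant traces, whose ACF is undefined.
    """
    if hasattr(trace, "intensity"):
        values = np.asarray(trace.intensity, dtype=float)
        frame_interval = float(trace.times[1] - trace.times[0])
    else:
        values = np.asarray(trace, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for bare arrays")
    if len(values) < 2 * max_lag:
        raise ValueError(f"trace too short for max_lag={max_lag}")
    if np.var(values) == 0:
        raise ValueError("constant trace: autocorrelation undefined")
    acf = acf_matrix(values[None, :], max_lag)[0]
    hl = acf_half_life(acf[None, :], frame_interval)[0]
    return AcfSummary(acf=acf, half_life=float(hl), lag1=float(acf[1]))


# ---------------------------------------------------------------------------
# burst segmentation


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def extract_bursts(
    trace,
    frame_interval: float | None = None,
    slope_threshold: float = 0.65,
    threshold_interval: float = 3.0,
    median_window: int = 5,
    upsample: int = 10,
) -> BurstAnnotation:
    """Segment a trace into transcriptional ON and OFF periods.

    The trace is smoothed with a running median (window ``median_window``),
    the frame-to-frame slope is linearly upsampled ``upsample``-fold, and
    frames where the slope exceeds ``slope_threshold`` transcripts per
    ``threshold_interval`` minutes are called active.  Gaps and peaks
    shorter than one imaging interval are discarded.  Boundary periods at
    the start/end of the trace are kept, so non-responding cells report one
    long OFF interval.  Burst size per ON period is the rise of the
    smoothed intensity across it; the initiation rate is size/duration.
    """
    if hasattr(trace, "intensity"):
        values = np.asarray(trace.intensity, dtype=float)
        times = np.asarray(trace.times, dtype=float)
        frame_interval = float(times[1] - times[0])
    else:
        values = np.asarray(trace, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for bare arrays")
        times = np.arange(len(values)) * frame_interval
    if len(values) < median_window:
        raise ValueError("trace shorter than the median window")

    dt = frame_interval
    smooth = median_filter(values, size=median_window, mode="nearest")
    slope = np.diff(smooth) / dt  # RNA per minute, at frame midpoints
    t_mid = times[:-1] + dt / 2.0

    if len(slope) > 1:
        n_fine = (len(slope) - 1) * upsample + 1
        t_fine = np.linspace(t_mid[0], t_mid[-1], n_fine)
        s_fine = np.interp(t_fine, t_mid, slope)
    else:
        t_fine, s_fine = t_mid, slope
    fine_dt = t_fine[1] - t_fine[0] if len(t_fine) > 1 else dt

    thr = slope_threshold / threshold_interval  # RNA per minute
    active = s_fine > thr
    min_len = max(1, int(round(dt / fine_dt)))

    # discard OFF gaps shorter than one imaging interval, then short ON peaks
    for s, e in _runs(~active):
        if 0 < s and e < len(active) and (e - s) < min_len:
            active[s:e] = True
    for s, e in _runs(active):
        if (e - s) < min_len:
            active[s:e] = False

    t0, t1 = times[0], times[-1]
    on_iv, off_iv = [], []
    runs_on = _runs(active)
    if not runs_on:
        off_iv.append((t0, t1))
    else:
        bounds = []
        for s, e in runs_on:
            bounds.append((t_fine[s], t_fine[min(e, len(t_fine) - 1)]))
        # extend first/last interval to the trace edges
        prev_end = t0
        for i, (s, e) in enumerate(bounds):
            s_adj = t0 if i == 0 and s <= t_fine[0] + fine_dt and active[0] else s
            if s_adj > prev_end:
                off_iv.append((prev_end, s_adj))
            e_adj = t1 if i == len(bounds) - 1 and active[-1] else e
            on_iv.append((s_adj, e_adj))
            prev_end = e_adj
        if prev_end < t1:
            off_iv.append((prev_end, t1))

    sm_at = lambda t: float(np.interp(t, times, smooth))
    sizes = np.array([max(0.0, sm_at(e) - sm_at(s)) for s, e in on_iv])
    durs = np.array([e - s for s, e in on_iv])
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(durs > 0, sizes / np.where(durs > 0, durs, 1.0), 0.0)
    return BurstAnnotation(
        on_intervals=on_iv, off_intervals=off_iv, burst_sizes=sizes,
        initiation_rates=rates,
    )


# ---------------------------------------------------------------------------
# response time, output, responder


def response_time(
    trace,
    stimulus_min: float = 0.0,
    threshold: float = 2.0,
    median_window: int = 7,
    persistence: int = 5,
    frame_interval: float | None = None,
):
    """Time from stimulus until the trace stays above threshold, or None.

    The trace is median-filtered (window ``median_window``); the response
    time is the first post-stimulus frame from which the filtered signal
    exceeds ``threshold`` RNA for at least ``persistence`` consecutive
    frames.  Returns minutes after the stimulus, or None for non-responders.
    """
    if hasattr(trace, "intensity"):
        values = np.asarray(trace.intensity, dtype=float)
        times = np.asarray(trace.times, dtype=float)
    else:
        values = np.asarray(trace, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for bare arrays")
        times = np.arange(len(values)) * frame_interval
    filt = median_filter(values, size=median_window, mode="nearest")
    above = filt > threshold
    for s, e in _runs(above):
        if (e - s) >= persistence and times[s] >= stimulus_min:
            return float(times[s] - stimulus_min)
    return None


def total_rna_output(
    trace,
    profile: SignalProfile = DEFAULT_PROFILE,
    background: float = 0.0,
    frame_interval: float | None = None,
) -> float:
    """Total transcripts produced over the observation window (sigma-RNA).

    Area under the background-subtracted trace (floored at zero) divided by
    the integrated signal of a single transcript.
    """
    if profile.area <= 0:
        raise ValueError("unit profile has nonpositive area")
    if hasattr(trace, "intensity"):
        values = np.asarray(trace.intensity, dtype=float)
        times = np.asarray(trace.times, dtype=float)
    else:
        values = np.asarray(trace, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for bare arrays")
        times = np.arange(len(values)) * frame_interval
    auc = float(np.trapezoid(values - background, times))
    return max(0.0, auc) / profile.area


def classify_responder(acf: AcfSummary, lag1_threshold: float = 0.2) -> bool:
    """Responder if the lag-1 autocorrelation exceeds the threshold.

    A trace of pure measurement background is frame-to-frame independent,
    so its ACF collapses to zero at lag 1; real transcription persists over
    the ~30-min transcript residence and keeps the lag-1 ACF high.
    """
    return bool(acf.lag1 > lag1_threshold)


# ---------------------------------------------------------------------------
# noise decomposition


def noise_decomposition(
    dataset: TraceDataset | np.ndarray, background_variance: float = 0.0
) -> NoiseDecomposition:
    """Split population variability into intrinsic and extrinsic components.

    Extrinsic variance is the variance across cells of per-cell temporal
    means (stable cell-to-cell differences); intrinsic variance is the mean
    across cells of the per-cell temporal variances, corrected for the
    measurement-background variance (floored at zero).  Both are normalized
    by the squared grand mean; ``cv2_total`` is their sum by construction
    (law of total variance).
    """
    X = dataset.intensity if isinstance(dataset, TraceDataset) else np.asarray(dataset, float)
    X = np.atleast_2d(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 traces")
    M = float(X.mean())
    if M <= 0:
        raise ValueError("grand mean must be positive")
    cell_means = X.mean(axis=1)
    ext_var = float(cell_means.var())  # ddof=0: exact total-variance split
    int_var = float(X.var(axis=1).mean())
    int_var = max(0.0, int_var - background_variance)
    cv2_ext = ext_var / M**2
    cv2_int = int_var / M**2
    return NoiseDecomposition(
        cv2_total=cv2_int + cv2_ext, cv2_int=cv2_int, cv2_ext=cv2_ext, mean_rna=M
    )


# ---------------------------------------------------------------------------
# dual-allele correlation


def allele_output_correlation(
    dataset: TraceDataset,
    profile: SignalProfile = DEFAULT_PROFILE,
    background: float = 0.0,
    n_bootstrap: int = 1000,
    rng=None,
) -> AlleleCorrelation:
    """Pearson correlation of total RNA output between sister alleles.

    Every cell must carry exactly two alleles.  The symmetric doubling
    convention is used: each pair enters once as (a, b) and once as (b, a),
    making the correlation independent of allele labelling.  Uncertainty
    comes from bootstrapping over cells.  The per-timepoint intensity PCC
    within each cell is returned as well (independence of the moment-to-
    moment bursting between alleles).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cells = np.unique(dataset.cell_ids)
    outputs = np.empty((len(cells), 2))
    trace_pcc = np.empty(len(cells))
    for i, c in enumerate(cells):
        idx = np.where(dataset.cell_ids == c)[0]
        if len(idx) != 2:
            raise ValueError(f"cell {c} does not have exactly 2 alleles")
        a, b = dataset.intensity[idx[0]], dataset.intensity[idx[1]]
        outputs[i, 0] = total_rna_output(a, profile, background, dataset.frame_interval)
        outputs[i, 1] = total_rna_output(b, profile, background, dataset.frame_interval)
        sa, sb = a.std(), b.std()
        trace_pcc[i] = float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0 else 0.0

    def doubled_pcc(out):
        x = np.concatenate([out[:, 0], out[:, 1]])
        y = np.concatenate([out[:, 1], out[:, 0]])
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    pcc = doubled_pcc(outputs)
    boots = np.empty(n_bootstrap)
    n = len(cells)
    for k in range(n_bootstrap):
        boots[k] = doubled_pcc(outputs[rng.integers(0, n, size=n)])
    return AlleleCorrelation(
        pcc=pcc, boot_mean=float(boots.mean()), boot_sd=float(boots.std()),
        per_cell_trace_pcc=trace_pcc, outputs=outputs,
    )
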
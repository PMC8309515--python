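"""Gait-event peak detection and evaluation metrics.

Six statistics compare an actual joint-angle trace with its prediction:
R² (all points), ROM = max − min of the actual trace, and RMSE / STD of the
residuals at gait-event peaks with their ROM-normalized percentages NRMSE and
NSTD. The knee's gait event is the small stance-phase flexion peak — the most
prominent interior maximum between consecutive swing peaks — and the hip's is
its per-cycle flexion maximum. Channel comparisons use two-tailed paired
t-tests with correlation strength labelled on the Schober scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

KIN_RATE = 100
#: maximum |Δt| between an actual and a predicted peak to count as the same
#: gait event (about a third of a running stride)
PEAK_MATCH_TOL_S = 0.25


class UndefinedMetricError(ValueError):
    """A metric's definition degenerates (constant trace, zero ROM, no pairs)."""


class DegenerateTestError(ValueError):
    """Paired test cannot run (zero-variance differences)."""


@dataclass
class PeakEventSeries:
    """Times and values of one joint's gait-event peaks."""

    joint: str
    event_kind: str  # "knee_stance_peak" | "hip_peak_flexion"
    times: np.ndarray
    values: np.ndarray


@dataclass
class MetricsReport:
    """The six evaluation statistics for one (joint, channel, scheme) cell."""

    r2: float
    rom: float
    rmse: float
    nrmse: float
    std: float
    nstd: float
    n_peaks_matched: int
    n_peaks_unmatched: int


@dataclass
class GroupComparison:
    """Accelerometer-vs-gyroscope paired comparison of one parameter."""

    parameter: str
    mean_accel: float
    sd_accel: float
    mean_gyro: float
    sd_gyro: float
    t_statistic: float
    p_value: float
    significant: bool
    r2_interpretation: tuple[str, str] | None = None  # (accel, gyro) labels


# ---------------------------------------------------------------- peaks

def _fundamental_period(x: np.ndarray, rate: float) -> float:
    """Dominant gait period (s) from the autocorrelation's first peak."""
    z = x - x.mean()
    ac = sps.correlate(z, z, mode="full")[z.size - 1:]
    lo, hi = int(0.3 * rate), min(int(2.0 * rate), ac.size - 1)
    if hi <= lo:
        return 0.75
    lag = lo + int(np.argmax(ac[lo:hi]))
    return lag / rate


def detect_peaks(trace: np.ndarray, joint: str, rate: float = KIN_RATE,
                 t0: float = 0.0) -> PeakEventSeries:
    """Locate the per-cycle gait-event peaks of one joint-angle trace.

    Hip: the per-cycle global maximum. Knee: cycles are delimited by the
    successive swing maxima (the per-cycle global maxima) and the event is the
    most prominent local maximum strictly between consecutive swing peaks;
    cycles with no interior maximum contribute no event. The same detector is
    applied to actual and predicted traces.
    """
    trace = np.asarray(trace, dtype=float)
    if joint not in ("knee", "hip"):
        raise ValueError(f"unknown joint {joint!r}")
    if trace.size < 2 * rate:
        raise ValueError("trace must cover at least 2 s")
    period = _fundamental_period(trace, rate)
    # light zero-phase smoothing for locating peaks; values are read from the
    # raw trace at the located sample
    smooth = sps.savgol_filter(trace, 7, 2) if trace.size >= 7 else trace
    span = trace.max() - trace.min()
    distance = max(int(0.6 * period * rate), 1)
    major, _ = sps.find_peaks(smooth, distance=distance,
                              height=trace.min() + 0.5 * span)
    if joint == "hip":
        idx = major
    else:
        stance = []
        for a, b in zip(major[:-1], major[1:]):
            interior, props = sps.find_peaks(smooth[a + 1:b],
                                             prominence=0.02 * span)
            if interior.size:
                stance.append(a + 1 + interior[np.argmax(props["prominences"])])
        idx = np.asarray(stance, dtype=int)
    kind = "hip_peak_flexion" if joint == "hip" else "knee_stance_peak"
    return PeakEventSeries(joint=joint, event_kind=kind,
                           times=t0 + idx / rate, values=trace[idx])


def match_peaks(actual: PeakEventSeries, predicted: PeakEventSeries,
                tol_s: float = PEAK_MATCH_TOL_S,
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy nearest-time pairing of actual and predicted peak events.

    Each event is used at most once and pairs farther apart than ``tol_s``
    are discarded. Returns ``(actual_values, predicted_values, n_unmatched)``.
    """
    ta, tp = np.asarray(actual.times), np.asarray(predicted.times)
    if ta.size == 0 or tp.size == 0:
        return np.empty(0), np.empty(0), ta.size + tp.size
    dt = np.abs(ta[:, None] - tp[None, :])
    order = np.argsort(dt, axis=None)
    used_a = np.zeros(ta.size, bool)
    used_p = np.zeros(tp.size, bool)
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), tp.size)
        if dt[i, j] > tol_s:
            break
        if not used_a[i] and not used_p[j]:
            used_a[i] = used_p[j] = True
            pairs.append((i, j))
    pairs.sort()
    ia = np.array([i for i, _ in pairs], dtype=int)
    ip = np.array([j for _, j in pairs], dtype=int)
    n_unmatched = int((~used_a).sum() + (~used_p).sum())
    return actual.values[ia], predicted.values[ip], n_unmatched


# ---------------------------------------------------------------- statistics

def r_squared(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 − SSres/SStot over all points."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("traces must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined for a constant actual trace")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rom(actual: np.ndarray) -> float:
    """Range of motion: max − min of the actual trace (degrees)."""
    y = np.asarray(actual, dtype=float)
    if y.size == 0:
        raise ValueError("empty trace")
    return float(y.max() - y.min())


def peak_rmse_std(actual_values: np.ndarray, predicted_values: np.ndarray,
                  ) -> tuple[float, float]:
    """RMSE and sample standard deviation (ddof=1) of peak residuals."""
    p = np.asarray(actual_values, dtype=float)
    phat = np.asarray(predicted_values, dtype=float)
    if p.size == 0:
        raise UndefinedMetricError("no matched peak pairs")
    r = p - phat
    rmse = float(np.sqrt(np.mean(r ** 2)))
    std = float(np.std(r, ddof=1)) if r.size >= 2 else float("nan")
    return rmse, std


def normalized(metric: float, rom_value: float) -> float:
    """Express a degree-valued error as a percentage of ROM."""
    if rom_value <= 0:
        raise UndefinedMetricError("normalization requires ROM > 0")
    return 100.0 * metric / rom_value


def evaluate_trace(actual: np.ndarray, predicted: np.ndarray, joint: str,
                   rate: float = KIN_RATE) -> MetricsReport:
    """Compute the full six-statistic report for one actual/predicted pair.

    If no peak pair can be matched (a prediction too poor to show gait
    events), the peak-based statistics are NaN and the report is flagged via
    ``n_peaks_matched == 0`` rather than raising.
    """
    r2 = r_squared(actual, predicted)
    rom_v = rom(actual)
    pk_a = detect_peaks(actual, joint, rate)
    pk_p = detect_peaks(predicted, joint, rate)
    va, vp, n_unmatched = match_peaks(pk_a, pk_p)
    if va.size == 0:
        rmse = std = float("nan")
    else:
        rmse, std = peak_rmse_std(va, vp)
    return MetricsReport(
        r2=r2, rom=rom_v, rmse=rmse, nrmse=normalized(rmse, rom_v),
        std=std, nstd=normalized(std, rom_v),
        n_peaks_matched=int(va.size), n_peaks_unmatched=n_unmatched)


SCHOBER_BINS = ((0.10, "negligible"), (0.40, "weak"), (0.70, "moderate"),
                (0.90, "strong"), (np.inf, "very strong"))


def schober_label(value: float) -> str:
    """Correlation-strength label (Schober bins) for a correlation magnitude."""
    v = abs(value)
    for upper, label in SCHOBER_BINS:
        if v < upper:
            return label
    return "very strong"  # pragma: no cover


def paired_comparison(accel: np.ndarray, gyro: np.ndarray, parameter: str,
                      ) -> GroupComparison:
    """Two-tailed paired t-test of one parameter between the two regressors."""
    a = np.asarray(accel, dtype=float)
    g = np.asarray(gyro, dtype=float)
    if a.shape != g.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - g
    if np.allclose(d, d[0]):
        raise DegenerateTestError(
            f"paired differences for {parameter!r} have zero variance")
    t_stat, p = stats.ttest_rel(a, g)
    labels = ((schober_label(a.mean()), schober_label(g.mean()))
              if parameter.lower() in ("r2", "r^2") else None)
    return GroupComparison(
        parameter=parameter, mean_accel=float(a.mean()), sd_accel=float(a.std(ddof=1)),
        mean_gyro=float(g.mean()), sd_gyro=float(g.std(ddof=1)),
        t_statistic=float(t_stat), p_value=float(p),
        significant=bool(p < 0.05), r2_interpretation=labels)
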
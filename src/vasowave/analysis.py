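"""Post-processing of recorded trajectories.

Temporal averaging of per-cell Ca2+ over a late window, oscillation metrics
(dominant period via inter-peak statistics with an autocorrelation
fallback, spike amplitude, non-oscillatory flagging), wave-front speed
along a cell path, and the frequency-encoded protein phosphorylation
readout: a zero-order ultrasensitive kinase/phosphatase cycle whose kinase
rate follows cytosolic Ca2+ through Michaelis-Menten activation,

    dW*/dt = v_p W_T [ (v_k/v_p)(1 - W*)/(K_1 + 1 - W*) - W*/(K_2 + W*) ],
    v_k    = V_MK Ca2+(t) / (K_a + Ca2+(t)).

With K_1, K_2 << 1 the steady state of W* switches sharply as v_k/v_p
crosses 1, so brief Ca2+ spikes flip the protein almost fully
phosphorylated while a low baseline leaves it dephosphorylated — the
mean of W* then encodes the spike frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .geometry import REGIONS
from .params import PhosphoParams
from .simulator import TimeSeriesRecord


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# temporal averaging
# ---------------------------------------------------------------------------

@dataclass
class AveragedField:
    """Per-cell time-averaged concentration over [t_i, t_f]."""

    mean: np.ndarray
    t_i: float
    t_f: float
    layer: str = "smc"
    var: str = "ca_cyt"


def temporal_average(record: TimeSeriesRecord, t_i: float = 300.0,
                     t_f: float = 500.0, layer: str = "smc",
                     var: str = "ca_cyt") -> AveragedField:
    """Arithmetic mean of the recorded samples in [t_i, t_f], per cell.

    Endpoints are inclusive and the sum is normalised by the number of
    samples, so the mean always lies within [min, max] of the windowed
    trace.
    """
    if not t_i < t_f:
        raise AnalysisError("need t_i < t_f")
    t = record.times
    mask = (t >= t_i - 1e-9) & (t <= t_f + 1e-9)
    if not mask.any():
        raise AnalysisError(
            f"averaging window [{t_i}, {t_f}] s contains no recorded samples")
    traces = record.ec_var(var) if layer == "ec" else record.smc_var(var)
    return AveragedField(mean=traces[mask].mean(axis=0), t_i=t_i, t_f=t_f,
                         layer=layer, var=var)


def region_means(avg: AveragedField, regions: np.ndarray) -> dict[str, float]:
    """Mean of an averaged field per region label."""
    out = {}
    for rid, name in enumerate(REGIONS):
        sel = regions == rid
        if sel.any():
            out[name] = float(avg.mean[sel].mean())
    return out


# ---------------------------------------------------------------------------
# phosphorylation cycle
# ---------------------------------------------------------------------------

def kinase_rate(ca, p: PhosphoParams):
    """Ca2+-activated kinase rate v_k, Michaelis-Menten bounded by V_MK."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise AnalysisError("Ca2+ drive must be >= 0")
    out = p.V_MK * ca / (p.K_a + ca)
    return float(out) if out.ndim == 0 else out


def phospho_rate(W_star, v_k, p: PhosphoParams):
    """dW*/dt of the phosphorylated fraction."""
    W = np.asarray(W_star, dtype=float)
    if np.any((W < 0) | (W > 1)):
        raise AnalysisError("W* must lie in [0, 1]")
    production = (v_k / p.v_p) * (1.0 - W) / (p.K_1 + 1.0 - W)
    decay = W / (p.K_2 + W)
    out = p.v_p * p.W_T * (production - decay)
    return float(out) if out.ndim == 0 else out


def phospho_steady(v_k: float, p: PhosphoParams) -> float:
    """Steady-state W* at constant kinase rate, by 1D root finding."""
    if v_k <= 0:
        return 0.0
    f = lambda w: phospho_rate(w, v_k, p)
    lo, hi = 0.0, 1.0
    flo, fhi = f(lo), f(hi)
    if flo <= 0:
        return 0.0
    if fhi >= 0:
        return 1.0
    return float(brentq(f, lo, hi, xtol=1e-12))


def simulate_phospho(ca_trace: np.ndarray, times: np.ndarray,
                     p: PhosphoParams, W0: float = 0.0) -> np.ndarray:
    """Integrate W*(t) under a sampled Ca2+ drive (linear interpolation).

    Returns W* at the input sample times; the trajectory stays in [0, 1].
    """
    ca_trace = np.asarray(ca_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(ca_trace)):
        raise AnalysisError("Ca2+ drive contains non-finite values")
    if not 0.0 <= W0 <= 1.0:
        raise AnalysisError("W0 must lie in [0, 1]")

    def rhs(t, y):
        ca = np.interp(t, times, ca_trace)
        w = min(max(y[0], 0.0), 1.0)
        return [phospho_rate(w, kinase_rate(ca, p), p)]

    sol = solve_ivp(rhs, (times[0], times[-1]), [W0], t_eval=times,
                    method="LSODA", rtol=1e-8, atol=1e-10, max_step=1.0)
    if not sol.success:
        raise AnalysisError(f"phosphorylation integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, 1.0)


def time_average_W(W_trace: np.ndarray, times: np.ndarray,
                   T_min: float = 0.0, T_max: float | None = None) -> float:
    """Trapezoidal time-mean of W* over [T_min, T_max] (default: whole trace)."""
    times = np.asarray(times, dtype=float)
    W = np.asarray(W_trace, dtype=float)
    if T_max is None:
        T_max = float(times[-1])
    mask = (times >= T_min - 1e-9) & (times <= T_max + 1e-9)
    if mask.sum() < 2:
        raise AnalysisError(f"window [{T_min}, {T_max}] holds fewer than 2 samples")
    tt, ww = times[mask], W[mask]
    return float(np.trapezoid(ww, tt) / (tt[-1] - tt[0]))


# ---------------------------------------------------------------------------
# oscillation & wave metrics
# ---------------------------------------------------------------------------

@dataclass
class WaveMetrics:
    """Per-cell oscillation metrics plus optional region summaries."""

    period: np.ndarray             # s; nan where non-oscillatory
    amplitude: np.ndarray          # uM, mean peak minus baseline
    baseline: np.ndarray           # uM, low-quantile level
    oscillatory: np.ndarray        # bool per cell
    region_summary: dict = field(default_factory=dict)


def trace_period(t: np.ndarray, x: np.ndarray,
                 prominence: float = 0.05) -> tuple[float, np.ndarray]:
    """Dominant period of one trace: median inter-peak interval, with an
    autocorrelation fallback when fewer than 3 peaks are found.  Returns
    (period or nan, peak indices)."""
    peaks, _ = find_peaks(x, prominence=prominence)
    if len(peaks) >= 3:
        return float(np.median(np.diff(t[peaks]))), peaks
    # autocorrelation fallback for weak/regular oscillations
    xc = x - x.mean()
    if np.allclose(xc, 0.0, atol=1e-12) or len(x) < 8:
        return float("nan"), peaks
    ac = np.correlate(xc, xc, mode="full")[len(x) - 1:]
    ac /= ac[0]
    lag_peaks, props = find_peaks(ac, height=0.2)
    if len(lag_peaks) == 0:
        return float("nan"), peaks
    dt = t[1] - t[0]
    return float(lag_peaks[0] * dt), peaks


def oscillation_metrics(record: TimeSeriesRecord, layer: str = "smc",
                        var: str = "ca_cyt", t_min: float = 0.0,
                        prominence: float = 0.05,
                        baseline_quantile: float = 0.1,
                        regions: np.ndarray | None = None) -> WaveMetrics:
    """Per-cell dominant period, amplitude and oscillatory flag."""
    t = record.times
    mask = t >= t_min
    traces = (record.ec_var(var) if layer == "ec" else record.smc_var(var))[mask]
    tt = t[mask]
    n = traces.shape[1]
    period = np.full(n, np.nan)
    amp = np.zeros(n)
    base = np.zeros(n)
    osc = np.zeros(n, dtype=bool)
    for i in range(n):
        x = traces[:, i]
        base[i] = np.quantile(x, baseline_quantile)
        per, peaks = trace_period(tt, x, prominence)
        if len(peaks) >= 2 and np.isfinite(per):
            period[i] = per
            amp[i] = x[peaks].mean() - base[i]
            osc[i] = True
    wm = WaveMetrics(period=period, amplitude=amp, baseline=base, oscillatory=osc)
    if regions is not None:
        for rid, name in enumerate(REGIONS):
            sel = regions == rid
            if sel.any():
                wm.region_summary[name] = {
                    "oscillating_fraction": float(osc[sel].mean()),
                    "period": float(np.nanmedian(period[sel])) if osc[sel].any() else float("nan"),
                    "amplitude": float(amp[sel].mean()),
                }
    return wm


def wave_front_speed(record: TimeSeriesRecord, path_cells: np.ndarray,
                     distances: np.ndarray | None = None, layer: str = "smc",
                     var: str = "ca_cyt", threshold: float | None = None,
                     t_min: float = 0.0) -> dict:
    """Front speed from threshold-crossing times along a cell path.

    ``distances`` are cumulative positions along the path (mm, or cell
    index units if omitted).  Arrival = first upward crossing of
    ``threshold`` (default: midway between global low and high quantiles).
    The speed is the inverse slope of a least-squares fit of arrival time
    against distance; a standing (in-phase) oscillation yields a near-zero
    slope and is flagged instead of reported as a finite speed.
    """
    t = record.times
    mask = t >= t_min
    tt = t[mask]
    traces = (record.ec_var(var) if layer == "ec" else record.smc_var(var))
    traces = traces[np.ix_(mask, path_cells)]
    if distances is None:
        distances = np.arange(len(path_cells), dtype=float)
    if threshold is None:
        threshold = 0.5 * (np.quantile(traces, 0.05) + np.quantile(traces, 0.95))
    arrivals = np.full(len(path_cells), np.nan)
    for k in range(traces.shape[1]):
        x = traces[:, k]
        above = x >= threshold
        idx = np.flatnonzero(~above[:-1] & above[1:])
        if idx.size:
            i = idx[0]
            frac = (threshold - x[i]) / (x[i + 1] - x[i])
            arrivals[k] = tt[i] + frac * (tt[i + 1] - tt[i])
        elif above[0]:
            arrivals[k] = tt[0]
    ok = np.isfinite(arrivals)
    if ok.sum() < 2:
        return {"speed": np.nan, "flag": "no_crossing", "arrivals": arrivals}
    d, a = np.asarray(distances, float)[ok], arrivals[ok]
    slope, intercept = np.polyfit(d, a, 1)
    span = a.max() - a.min()
    if span < 2 * (tt[1] - tt[0]) or abs(slope) * (d.max() - d.min()) < 1e-9:
        return {"speed": np.inf, "flag": "standing", "arrivals": arrivals}
    return {"speed": float(1.0 / slope), "flag": "ok", "arrivals": arrivals,
            "slope": float(slope), "intercept": float(intercept)}
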
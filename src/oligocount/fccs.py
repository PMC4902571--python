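"""Pulsed-interleaved-excitation FCCS analysis.

Photon streams are time-gated on (pulse origin, microtime) to remove
green-to-red bleed-through and direct red excitation, binned into intensity
traces, correlated with a multi-tau correlator, and fitted with a
single-component 2D membrane-diffusion model

    G(tau) = G0 / (1 + tau / tau_D),      D = w^2 / (4 tau_D)

for a Gaussian observation profile of 1/e^2 waist w. The fraction of
co-diffusing molecules is reported as

    f_c = G_x(0) / max(G_gg(0), G_rr(0)),

using fit-extrapolated zero-lag amplitudes; with equal labeling this keeps
f_c in [0, 1] regardless of which color is in excess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from oligocount.containers import GREEN, RED, PhotonStream
from oligocount.synthetic import PIEConfig


@dataclass
class GatedTraces:
    green: np.ndarray
    red: np.ndarray
    bin_width: float
    rejected_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class CorrelationCurve:
    """One auto- or cross-correlation on a quasi-logarithmic lag grid."""

    lags: np.ndarray
    G: np.ndarray
    se: np.ndarray | None = None
    kind: str = "auto"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class CorrelationCurves:
    lags: np.ndarray
    G_gg: np.ndarray
    G_rr: np.ndarray
    G_x: np.ndarray
    se_gg: np.ndarray | None = None
    se_rr: np.ndarray | None = None
    se_x: np.ndarray | None = None
    segment_count: int = 1


@dataclass
class FCSModelFit:
    G0: float
    tau_D: float
    D: float
    n_effective: float
    residual: float
    offset: float = 0.0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ok: bool = True


@dataclass
class CellSummary:
    f_c: float
    D_green: float
    D_red: float
    segment_fc: list[float]
    flags: list[str] = field(default_factory=list)
    fits: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gating and binning
# ---------------------------------------------------------------------------


def gate_photons(
    green_stream: PhotonStream,
    red_stream: PhotonStream,
    pie: PIEConfig,
    bin_width: float = 2e-4,
    duration: float | None = None,
) -> GatedTraces:
    """PIE time gating followed by binning into intensity traces.

    Red-channel photons whose originating pulse is 488 nm and whose
    microtime falls inside the gate window are rejected (bleed-through and
    FRET); symmetrically, green-channel photons tied to the 561 nm pulse are
    rejected. Survivors are histogrammed at ``bin_width``.
    """
    if green_stream.pulse_origin.size != green_stream.n_photons:
        raise ValueError("photon streams must carry pulse tags")
    if duration is None:
        duration = max(green_stream.duration, red_stream.duration)
    n_bins = max(1, int(np.ceil(duration / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width

    def gated(stream: PhotonStream, reject_origin: int) -> tuple[np.ndarray, int]:
        reject = (stream.pulse_origin == reject_origin) & (
            stream.microtimes < pie.gate_window
        )
        keep = stream.arrival_times[~reject]
        counts, _ = np.histogram(keep, bins=edges)
        return counts.astype(float), int(reject.sum())

    g_counts, g_rej = gated(green_stream, 561)
    r_counts, r_rej = gated(red_stream, 488)
    return GatedTraces(
        green=g_counts,
        red=r_counts,
        bin_width=bin_width,
        rejected_counts={GREEN: g_rej, RED: r_rej},
    )


def detrend_linear(trace: np.ndarray) -> np.ndarray:
    """Remove a linear photobleaching trend while preserving the mean."""
    t = np.arange(trace.size, dtype=float)
    slope, intercept = np.polyfit(t, trace, 1)
    return trace - (slope * t + intercept) + trace.mean()


# ---------------------------------------------------------------------------
# multi-tau correlation
# ---------------------------------------------------------------------------


def multi_tau_correlate(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    bin_width: float,
    m: int = 16,
    max_lag: float = 1.0,
) -> CorrelationCurve:
    """Multi-tau correlator with successive 2x rebinning.

    The first stage evaluates lags 1..2m at the base bin width; each later
    stage rebins both traces by two and evaluates lags m+1..2m. Each point
    uses the symmetrically normalized estimator

        G(k) = <a_i b_{i+k}> / (<a>_head <b>_tail) - 1

    with means taken over the overlapping portions of the traces.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be equal-length 1D arrays")
    if a.mean() == 0 or b.mean() == 0:
        raise ValueError("zero-mean trace: normalization undefined")
    if max_lag >= a.size * bin_width / 2:
        raise ValueError("max_lag must be well below the trace duration")

    lags, G = [], []
    dt = bin_width
    level = 0
    while True:
        k_range = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        done = False
        for k in k_range:
            tau = k * dt
            if tau > max_lag or k >= a.size:
                done = True
                break
            n = a.size - k
            head, tail = a[:n], b[k:]
            G.append(float(head @ tail / n / (head.mean() * tail.mean()) - 1.0))
            lags.append(tau)
        if done or a.size < 4 * m:
            break
        even = (a.size // 2) * 2
        a = a[0:even:2] + a[1:even:2]
        b = b[0:even:2] + b[1:even:2]
        dt *= 2
        level += 1
    kind = "auto" if trace_a is trace_b else "cross"
    return CorrelationCurve(lags=np.array(lags), G=np.array(G), kind=kind)


def correlate_traces(
    traces: GatedTraces, m: int = 16, max_lag: float = 1.0
) -> CorrelationCurves:
    """Auto- and cross-correlate a gated two-channel trace pair."""
    gg = multi_tau_correlate(traces.green, traces.green, traces.bin_width, m, max_lag)
    rr = multi_tau_correlate(traces.red, traces.red, traces.bin_width, m, max_lag)
    gx = multi_tau_correlate(traces.green, traces.red, traces.bin_width, m, max_lag)
    return CorrelationCurves(lags=gg.lags, G_gg=gg.G, G_rr=rr.G, G_x=gx.G)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _model(tau: np.ndarray, g0: float, tau_d: float, offset: float = 0.0) -> np.ndarray:
    return g0 / (1.0 + tau / tau_d) + offset


def fit_2d_diffusion(
    lags: np.ndarray,
    G: np.ndarray,
    waist: float,
    se: np.ndarray | None = None,
    fix_tau: float | None = None,
    fit_offset: bool = True,
) -> FCSModelFit:
    """Weighted least-squares fit of the single-component 2D diffusion model.

    A free constant offset is included by default: correlation curves
    estimated from finite segments sit on a small negative baseline (the
    segment mean is estimated from the same data), and forcing the model
    through zero at long lags biases tau_D low. With ``fix_tau`` the
    diffusion time is held fixed and only amplitude and offset are fitted (a
    linear problem) — used for cross-correlation curves whose amplitude may
    be near zero. A non-decaying curve is returned with ``ok=False`` and no
    usable numbers.
    """
    lags = np.asarray(lags, dtype=float)
    G = np.asarray(G, dtype=float)
    if lags.size < 20:
        raise ValueError("need >= 20 lag points spanning tau_D")
    sigma = None if se is None else np.clip(se, np.max(se) * 1e-3, None)

    failed = FCSModelFit(
        G0=np.nan, tau_D=np.nan, D=np.nan, n_effective=np.nan, residual=np.nan, ok=False
    )

    if fix_tau is not None:
        f = 1.0 / (1.0 + lags / fix_tau)
        wt = np.ones_like(f) if sigma is None else 1.0 / sigma**2
        sw, swf, swff = wt.sum(), (wt * f).sum(), (wt * f * f).sum()
        det = swff * sw - swf**2
        if fit_offset:
            # linear least squares in (G0, offset)
            swg, swfg = (wt * G).sum(), (wt * f * G).sum()
            g0 = float((swfg * sw - swf * swg) / det)
            b = float((swff * swg - swf * swfg) / det)
        else:
            g0 = float((wt * f * G).sum() / swff)
            b = 0.0
        resid = float(np.sqrt(np.mean((G - g0 * f - b) ** 2)))
        var = resid**2 * (sw / det if fit_offset else 1.0 / swff)
        half = 1.96 * np.sqrt(max(var, 0.0))
        return FCSModelFit(
            G0=g0,
            tau_D=fix_tau,
            D=waist**2 / (4 * fix_tau),
            n_effective=np.inf if g0 <= 0 else 1.0 / g0,
            residual=resid,
            offset=b,
            ci={"G0": (g0 - half, g0 + half)},
            ok=True,
        )

    head = float(np.mean(G[: max(3, G.size // 20)]))
    tail = float(np.mean(G[-max(3, G.size // 20):]))
    if head <= 0 or head <= tail + 1e-12:
        return failed
    # initial tau_D: lag nearest half amplitude
    tau0 = float(lags[np.argmin(np.abs(G - head / 2.0))])
    if fit_offset:
        p0 = (head - tail, max(tau0, lags[1]), tail)
        bounds = ((0.0, lags[0] * 0.1, -1.0), (np.inf, lags[-1] * 100.0, 1.0))
        model = _model
    else:
        p0 = (head, max(tau0, lags[1]))
        bounds = ((0.0, lags[0] * 0.1), (np.inf, lags[-1] * 100.0))
        model = lambda tau, g0, td: _model(tau, g0, td)  # noqa: E731
    try:
        popt, pcov = optimize.curve_fit(
            model, lags, G, p0=p0, sigma=sigma, bounds=bounds, maxfev=5000
        )
    except RuntimeError:
        return failed
    g0, tau_d = popt[0], popt[1]
    b = popt[2] if fit_offset else 0.0
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = float(np.sqrt(np.mean((G - model(lags, *popt)) ** 2)))
    return FCSModelFit(
        G0=float(g0),
        tau_D=float(tau_d),
        D=waist**2 / (4.0 * tau_d),
        n_effective=1.0 / g0 if g0 > 0 else np.inf,
        residual=resid,
        offset=float(b),
        ci={
            "G0": (g0 - 1.96 * perr[0], g0 + 1.96 * perr[0]),
            "tau_D": (tau_d - 1.96 * perr[1], tau_d + 1.96 * perr[1]),
        },
        ok=bool(np.isfinite(g0) and g0 > 0 and tau_d > 0),
    )


def fraction_correlated(
    G_x0: float,
    G_gg0: float,
    G_rr0: float,
    convention: str = "max",
) -> tuple[float, list[str]]:
    """Fraction correlated from fitted zero-lag amplitudes.

    ``convention="max"`` divides by the larger autocorrelation amplitude
    (insensitive to which color is in excess, ideal range [0, 1]);
    ``"green"``/``"red"`` divide by that color's amplitude. Negative cross
    amplitudes clip to zero with a flag.
    """
    flags: list[str] = []
    if G_gg0 <= 0 or G_rr0 <= 0:
        return float("nan"), ["undefined_autocorrelation"]
    denom = {
        "max": max(G_gg0, G_rr0),
        "green": G_gg0,
        "red": G_rr0,
    }[convention]
    fc = G_x0 / denom
    if fc < 0:
        fc = 0.0
        flags.append("negative_cross_amplitude")
    if fc > 1.0:
        flags.append("fc_above_one")
    if fc > 1.5:
        fc = 1.5
        flags.append("fc_clipped")
    return float(fc), flags


# ---------------------------------------------------------------------------
# per-cell and population analysis
# ---------------------------------------------------------------------------


def _split_stream(stream: PhotonStream, t0: float, t1: float) -> PhotonStream:
    sel = (stream.arrival_times >= t0) & (stream.arrival_times < t1)
    return PhotonStream(
        arrival_times=stream.arrival_times[sel] - t0,
        microtimes=stream.microtimes[sel],
        pulse_origin=stream.pulse_origin[sel],
        channel=stream.channel,
        pulse_period=stream.pulse_period,
        meta={"duration": t1 - t0},
    )


def analyze_cell(
    green_stream: PhotonStream,
    red_stream: PhotonStream,
    pie: PIEConfig,
    waist: float = 0.25,
    segment_length: float = 15.0,
    bin_width: float = 2e-4,
    m: int = 16,
    max_lag: float = 1.0,
    detrend: bool = True,
    bleach_threshold: float = 0.5,
    fc_convention: str = "max",
    weighted_fit: bool = False,
) -> CellSummary:
    """Full per-cell PIE-FCCS analysis of one acquisition.

    The streams are split into ``segment_length`` segments (the acquisition
    protocol records five 15 s segments per cell), each segment is gated,
    optionally detrended, and correlated; curves are averaged across
    segments with per-lag standard errors; the averaged autocorrelations are
    fitted freely and the cross-correlation amplitude is fitted with the
    diffusion time fixed to the mean of the two autocorrelation fits.
    Segments whose intensity drops by more than ``bleach_threshold``
    (relative first-half/second-half change) are excluded.

    Fits are unweighted by default: per-lag standard errors estimated from
    only five segments are noisy enough that inverse-variance weighting
    destabilizes the fit (``weighted_fit=True`` restores it for longer
    acquisitions).
    """
    duration = max(green_stream.duration, red_stream.duration)
    n_segments = int(duration // segment_length)
    flags: list[str] = []
    if n_segments < 5:
        warnings.warn(f"only {n_segments} full segments available", stacklevel=2)
        flags.append("short_acquisition")
    if n_segments < 1:
        raise ValueError("acquisition shorter than one segment")

    seg_curves: list[CorrelationCurves] = []
    for s in range(n_segments):
        t0 = s * segment_length
        g = _split_stream(green_stream, t0, t0 + segment_length)
        r = _split_stream(red_stream, t0, t0 + segment_length)
        traces = gate_photons(g, r, pie, bin_width, duration=segment_length)
        drop = False
        for tr in (traces.green, traces.red):
            half = tr.size // 2
            mean_head, mean_tail = tr[:half].mean(), tr[half:].mean()
            if mean_head > 0 and (mean_head - mean_tail) / mean_head > bleach_threshold:
                drop = True
        if drop:
            flags.append(f"segment_{s}_bleached")
            continue
        gtr = detrend_linear(traces.green) if detrend else traces.green
        rtr = detrend_linear(traces.red) if detrend else traces.red
        gated = GatedTraces(gtr, rtr, bin_width, traces.rejected_counts)
        seg_curves.append(correlate_traces(gated, m=m, max_lag=max_lag))

    if not seg_curves:
        raise ValueError("all segments rejected for photobleaching")
    lags = seg_curves[0].lags
    stack = {
        name: np.array([getattr(c, name) for c in seg_curves])
        for name in ("G_gg", "G_rr", "G_x")
    }
    n_used = len(seg_curves)
    avg = {k: v.mean(axis=0) for k, v in stack.items()}
    se = {
        k: (v.std(axis=0, ddof=1) / np.sqrt(n_used) if n_used > 1 else None)
        for k, v in stack.items()
    }

    fit_se = se if weighted_fit else {"G_gg": None, "G_rr": None, "G_x": None}
    fit_g = fit_2d_diffusion(lags, avg["G_gg"], waist, se=fit_se["G_gg"])
    fit_r = fit_2d_diffusion(lags, avg["G_rr"], waist, se=fit_se["G_rr"])
    if not (fit_g.ok and fit_r.ok):
        flags.append("autocorrelation_fit_failed")
        return CellSummary(
            f_c=float("nan"),
            D_green=fit_g.D,
            D_red=fit_r.D,
            segment_fc=[],
            flags=flags,
            fits={"green": fit_g, "red": fit_r},
        )
    tau_x = 0.5 * (fit_g.tau_D + fit_r.tau_D)
    fit_x = fit_2d_diffusion(lags, avg["G_x"], waist, se=fit_se["G_x"], fix_tau=tau_x)
    fc, fc_flags = fraction_correlated(fit_x.G0, fit_g.G0, fit_r.G0, fc_convention)
    flags.extend(fc_flags)

    segment_fc: list[float] = []
    for c in seg_curves:
        sg = fit_2d_diffusion(lags, c.G_gg, waist, fix_tau=fit_g.tau_D)
        sr = fit_2d_diffusion(lags, c.G_rr, waist, fix_tau=fit_r.tau_D)
        sx = fit_2d_diffusion(lags, c.G_x, waist, fix_tau=tau_x)
        s_fc, _ = fraction_correlated(sx.G0, sg.G0, sr.G0, fc_convention)
        segment_fc.append(s_fc)

    return CellSummary(
        f_c=fc,
        D_green=fit_g.D,
        D_red=fit_r.D,
        segment_fc=segment_fc,
        flags=flags,
        fits={"green": fit_g, "red": fit_r, "cross": fit_x},
    )


def summarize_population(cells: list[CellSummary]) -> dict:
    """Box-plot summary (median, quartiles, whiskers, 1.5x IQR outliers) of
    per-cell f_c and diffusion coefficients."""
    if len(cells) < 5:
        raise ValueError("need at least 5 cells for a population summary")

    def box(values: np.ndarray) -> dict:
        q25, med, q75 = np.percentile(values, [25, 50, 75])
        iqr = q75 - q25
        outliers = values[(values < q25 - 1.5 * iqr) | (values > q75 + 1.5 * iqr)]
        return {
            "median": float(med),
            "q25": float(q25),
            "q75": float(q75),
            "whisker_low": float(values.min()),
            "whisker_high": float(values.max()),
            "outliers": outliers.tolist(),
            "n": int(values.size),
        }

    fc = np.array([c.f_c for c in cells if np.isfinite(c.f_c)])
    dg = np.array([c.D_green for c in cells if np.isfinite(c.D_green)])
    dr = np.array([c.D_red for c in cells if np.isfinite(c.D_red)])
    return {"f_c": box(fc), "D_green": box(dg), "D_red": box(dr)}


def compare_populations(
    cells_a: list[CellSummary], cells_b: list[CellSummary]
) -> dict:
    """Two-sample Student's t test on per-cell f_c between two conditions."""
    a = np.array([c.f_c for c in cells_a if np.isfinite(c.f_c)])
    b = np.array([c.f_c for c in cells_b if np.isfinite(c.f_c)])
    t, p = stats.ttest_ind(a, b)
    return {
        "t_statistic": float(t),
        "p_value": float(p),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
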
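"""Kinetic and spectral analysis of heat-evoked currents and fluorescence.

Covers the quantitative readouts of heat-gating experiments:

- mono-exponential fitting of desensitization time courses (τ);
- degree of heat desensitization, the percent decline from the heat-evoked
  current maximum (Imax) to the desensitized level (Id) at constant
  temperature;
- heat-activation threshold detection as the breakpoint of a two-segment
  linear fit in Arrhenius coordinates (log10 |I| against 1/T);
- skew-Gaussian emission-peak fitting (λmax of ANAP-like fluorophores);
- acceptor/donor spectral ratios and temperature-dependent FRET-ratio
  correction against a control construct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.special import erf

import lmfit

__all__ = [
    "CurrentTrace",
    "ExpFit",
    "DhResult",
    "ThresholdResult",
    "EmissionSpectrum",
    "SkewGaussFit",
    "FretTimeCourse",
    "fit_monoexp",
    "dh_degree",
    "activation_threshold",
    "fit_skew_gauss",
    "spectral_ratio",
    "correct_fret_ratio",
    "find_constant_T_window",
    "read_trace",
    "write_trace",
    "read_spectrum",
    "fit_to_json",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CurrentTrace:
    """Whole-cell current with a paired temperature readout.

    ``time`` in s (uniformly sampled, strictly increasing), ``current`` in
    pA (outward at +80 mV positive), ``temperature`` in °C.
    """

    time: np.ndarray
    current: np.ndarray
    temperature: np.ndarray
    voltage_mV: float = 80.0
    spec: object | None = None  # GeneratorSpec when synthetic

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (len(self.time) == len(self.current) == len(self.temperature)):
            raise ValueError("time, current, temperature must share length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ExpFit:
    """Result of a single-exponential fit I(t) = offset + A·e^{−(t−t0)/τ}."""

    tau: float | None
    amplitude: float | None
    offset: float | None
    window: tuple[float, float]
    residual_rms: float | None
    success: bool
    message: str = ""


@dataclass
class DhResult:
    """Degree of heat desensitization over a constant-temperature window."""

    degree_percent: float
    id_over_imax_percent: float
    imax: float
    i_end: float
    window: tuple[float, float]


@dataclass
class ThresholdResult:
    """Two-segment Arrhenius breakpoint (heat-activation threshold)."""

    threshold_C: float | None
    found: bool
    segment_cold: tuple[float, float]   # (slope, intercept) in (1/K, log10 pA)
    segment_hot: tuple[float, float]
    f_ratio: float
    n_points: int


@dataclass
class SkewGaussFit:
    """Skew-normal peak parameters with the derived peak wavelength."""

    amplitude: float
    location: float      # ξ, nm
    scale: float         # ω, nm
    shape: float         # α (0 = symmetric Gaussian)
    baseline: float
    lambda_max: float    # nm, maximum of the fitted curve
    residual_rms: float
    success: bool


@dataclass
class EmissionSpectrum:
    """Emission spectrum with optional skew-Gaussian fit attached."""

    wavelength: np.ndarray   # nm, increasing
    intensity: np.ndarray    # a.u.
    fit: SkewGaussFit | None = None
    spec: object | None = None

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.wavelength) != len(self.intensity):
            raise ValueError("wavelength and intensity must share length")
        if len(self.wavelength) > 1 and not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelength must be strictly increasing")


@dataclass
class FretTimeCourse:
    """Acceptor/donor intensity ratio over time with paired temperature."""

    time: np.ndarray
    ratio: np.ndarray
    temperature: np.ndarray
    corrected: np.ndarray | None = None
    spec: object | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (len(self.time) == len(self.ratio) == len(self.temperature)):
            raise ValueError("time, ratio, temperature must share length")
        if np.any(self.ratio <= 0):
            raise ValueError("intensity ratios must be positive")

    def as_trace(self, use_corrected: bool = True) -> CurrentTrace:
        """View the (corrected) ratio as a trace for exponential fitting."""
        y = self.corrected if (use_corrected and self.corrected is not None) \
            else self.ratio
        return CurrentTrace(self.time, y, self.temperature, spec=self.spec)


# ---------------------------------------------------------------------------
# Mono-exponential fitting
# ---------------------------------------------------------------------------

def _monoexp(t, offset, amplitude, tau, t0):
    return offset + amplitude * np.exp(-(t - t0) / tau)


def fit_monoexp(
    trace: CurrentTrace, window: tuple[float, float] | None = None
) -> ExpFit:
    """Least-squares single-exponential fit of a current (or ratio) decay.

    The fit is initialised from a log-linear regression on the
    offset-subtracted signal (offset seeded from the tail mean) and refined
    by damped least squares.  A window whose amplitude is indistinguishable
    from zero returns ``success=False`` with no τ.
    """
    t = trace.time
    y = trace.current
    if window is None:
        window = (float(t[0]), float(t[-1]))
    mask = (t >= window[0]) & (t <= window[1])
    t = t[mask]
    y = y[mask]
    if len(t) < 10:
        raise ValueError("fit window must contain at least 10 samples")
    t0 = float(t[0])
    span = float(np.ptp(y))
    scale = max(np.max(np.abs(y)), 1.0)
    if span < 1e-12 * scale:
        return ExpFit(None, None, None, window, None, False,
                      "signal constant within the window")

    # Initialisation: offset from the tail, τ from log-linear decay.
    n_tail = max(3, len(t) // 10)
    offset0 = float(np.mean(y[-n_tail:]))
    resid = y - offset0
    sign = float(np.sign(resid[: max(3, len(t) // 20)].mean())) or 1.0
    u = sign * resid
    ok = u > 1e-3 * span
    if ok.sum() >= 5:
        slope, intercept = np.polyfit(t[ok] - t0, np.log(u[ok]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t0) / 3.0
        amp0 = sign * float(np.exp(intercept))
    else:
        tau0 = (t[-1] - t0) / 3.0
        amp0 = float(resid[0])
    tau0 = float(np.clip(tau0, 1e-6, 100 * (t[-1] - t0)))

    model = lmfit.Model(_monoexp, independent_vars=["t"])
    params = model.make_params(
        offset=offset0, amplitude=amp0, tau=dict(value=tau0, min=1e-9),
        t0=dict(value=t0, vary=False),
    )
    try:
        result = model.fit(y, params, t=t)
    except Exception as exc:
        return ExpFit(None, None, None, window, None, False, str(exc))
    rms = float(np.sqrt(np.mean(result.residual**2)))
    amp = float(result.params["amplitude"].value)
    amp_err = result.params["amplitude"].stderr
    if abs(amp) < 1e-9 * scale or (
        amp_err is not None and np.isfinite(amp_err) and abs(amp) < 2 * amp_err
    ):
        return ExpFit(None, None, None, window, rms, False,
                      "amplitude indistinguishable from zero")
    return ExpFit(
        tau=float(result.params["tau"].value),
        amplitude=amp,
        offset=float(result.params["offset"].value),
        window=window,
        residual_rms=rms,
        success=True,
    )


# ---------------------------------------------------------------------------
# Degree of desensitization
# ---------------------------------------------------------------------------

def find_constant_T_window(
    trace: CurrentTrace, tolerance: float = 1.0
) -> tuple[float, float]:
    """Longest contiguous window whose temperature excursion stays within
    ±tolerance of the window midpoint (two-pointer scan with monotone
    deques; O(n))."""
    from collections import deque

    T = trace.temperature
    n = len(T)
    best = (0, 0)
    lo = 0
    maxq: deque[int] = deque()
    minq: deque[int] = deque()
    for hi in range(n):
        while maxq and T[maxq[-1]] <= T[hi]:
            maxq.pop()
        maxq.append(hi)
        while minq and T[minq[-1]] >= T[hi]:
            minq.pop()
        minq.append(hi)
        while T[maxq[0]] - T[minq[0]] > 2 * tolerance:
            lo += 1
            if maxq[0] < lo:
                maxq.popleft()
            if minq[0] < lo:
                minq.popleft()
        if hi - lo > best[1] - best[0]:
            best = (lo, hi)
    lo, hi = best
    # Trim until every sample is within tolerance of the window *mean*
    # (a ramp tail can satisfy the max-min bound but not the mean bound).
    while hi > lo:
        seg = T[lo:hi + 1]
        dev = np.abs(seg - seg.mean())
        if dev.max() <= tolerance:
            break
        if dev[0] >= dev[-1]:
            lo += 1
        else:
            hi -= 1
    return float(trace.time[lo]), float(trace.time[hi])


def dh_degree(
    trace: CurrentTrace,
    constant_T_window: tuple[float, float] | None = None,
    temperature_tolerance: float = 1.0,
    end_fraction: float = 0.1,
    smooth_samples: int | None = None,
) -> DhResult:
    """Degree of heat desensitization (%) over a constant-T window.

    degree = 100 · (Imax − I_end)/Imax, with Imax the window maximum of the
    (optionally smoothed) current and I_end the mean over the final
    ``end_fraction`` of the window; Id/Imax (%) is returned as the exact
    complement.  The temperature within the window must stay within
    ``temperature_tolerance`` of its mean, else an error names the
    excursion.
    """
    if constant_T_window is None:
        constant_T_window = find_constant_T_window(trace,
                                                   temperature_tolerance)
    lo, hi = constant_T_window
    mask = (trace.time >= lo) & (trace.time <= hi)
    if mask.sum() < 10:
        raise ValueError("constant-T window contains fewer than 10 samples")
    T = trace.temperature[mask]
    excursion = np.abs(T - T.mean())
    if excursion.max() > temperature_tolerance:
        i = int(np.argmax(excursion))
        raise ValueError(
            f"temperature not constant in window: |T − mean| = "
            f"{excursion.max():.2f} °C at t = {trace.time[mask][i]:.2f} s"
        )
    y = trace.current[mask]
    if smooth_samples and smooth_samples > 1:
        y = uniform_filter1d(y, smooth_samples, mode="nearest")
    imax = float(np.max(y))
    if imax == 0:
        raise ValueError("window maximum current is zero")
    n_end = max(1, int(round(end_fraction * len(y))))
    i_end = float(np.mean(y[-n_end:]))
    degree = 100.0 * (imax - i_end) / imax
    return DhResult(degree, 100.0 - degree, imax, i_end, constant_T_window)


# ---------------------------------------------------------------------------
# Activation threshold (Arrhenius breakpoint)
# ---------------------------------------------------------------------------

def activation_threshold(
    trace: CurrentTrace,
    min_f_ratio: float = 10.0,
    smooth_time: float = 1.0,
    min_edge_points: int = 5,
) -> ThresholdResult:
    """Heat-activation threshold from a monotone heating ramp.

    log10 |I| is fitted against 1/T (Kelvin) with a continuous two-segment
    line; the breakpoint is scanned over the sample grid and the candidate
    with minimal squared error wins, then is mapped back to °C.  The
    breakpoint must improve on a single line by at least ``min_f_ratio``
    (F-statistic), otherwise a "no threshold" result is returned.  The
    current is smoothed with a ``smooth_time``-second moving average before
    the log transform.  Invariant to scaling the current by a positive
    constant.
    """
    T = trace.temperature
    ramp_end = int(np.argmax(T)) + 1
    t = trace.time[:ramp_end]
    y = trace.current[:ramp_end]
    Tr = T[:ramp_end]
    if len(t) < 2 * min_edge_points + 2:
        raise ValueError("ramp too short for breakpoint detection")
    if np.ptp(Tr) < 15.0:
        raise ValueError(
            f"heating ramp spans {np.ptp(Tr):.1f} °C; need >= 15 °C"
        )
    if smooth_time > 0 and len(t) > 2:
        dt = float(np.median(np.diff(t)))
        w = max(1, int(round(smooth_time / dt)))
        if w > 1:
            y = uniform_filter1d(y, w, mode="nearest")
    eps = 1e-9 * max(float(np.max(np.abs(y))), 1.0)
    logI = np.log10(np.maximum(np.abs(y), eps))
    x = 1.0 / (Tr + 273.15)
    order = np.argsort(x)
    x, logI = x[order], logI[order]

    # Single-line reference.
    A1 = np.column_stack([np.ones_like(x), x])
    coef1, res1, *_ = np.linalg.lstsq(A1, logI, rcond=None)
    sse1 = float(res1[0]) if len(res1) else float(
        np.sum((logI - A1 @ coef1) ** 2))
    if sse1 <= 1e-10:
        # a single Arrhenius line already explains the data exactly
        return ThresholdResult(None, False, (float(coef1[1]), float(coef1[0])),
                               (float(coef1[1]), float(coef1[0])), 0.0, len(x))

    best = (np.inf, None, None)
    for k in range(min_edge_points, len(x) - min_edge_points):
        xb = x[k]
        hinge = np.maximum(0.0, x - xb)
        A = np.column_stack([np.ones_like(x), x, hinge])
        coef, res, *_ = np.linalg.lstsq(A, logI, rcond=None)
        sse = float(res[0]) if len(res) else float(
            np.sum((logI - A @ coef) ** 2))
        if sse < best[0]:
            best = (sse, xb, coef)
    sse2, xb, coef = best
    dof = len(x) - 4  # intercept, slope, slope change, breakpoint
    f_ratio = ((sse1 - sse2) / 2) / (sse2 / max(dof, 1)) if sse2 > 0 \
        else np.inf
    # Hot side is small x (< xb); the hinge adds slope on the cold side.
    slope_hot, icpt_hot = float(coef[1]), float(coef[0])
    slope_cold = float(coef[1] + coef[2])
    icpt_cold = float(coef[0] - coef[2] * xb)
    if f_ratio < min_f_ratio:
        return ThresholdResult(None, False, (slope_cold, icpt_cold),
                               (slope_hot, icpt_hot), float(f_ratio), len(x))
    threshold_C = 1.0 / xb - 273.15
    return ThresholdResult(float(threshold_C), True,
                           (slope_cold, icpt_cold), (slope_hot, icpt_hot),
                           float(f_ratio), len(x))


# ---------------------------------------------------------------------------
# Emission spectra
# ---------------------------------------------------------------------------

def skew_gauss(wl, amplitude, location, scale, shape, baseline=0.0):
    """Skew-normal peak: A·e^{−(λ−ξ)²/2ω²}·(1 + erf(α(λ−ξ)/ω√2)) + b."""
    z = (wl - location) / scale
    return amplitude * np.exp(-0.5 * z**2) \
        * (1.0 + erf(shape * z / np.sqrt(2))) + baseline


def fit_skew_gauss(spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Fit a skew-Gaussian peak and locate λmax on a 0.1 nm grid.

    Returns a new :class:`EmissionSpectrum` with the ``fit`` field
    populated; on non-convergence the fit carries ``success=False``.
    """
    wl = spectrum.wavelength
    y = spectrum.intensity
    if len(wl) < 20:
        raise ValueError("need at least 20 wavelength points")
    baseline0 = float(np.min(y))
    amp0 = float(np.max(y) - baseline0)
    loc0 = float(wl[int(np.argmax(y))])
    above = wl[y - baseline0 > amp0 / 2]
    scale0 = max(float(above[-1] - above[0]) / 2.355, 1.0) if len(above) > 1 \
        else float(np.ptp(wl)) / 6
    model = lmfit.Model(skew_gauss, independent_vars=["wl"])
    params = model.make_params(
        amplitude=dict(value=amp0, min=0),
        location=loc0,
        scale=dict(value=scale0, min=1e-3),
        shape=0.0,
        baseline=baseline0,
    )
    try:
        result = model.fit(y, params, wl=wl)
        success = bool(result.success)
    except Exception:
        result = None
        success = False
    if not success or result is None:
        fit = SkewGaussFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           np.nan, False)
        return EmissionSpectrum(wl, y, fit, spectrum.spec)
    p = {k: float(v.value) for k, v in result.params.items()}
    grid = np.arange(wl[0], wl[-1] + 0.05, 0.1)
    curve = skew_gauss(grid, p["amplitude"], p["location"], p["scale"],
                       p["shape"], 0.0)
    lambda_max = float(grid[int(np.argmax(curve))])
    fit = SkewGaussFit(
        p["amplitude"], p["location"], p["scale"], p["shape"], p["baseline"],
        lambda_max, float(np.sqrt(np.mean(result.residual**2))), True,
    )
    return EmissionSpectrum(wl, y, fit, spectrum.spec)


def spectral_ratio(
    spectrum: EmissionSpectrum,
    donor_band: tuple[float, float],
    acceptor_band: tuple[float, float],
    background: float = 0.0,
) -> float:
    """Acceptor/donor ratio of background-subtracted band integrals.

    Bands are (λ_lo, λ_hi) in nm, must lie within the spectrum and must not
    overlap.  Raises if the donor integral is non-positive after background
    subtraction.
    """
    wl = spectrum.wavelength
    for name, (lo, hi) in (("donor", donor_band), ("acceptor", acceptor_band)):
        if lo >= hi:
            raise ValueError(f"{name} band is empty")
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError(f"{name} band outside the wavelength range")
    if not (donor_band[1] <= acceptor_band[0]
            or acceptor_band[1] <= donor_band[0]):
        raise ValueError("donor and acceptor bands overlap")

    def integral(band):
        lo, hi = band
        mask = (wl >= lo) & (wl <= hi)
        return float(np.trapezoid(spectrum.intensity[mask] - background,
                                  wl[mask]))

    donor = integral(donor_band)
    if donor <= 0:
        raise ValueError("donor band integral non-positive after background "
                         "subtraction")
    return integral(acceptor_band) / donor


# ---------------------------------------------------------------------------
# FRET ratio correction
# ---------------------------------------------------------------------------

def correct_fret_ratio(
    raw: FretTimeCourse, control: FretTimeCourse
) -> FretTimeCourse:
    """Divide out the temperature dependence measured on a control construct.

    corrected(t) = raw(t) / control_ratio(T(t)), with the control's
    temperature–ratio relation linearly interpolated.  Temperatures outside
    the control's range are an error (no extrapolation).
    """
    order = np.argsort(control.temperature)
    cT = control.temperature[order]
    cR = control.ratio[order]
    lo, hi = cT[0], cT[-1]
    if np.any(raw.temperature < lo - 1e-9) \
            or np.any(raw.temperature > hi + 1e-9):
        raise ValueError(
            f"trace temperature range [{raw.temperature.min():.2f}, "
            f"{raw.temperature.max():.2f}] °C exceeds control range "
            f"[{lo:.2f}, {hi:.2f}] °C"
        )
    corrected = raw.ratio / np.interp(raw.temperature, cT, cR)
    return FretTimeCourse(raw.time, raw.ratio, raw.temperature,
                          corrected=corrected, spec=raw.spec)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace(path) -> CurrentTrace:
    """Read a headered TSV/CSV with columns time, current, temperature."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return CurrentTrace(df["time"].to_numpy(), df["current"].to_numpy(),
                        df["temperature"].to_numpy())


def write_trace(trace: CurrentTrace, path) -> None:
    pd.DataFrame({
        "time": trace.time,
        "current": trace.current,
        "temperature": trace.temperature,
    }).to_csv(path, sep="\t", index=False)


def read_spectrum(path) -> EmissionSpectrum:
    """Read a headered TSV/CSV with columns wavelength, intensity."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return EmissionSpectrum(df["wavelength"].to_numpy(),
                            df["intensity"].to_numpy())


def fit_to_json(fit, path) -> None:
    """Serialise any of the result dataclasses to JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    with open(path, "w") as fh:
        json.dump(asdict(fit), fh, indent=2, default=default)
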
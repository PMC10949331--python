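"""Circular-dichroism and FTIR analysis.

CD: conversion of raw ellipticity to mean residue ellipticity (MRE),
helix fraction from MRE at 222 nm, linear decomposition of a spectrum
into helix/sheet/coil basis spectra, and two-state thermal melt fits.

FTIR: three-Gaussian decomposition of the amide-I' band (beta-sheet
low/high wings plus an unordered/helical centre), and hydrogen-
deuterium-exchange kinetics from the amide-II' band area.

Formulas
--------
MRE [deg cm^2 dmol^-1 res^-1] = theta[mdeg] * 100 / (c[mM] * l[cm] * b)

Fraction helix (%) = 100 * (MRE222 - MRE_coil)
                     / (-42500 * (1 - 3/n) - MRE_coil),
MRE_coil = 640 - 45*T  (T in degC, n = number of amide bonds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy.optimize import nnls, minimize
from scipy.signal import savgol_filter

from gelkit.io import KineticTrace, Spectrum, ValidationError

logger = logging.getLogger("gelkit")

#: amide-I' three-component windows (1/cm): centre must land inside.
AMIDE_WINDOWS = {
    "beta_low": (1619.0, 1628.0),
    "unordered": (1644.0, 1648.0),
    "beta_high": (1676.0, 1688.0),
}
AMIDE_I_RANGE = (1600.0, 1700.0)
AMIDE_II_RANGE = (1400.0, 1500.0)


# ---------------------------------------------------------------------------
# CD


def mre_convert(spec: Spectrum, c_mM: float, l_cm: float, n_bonds: int) -> Spectrum:
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    MRE = theta * 100 / (c * l * b) pointwise, with c the millimolar
    concentration, l the path length in cm and b the number of amide
    bonds.
    """
    if c_mM <= 0 or l_cm <= 0 or n_bonds <= 0:
        raise ValidationError("c, l and bond count must all be positive")
    factor = 100.0 / (c_mM * l_cm * n_bonds)
    meta = dict(spec.meta)
    meta["units"] = "MRE"
    return Spectrum(spec.abscissa.copy(), spec.signal * factor, meta)


def mre_coil(T: float) -> float:
    """Random-coil MRE at 222 nm: 640 - 45*T (T in degC)."""
    return 640.0 - 45.0 * T


def fraction_helix(mre222: float, T: float, n_bonds: int) -> float:
    """Percent helix from MRE at 222 nm (temperature-corrected coil baseline)."""
    if n_bonds <= 3:
        raise ValidationError("bond count must exceed 3")
    coil = mre_coil(T)
    full = -42500.0 * (1.0 - 3.0 / n_bonds)
    return 100.0 * (mre222 - coil) / (full - coil)


def synthetic_basis_spectra(wavelengths=None) -> dict:
    """Synthetic helix/sheet/coil CD basis spectra (not measured references).

    Parametric Gaussian-band idealisations of the canonical far-UV CD
    shapes: helix with a positive ~192 nm band and minima at 208 and
    222 nm; sheet with a ~195 nm maximum and a single ~217 nm minimum;
    coil dominated by a deep ~198 nm minimum.  Amplitudes are on the MRE
    scale.  These are synthetic stand-ins for published reference sets
    and serve deconvolution tests and demos; swap in measured basis
    spectra for real samples.
    """
    wl = np.arange(190.0, 251.0, 1.0) if wavelengths is None else np.asarray(wavelengths, float)

    def bands(*parts):
        y = np.zeros_like(wl)
        for center, width, amp in parts:
            y += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return y

    helix = bands((192, 6, 65000), (208, 7, -36000), (222, 8, -37000))
    sheet = bands((195, 7, 35000), (217, 9, -20000))
    coil = bands((198, 7, -40000), (220, 12, 2500))
    return {
        "helix": Spectrum(wl, helix, {"basis": "synthetic"}),
        "sheet": Spectrum(wl, sheet, {"basis": "synthetic"}),
        "coil": Spectrum(wl, coil, {"basis": "synthetic"}),
    }


def cd_deconvolve(mre_spectrum: Spectrum, basis: dict, simplex: bool = False) -> dict:
    """Decompose an MRE spectrum into non-negative basis-spectrum fractions.

    Basis spectra are resampled onto the spectrum's wavelength grid.
    Default is unconstrained-sum non-negative least squares; with
    ``simplex=True`` the coefficients are additionally constrained to
    sum to 1.

    Raises on a rank-deficient basis.
    """
    spec = mre_spectrum.ascending()
    wl = spec.abscissa
    names = list(basis)
    A = np.column_stack(
        [np.interp(wl, b.ascending().abscissa, b.ascending().signal) for b in basis.values()]
    )
    if np.linalg.matrix_rank(A) < len(names):
        raise ValidationError("basis spectra are rank-deficient on this grid")
    y = spec.signal
    if not simplex:
        coef, _ = nnls(A, y)
    else:
        x0, _ = nnls(A, y)
        s = x0.sum()
        x0 = x0 / s if s > 0 else np.full(len(names), 1.0 / len(names))
        res = minimize(
            lambda x: float(np.sum((A @ x - y) ** 2)),
            x0,
            jac=lambda x: 2.0 * A.T @ (A @ x - y),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(names),
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
        )
        coef = res.x
    return dict(zip(names, (float(c) for c in coef)))


# ---------------------------------------------------------------------------
# thermal melts


@dataclass(frozen=True)
class MeltFit:
    """Single-ramp two-state melt fit (sigmoid with linear baselines)."""

    tm: float | None
    width: float | None
    direction: str
    amplitude: float
    residual_sd: float
    flagged: bool
    params: dict

    def transition_detected(self) -> bool:
        return not self.flagged


@dataclass(frozen=True)
class MeltResult:
    """Paired heating/cooling melt with hysteresis |Tm_heat - Tm_cool| (degC)."""

    heating: MeltFit
    cooling: MeltFit
    hysteresis: float | None

    def summary(self) -> str:
        def one(f: MeltFit) -> str:
            if f.flagged:
                return f"  {f.direction:8s}: no transition detected (amplitude {f.amplitude:.3g} < 3x noise)"
            return f"  {f.direction:8s}: Tm = {f.tm:.2f} degC (width {f.width:.2f})"

        lines = ["Thermal melt", one(self.heating), one(self.cooling)]
        if self.hysteresis is not None:
            lines.append(f"  hysteresis: {self.hysteresis:.2f} degC")
        return "\n".join(lines)


class ThermalMeltModel:
    """Two-state melt fit of a signal-vs-temperature ramp.

    Model: y(T) = folded_baseline(T) * f(T) + unfolded_baseline(T) * (1 - f(T)),
    with f = 1/(1 + exp((T - Tm)/w)) and linear baselines.  Tm is the
    inflection point.  If the fitted amplitude at Tm is below 3x the
    residual SD the result is flagged (no transition), not raised.
    """

    def __init__(self, temperature, signal, direction: str = "heating"):
        T = np.asarray(temperature, dtype=float)
        y = np.asarray(signal, dtype=float)
        if T.size != y.size:
            raise ValidationError("temperature and signal lengths differ")
        if T.size < 10:
            raise ValidationError("need at least 10 temperature points")
        order = np.argsort(T)
        self.T, self.y = T[order], y[order]
        self.direction = direction

    def fit(self) -> MeltFit:
        T, y = self.T, self.y
        p = lmfit.Parameters()
        n4 = max(3, len(T) // 4)
        af, bf = np.polyfit(T[:n4], y[:n4], 1)[::-1]
        au, bu = np.polyfit(T[-n4:], y[-n4:], 1)[::-1]
        p.add("tm", value=float(T[np.argmax(np.abs(np.gradient(y, T)))]), min=T[0], max=T[-1])
        p.add("width", value=(T[-1] - T[0]) / 20.0, min=1e-3, max=(T[-1] - T[0]))
        p.add("af", value=af)
        p.add("bf", value=bf)
        p.add("au", value=au)
        p.add("bu", value=bu)

        def model(pars):
            f = 1.0 / (1.0 + np.exp((T - pars["tm"].value) / pars["width"].value))
            folded = pars["af"].value + pars["bf"].value * T
            unfolded = pars["au"].value + pars["bu"].value * T
            return folded * f + unfolded * (1.0 - f)

        out = lmfit.minimize(lambda pars: model(pars) - y, p, method="leastsq")
        v = {k: float(out.params[k].value) for k in out.params}
        resid_sd = float(np.std(model(out.params) - y))
        amplitude = abs((v["au"] + v["bu"] * v["tm"]) - (v["af"] + v["bf"] * v["tm"]))
        flagged = amplitude < 3.0 * resid_sd
        return MeltFit(
            tm=None if flagged else v["tm"],
            width=None if flagged else v["width"],
            direction=self.direction,
            amplitude=amplitude,
            residual_sd=resid_sd,
            flagged=flagged,
            params=v,
        )


def melt_analysis(heating, cooling) -> MeltResult:
    """Fit heating and cooling ramps; each is (temperature, signal) arrays."""
    heat = ThermalMeltModel(*heating, direction="heating").fit()
    cool = ThermalMeltModel(*cooling, direction="cooling").fit()
    hyst = None
    if heat.transition_detected() and cool.transition_detected():
        hyst = abs(heat.tm - cool.tm)
    return MeltResult(heating=heat, cooling=cool, hysteresis=hyst)


# ---------------------------------------------------------------------------
# FTIR amide-I' decomposition


@dataclass(frozen=True)
class AmideBandFit:
    """Three-Gaussian amide-I' decomposition: bands and fractional areas."""

    bands: dict  # name -> {"center", "width", "area"}
    fractions: dict  # name -> fractional area
    baseline: tuple
    redchi: float
    success: bool

    def summary(self) -> str:
        lines = ["Amide-I' three-Gaussian decomposition"]
        for name, b in self.bands.items():
            lines.append(
                f"  {name:10s}: center {b['center']:.1f} 1/cm, width {b['width']:.1f},"
                f" fraction {self.fractions[name]:.3f}"
            )
        lines.append(f"  red-chi2: {self.redchi:.4g}   converged: {self.success}")
        return "\n".join(lines)


def _derivative_seeds(spec: Spectrum, windows: dict) -> dict:
    """Candidate band centres from smoothed 2nd-derivative minima and
    4th-derivative maxima, constrained to the assignment windows."""
    x, y = spec.abscissa, spec.signal
    dx = float(np.mean(np.diff(x)))
    win = max(5, 2 * int(2.0 / abs(dx)) + 1)  # ~4 1/cm smoothing window
    if win >= len(x):
        win = len(x) - 1 if (len(x) - 1) % 2 == 1 else len(x) - 2
    d2 = savgol_filter(y, win, polyorder=4, deriv=2, delta=dx)
    d4 = savgol_filter(y, win, polyorder=5 if win > 5 else 4, deriv=4, delta=dx)
    seeds = {}
    for name, (lo, hi) in windows.items():
        mask = (x >= lo) & (x <= hi)
        if not np.any(mask):
            continue
        c2 = x[mask][np.argmin(d2[mask])]
        c4 = x[mask][np.argmax(d4[mask])]
        seeds[name] = 0.5 * (c2 + c4)
    return seeds


class AmideBandModel:
    """Derivative-seeded least-squares fit of three Gaussians to the amide-I' band.

    Band centres are seeded from the Savitzky-Golay-smoothed second-
    derivative minima and fourth-derivative maxima and constrained to
    their assignment windows during the fit.  An optional linear
    baseline is co-fit.
    """

    def __init__(self, spec: Spectrum, windows: dict | None = None, fit_baseline: bool = True):
        self.spec = spec.ascending()
        self.windows = dict(windows or AMIDE_WINDOWS)
        self.fit_baseline = fit_baseline
        x = self.spec.abscissa
        if x[0] > AMIDE_I_RANGE[0] + 5 or x[-1] < AMIDE_I_RANGE[1] - 5:
            raise ValidationError(
                f"spectrum [{x[0]}, {x[-1]}] does not cover the amide-I' range {AMIDE_I_RANGE}"
            )

    def fit(self) -> AmideBandFit:
        spec = self.spec
        x, y = spec.abscissa, spec.signal
        seeds = _derivative_seeds(spec, self.windows)
        if len(seeds) < len(self.windows):
            missing = sorted(set(self.windows) - set(seeds))
            raise ValidationError(
                f"fewer than {len(self.windows)} candidate centres found "
                f"(missing {missing}); consider relaxing the windows"
            )
        p = lmfit.Parameters()
        amp0 = max(float(y.max()), 1e-12)
        for name, (lo, hi) in self.windows.items():
            p.add(f"{name}_center", value=seeds[name], min=lo, max=hi)
            p.add(f"{name}_sigma", value=6.0, min=1.0, max=40.0)
            p.add(f"{name}_amp", value=0.5 * amp0, min=0.0)
        p.add("base_a", value=float(y.min()), vary=self.fit_baseline)
        p.add("base_b", value=0.0, vary=self.fit_baseline)

        def model(pars):
            out = pars["base_a"].value + pars["base_b"].value * (x - x.mean())
            for name in self.windows:
                c = pars[f"{name}_center"].value
                s = pars[f"{name}_sigma"].value
                a = pars[f"{name}_amp"].value
                out = out + a * np.exp(-0.5 * ((x - c) / s) ** 2)
            return out

        out = lmfit.minimize(lambda pars: model(pars) - y, p, method="leastsq")
        bands, total = {}, 0.0
        for name in self.windows:
            c = float(out.params[f"{name}_center"].value)
            s = float(out.params[f"{name}_sigma"].value)
            a = float(out.params[f"{name}_amp"].value)
            area = a * s * np.sqrt(2.0 * np.pi)
            bands[name] = {"center": c, "width": s, "area": area}
            total += area
        if total <= 0:
            raise ValidationError("all fitted band areas are zero")
        fractions = {name: b["area"] / total for name, b in bands.items()}
        return AmideBandFit(
            bands=bands,
            fractions=fractions,
            baseline=(float(out.params["base_a"].value), float(out.params["base_b"].value)),
            redchi=float(out.redchi),
            success=bool(out.success),
        )


def ftir_band_decompose(
    spec: Spectrum, windows: dict | None = None, fit_baseline: bool = True
) -> AmideBandFit:
    """Functional wrapper around :class:`AmideBandModel`."""
    return AmideBandModel(spec, windows=windows, fit_baseline=fit_baseline).fit()


# ---------------------------------------------------------------------------
# HDX kinetics from the amide-II' band


def band_area(spec: Spectrum, window: tuple) -> float:
    """Band area after subtracting the straight baseline between the
    minima on either side of the band peak inside ``window``."""
    s = spec.ascending()
    x, y = s.abscissa, s.signal
    mask = (x >= window[0]) & (x <= window[1])
    if mask.sum() < 5:
        raise ValidationError(f"window {window} covers fewer than 5 points")
    xs, ys = x[mask], y[mask]
    peak = int(np.argmax(ys))
    if peak == 0 or peak == len(ys) - 1:
        # no interior peak: treat as flat/no band
        return 0.0
    left = int(np.argmin(ys[: peak + 1]))
    right = peak + int(np.argmin(ys[peak:]))
    if right <= left + 1:
        return 0.0
    xl, xr = xs[left], xs[right]
    yl, yr = ys[left], ys[right]
    baseline = yl + (yr - yl) * (xs[left : right + 1] - xl) / (xr - xl)
    return float(np.trapezoid(ys[left : right + 1] - baseline, xs[left : right + 1]))


def hdx_kinetics(
    spectra_time_series,
    times,
    amide_ii_window: tuple = AMIDE_II_RANGE,
    amide_i_window: tuple = AMIDE_I_RANGE,
    fit_exponential: bool = False,
):
    """H/D-exchange trace: amide-II' area normalized to amide-I' area per time point.

    Each spectrum must cover both bands.  The normalization makes the
    trace invariant to global intensity rescaling.  With
    ``fit_exponential=True`` the trace is additionally fit to
    y(t) = y_inf + (y0 - y_inf) * exp(-k t) and the rate is reported.

    Returns (KineticTrace, fit-dict-or-None).
    """
    times = np.asarray(times, dtype=float)
    values = []
    for idx, spec in enumerate(spectra_time_series):
        a2 = band_area(spec, amide_ii_window)
        a1 = band_area(spec, amide_i_window)
        if a1 <= 0:
            raise ValidationError(f"time point {idx}: amide-I' band not found")
        values.append(a2 / a1)
    trace = KineticTrace(times, np.array(values))
    fit = None
    if fit_exponential:
        p = lmfit.Parameters()
        y0, yinf = trace.y[0], trace.y[-1]
        p.add("y0", value=y0)
        p.add("yinf", value=yinf)
        span = trace.t[-1] - trace.t[0]
        p.add("k", value=2.0 / span if span > 0 else 1.0, min=1e-12)

        def resid(pars):
            model = pars["yinf"].value + (pars["y0"].value - pars["yinf"].value) * np.exp(
                -pars["k"].value * trace.t
            )
            return model - trace.y

        out = lmfit.minimize(resid, p, method="leastsq")
        fit = {
            "k": float(out.params["k"].value),
            "k_stderr": float(out.params["k"].stderr) if out.params["k"].stderr else None,
            "y0": float(out.params["y0"].value),
            "yinf": float(out.params["yinf"].value),
            "success": bool(out.success),
        }
    return trace, fit
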
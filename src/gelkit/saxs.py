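"""SAXS analysis: Guinier and Kratky transforms, the composite
gel-network scattering model, and ensemble-histogram summary statistics.

The gel model superposes three components over the measured q-range:

    I(q) = A1 / (1 + (q*zeta)^dim)          Lorentzian-like mesh term,
                                            zeta = correlation length
                                            (mesh size inside fibers)
         + A2 * q^(-pl_exp)                 low-q power law from the
                                            fiber/void interface
         + A3 / (1 + ((q - q0)/B)^2)        Lorentzian diffraction peak
                                            from the fiber repeat

q is in 1/Angstrom; real-space outputs (zeta, the repeat spacing
2*pi/q0) are reported in nm.  The peak width B is conventionally held
fixed during fitting so the amplitude A3 is well determined across a
concentration series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import lmfit

from gelkit.io import NM_PER_ANGSTROM, ScatteringCurve, ValidationError

logger = logging.getLogger("gelkit")

TWO_PI = 2.0 * np.pi


class NoGuinierRegimeError(ValueError):
    """The low-q data do not show a decaying Guinier region."""


@dataclass(frozen=True)
class GuinierResult:
    """Guinier fit output: Rg (nm), forward intensity, window diagnostics."""

    rg_nm: float
    i0: float
    q_window: tuple
    qrg_max: float
    n_points: int
    rg_stderr_nm: float
    r_squared: float

    def summary(self) -> str:
        return (
            "Guinier fit\n"
            f"  Rg           : {self.rg_nm:.3f} +/- {self.rg_stderr_nm:.3f} nm\n"
            f"  I(0)         : {self.i0:.4g}\n"
            f"  q window     : [{self.q_window[0]:.4g}, {self.q_window[1]:.4g}] 1/A"
            f" ({self.n_points} pts, q_max*Rg <= {self.qrg_max})\n"
            f"  linearity R^2: {self.r_squared:.5f}"
        )


class GuinierModel:
    """Weighted linear fit of ln I vs q^2 in the low-q (Guinier) window.

    The window starts from the 5 lowest-q points and grows while
    q_max * Rg stays below ``qrg_max`` (default 1.3, the conventional
    bound for disordered chains).
    """

    def __init__(self, curve: ScatteringCurve, qrg_max: float = 1.3):
        self.curve = curve
        self.qrg_max = qrg_max

    def _linfit(self, n: int):
        q = self.curve.q[:n]
        i = self.curve.intensity[:n]
        if np.any(i <= 0):
            raise NoGuinierRegimeError("non-positive intensity in Guinier window")
        x, y = q**2, np.log(i)
        if self.curve.sigma is not None:
            w = (i / self.curve.sigma[:n]) ** 2  # var(ln I) = (sigma/I)^2
        else:
            w = np.ones_like(y)
        W = w.sum()
        xbar, ybar = (w * x).sum() / W, (w * y).sum() / W
        sxx = (w * (x - xbar) ** 2).sum()
        slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        dof = max(n - 2, 1)
        s2 = (w * resid**2).sum() / dof
        slope_var = s2 / sxx
        ss_tot = (w * (y - ybar) ** 2).sum()
        r2 = 1.0 - (w * resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
        return slope, intercept, slope_var, r2

    def fit(self, min_points: int = 5) -> GuinierResult:
        curve = self.curve
        if len(curve) < min_points:
            raise ValidationError(f"need at least {min_points} points")
        best = None
        over_bound = 0
        for n in range(min_points, len(curve) + 1):
            slope, intercept, slope_var, r2 = self._linfit(n)
            if slope >= 0:
                # a positive slope on a small noisy window is inconclusive;
                # keep growing and decide at the end
                continue
            rg_ang = float(np.sqrt(-3.0 * slope))
            if curve.q[n - 1] * rg_ang > self.qrg_max:
                over_bound += 1
                if over_bound >= 3 and best is not None:
                    break
                continue
            over_bound = 0
            rg_err_ang = (
                float(1.5 * np.sqrt(slope_var) / rg_ang) if slope_var > 0 else 0.0
            )
            best = GuinierResult(
                rg_nm=rg_ang * NM_PER_ANGSTROM,
                i0=float(np.exp(intercept)),
                q_window=(float(curve.q[0]), float(curve.q[n - 1])),
                qrg_max=self.qrg_max,
                n_points=n,
                rg_stderr_nm=rg_err_ang * NM_PER_ANGSTROM,
                r_squared=float(r2),
            )
        if best is None:
            raise NoGuinierRegimeError("no window satisfies q_max * Rg <= qrg_max")
        logger.info("Guinier fit: Rg=%.3f nm over %d points", best.rg_nm, best.n_points)
        return best


def kratky_transform(curve: ScatteringCurve):
    """Pointwise Kratky transform (q, q^2 * I(q)); no smoothing applied."""
    return curve.q.copy(), curve.q**2 * curve.intensity


# ---------------------------------------------------------------------------
# composite gel model


def gel_model_eval(params: dict, q_grid) -> np.ndarray:
    """Evaluate the three-component gel scattering model on a q grid (1/A).

    ``params`` keys: A1, zeta_nm, dim, A2, pl_exp, A3, q0, B.
    zeta is in nm (converted internally); q0 and B in 1/A.
    """
    q = np.asarray(q_grid, dtype=float)
    zeta_ang = params["zeta_nm"] / NM_PER_ANGSTROM
    lorentz = params["A1"] / (1.0 + (q * zeta_ang) ** params["dim"])
    powerlaw = params["A2"] * q ** (-params["pl_exp"])
    peak = params["A3"] / (1.0 + ((q - params["q0"]) / params["B"]) ** 2)
    return lorentz + powerlaw + peak


@dataclass(frozen=True)
class GelFitResult:
    """Fitted gel-model parameters with uncertainties and diagnostics."""

    params: dict
    stderr: dict
    spacing_nm: float
    redchi: float
    success: bool
    lmfit_result: object = None

    @property
    def zeta_nm(self) -> float:
        return self.params["zeta_nm"]

    @property
    def q0(self) -> float:
        return self.params["q0"]

    def summary(self) -> str:
        lines = ["Gel scattering model fit"]
        for k in ("A1", "zeta_nm", "dim", "A2", "pl_exp", "A3", "q0", "B"):
            err = self.stderr.get(k)
            err_s = f" +/- {err:.3g}" if err is not None else " (fixed)"
            lines.append(f"  {k:8s}: {self.params[k]:.5g}{err_s}")
        lines.append(f"  spacing : {self.spacing_nm:.3f} nm (= 2*pi/q0)")
        lines.append(f"  red-chi2: {self.redchi:.4g}   converged: {self.success}")
        return "\n".join(lines)


class GelScatteringModel:
    """Nonlinear least-squares fit of the composite gel model to a curve.

    Initialization heuristics: q0 from the residual peak after a smooth
    power-law background estimate; zeta from the q where the high-q
    Lorentzian term falls to half its plateau.  B is fixed by default
    (pass ``fix_B=False`` to float it).
    """

    PARAM_NAMES = ("A1", "zeta_nm", "dim", "A2", "pl_exp", "A3", "q0", "B")

    def __init__(self, curve: ScatteringCurve, init: dict | None = None, fix_B: bool = True):
        self.curve = curve
        self.fix_B = fix_B
        self.init = self._default_init()
        if init:
            self.init.update(init)

    def _default_init(self) -> dict:
        q, i = self.curve.q, self.curve.intensity
        # crude power-law background from the low-q decade
        nlow = max(5, len(q) // 10)
        slope = np.polyfit(np.log(q[:nlow]), np.log(np.clip(i[:nlow], 1e-300, None)), 1)[0]
        pl_exp = float(np.clip(-slope, 0.5, 4.5))
        a2 = float(np.exp(np.median(np.log(i[:nlow]) + pl_exp * np.log(q[:nlow]))))
        resid = i - a2 * q ** (-pl_exp)
        # peak guess from the most positive residual in the upper half
        upper = q > np.median(q)
        if np.any(resid[upper] > 0):
            q0 = float(q[upper][np.argmax(resid[upper])])
        else:
            q0 = float(q[int(0.75 * len(q))])
        a1 = float(max(np.median(i[upper]), 1e-12))
        return {
            "A1": a1,
            "zeta_nm": 2.5,
            "dim": 2.0,
            "A2": a2,
            "pl_exp": pl_exp,
            "A3": float(max(resid.max(), a1 / 10)),
            "q0": q0,
            "B": 0.01,
        }

    #: correlation-length starting values for the multi-start search; the
    #: Lorentzian term's chi^2 surface is multimodal in (zeta, dim)
    ZETA_STARTS_NM = (1.0, 2.0, 3.0, 4.5)

    def fit(self) -> GelFitResult:
        best = None
        for zeta0 in self.ZETA_STARTS_NM:
            try:
                candidate = self._fit_once(dict(self.init, zeta_nm=zeta0))
            except RuntimeError:
                continue
            if best is None or candidate.redchi < best.redchi:
                best = candidate
        if best is None:
            raise RuntimeError(
                "gel model fit failed from every start; consider freezing dim or pl_exp"
            )
        logger.info(
            "gel fit: zeta=%.3f nm q0=%.4g 1/A spacing=%.2f nm redchi=%.3g",
            best.params["zeta_nm"],
            best.params["q0"],
            best.spacing_nm,
            best.redchi,
        )
        return best

    def _fit_once(self, init: dict) -> GelFitResult:
        curve = self.curve
        p = lmfit.Parameters()
        qmin, qmax = float(curve.q[0]), float(curve.q[-1])
        p.add("A1", value=init["A1"], min=0)
        p.add("zeta_nm", value=init["zeta_nm"], min=1e-3)
        p.add("dim", value=init["dim"], min=0.3, max=6)
        p.add("A2", value=init["A2"], min=0)
        p.add("pl_exp", value=init["pl_exp"], min=0.1, max=5)
        p.add("A3", value=init["A3"], min=0)
        p.add("q0", value=init["q0"], min=qmin, max=qmax)
        p.add("B", value=init["B"], min=1e-5, vary=not self.fix_B)

        # intensities span decades: weight by sigma when measured, else
        # fall back to relative residuals
        if curve.sigma is not None:
            weights = 1.0 / curve.sigma
        else:
            weights = 1.0 / np.maximum(np.abs(curve.intensity), 1e-300)

        def residual(pars):
            vals = {k: pars[k].value for k in self.PARAM_NAMES}
            return (gel_model_eval(vals, curve.q) - curve.intensity) * weights

        try:
            out = lmfit.minimize(residual, p, method="leastsq")
        except Exception as exc:  # singular Jacobian and friends
            raise RuntimeError(
                f"gel model fit failed ({exc}); consider freezing dim or pl_exp"
            ) from exc
        vals = {k: float(out.params[k].value) for k in self.PARAM_NAMES}
        errs = {
            k: (float(out.params[k].stderr) if out.params[k].stderr is not None else None)
            for k in self.PARAM_NAMES
            if out.params[k].vary
        }
        spacing_nm = TWO_PI / vals["q0"] * NM_PER_ANGSTROM
        return GelFitResult(
            params=vals,
            stderr=errs,
            spacing_nm=float(spacing_nm),
            redchi=float(out.redchi),
            success=bool(out.success),
            lmfit_result=out,
        )


# ---------------------------------------------------------------------------
# ensemble-histogram statistics


@dataclass(frozen=True)
class EomStats:
    """Mean and population SD of an Rg probability histogram (nm)."""

    mean_rg: float
    sd_rg: float
    histogram: tuple


def eom_stats(histogram) -> EomStats:
    """Mean and SD of an Rg histogram: <Rg> = sum Rg*P(Rg), population SD.

    ``histogram`` is a sequence of (rg_nm, probability) pairs; the
    probabilities must be non-negative and sum to 1 within 1e-6 (they
    are renormalized inside that tolerance).
    """
    pairs = [(float(r), float(p)) for r, p in histogram]
    rg = np.array([r for r, _ in pairs])
    prob = np.array([p for _, p in pairs])
    if np.any(prob < 0):
        raise ValidationError("negative probability in histogram")
    total = prob.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"probabilities sum to {total}, not 1")
    prob = prob / total
    mean = float(np.sum(rg * prob))
    var = float(np.sum(rg**2 * prob) - mean**2)
    return EomStats(mean_rg=mean, sd_rg=float(np.sqrt(max(var, 0.0))), histogram=tuple(pairs))
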
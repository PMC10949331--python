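"""Bayesian/Maximum-Entropy (BME) reweighting of a conformer ensemble
against an experimental scattering curve.

The frame weights w minimize

    L(w) = 1/2 * chi^2(w) - theta * S_rel(w),     w on the simplex,

with chi^2 the (unreduced) misfit of the weighted-mean curve to the
experiment and S_rel = -sum_j w_j ln(N w_j) the entropy relative to
uniform weights.  theta trades misfit against how far the weights move
from uniform; the effective frame fraction Phi = exp(S_rel) summarizes
the trade-off (Phi = 1 iff weights are uniform).

Optimization is in the dual: one Lagrange multiplier per data point,

    Gamma(lambda) = theta * ln Z(lambda) + sum_i lambda_i I_i
                    + 1/2 sum_i sigma_i^2 lambda_i^2,
    w_j propto w0_j exp(-sum_i lambda_i F_ij / theta),

which is smooth and convex and solved with L-BFGS-B using the analytic
gradient (I_i - <F_i>_w + sigma_i^2 lambda_i residuals at the optimum).
A scalar intensity scale is re-fit by weighted least squares between
dual solves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from gelkit.io import ScatteringCurve, ValidationError

logger = logging.getLogger("gelkit")


@dataclass(frozen=True)
class ReweightResult:
    """BME output: weights, chi^2 before/after, theta, Phi, intensity scale."""

    weights: np.ndarray
    chi2_before: float
    chi2_after: float
    theta_reg: float
    phi_eff: float
    scale: float
    converged: bool
    n_iter: int

    def summary(self) -> str:
        return (
            "BME reweighting\n"
            f"  theta          : {self.theta_reg:g}\n"
            f"  reduced chi^2  : {self.chi2_before:.4g} -> {self.chi2_after:.4g}\n"
            f"  Phi (effective): {self.phi_eff:.3f}\n"
            f"  scale          : {self.scale:.5g}\n"
            f"  converged      : {self.converged} ({self.n_iter} iterations)"
        )


def _entropy_rel(w: np.ndarray) -> float:
    n = w.size
    nz = w > 0
    return float(-np.sum(w[nz] * np.log(n * w[nz])))


def phi_eff(weights) -> float:
    """Effective frame fraction Phi = exp(S_rel); 1 iff weights uniform."""
    return float(np.exp(_entropy_rel(np.asarray(weights, dtype=float))))


def _fit_scale(mean_curve, experiment: ScatteringCurve) -> float:
    w = 1.0 / experiment.sigma**2
    denom = np.sum(w * mean_curve**2)
    return float(np.sum(w * mean_curve * experiment.intensity) / denom) if denom > 0 else 1.0


def _reduced_chi2(mean_curve, experiment, scale) -> float:
    r = (scale * mean_curve - experiment.intensity) / experiment.sigma
    return float(np.sum(r**2) / len(experiment))


class BMEReweight:
    """Model object for BME reweighting of per-frame curves vs an experiment.

    Parameters
    ----------
    per_frame_curves : (frames, n_q) array
        Calculated scattering per conformer, on the experiment's q grid.
    experiment : ScatteringCurve
        Must carry per-point uncertainties.
    initial_weights : array, optional
        Prior weights w0 (default uniform).
    """

    def __init__(self, per_frame_curves, experiment: ScatteringCurve, initial_weights=None):
        F = np.asarray(per_frame_curves, dtype=float)
        if F.ndim != 2:
            raise ValidationError("per_frame_curves must be 2-D (frames, n_q)")
        if F.shape[1] != len(experiment):
            raise ValidationError(
                f"per-frame curves have {F.shape[1]} q points, experiment has {len(experiment)}"
            )
        if experiment.sigma is None:
            raise ValidationError("experiment must carry sigma for BME")
        self.F = F
        self.experiment = experiment
        if initial_weights is None:
            self.w0 = np.full(F.shape[0], 1.0 / F.shape[0])
        else:
            self.w0 = np.asarray(initial_weights, dtype=float)
            self.w0 = self.w0 / self.w0.sum()

    def _weights_from_lambda(self, lam: np.ndarray, theta: float, scale: float):
        # w_j propto w0_j exp(-sum_i lam_i * scale * F_ij / theta)
        arg = -(self.F * scale) @ lam / theta
        arg -= arg.max()
        w = self.w0 * np.exp(arg)
        return w / w.sum()

    def fit(
        self, theta_reg: float, max_scale_iters: int = 100, tol: float = 1e-10
    ) -> ReweightResult:
        """Solve the dual BME problem at regularization strength ``theta_reg``.

        Non-convergence of the inner optimizer is flagged on the result,
        not raised.
        """
        if theta_reg < 0:
            raise ValidationError("theta must be >= 0")
        exp = self.experiment
        I, sig = exp.intensity, exp.sigma
        mean0 = self.w0 @ self.F
        scale = _fit_scale(mean0, exp)
        chi2_before = _reduced_chi2(mean0, exp, scale)

        if theta_reg == 0:
            theta = 1e-6  # dual needs theta > 0; effectively unregularized
        else:
            theta = float(theta_reg)

        # work in mu = sigma * lambda so the gradient is in units of the
        # standardized residual and tolerances are scale-free
        mu = np.zeros(len(exp))
        converged, n_iter = True, 0
        # alternate dual solves with weighted-least-squares scale refits
        # until the scale stabilizes
        for _ in range(max_scale_iters):
            Fn = (self.F * scale) / sig  # frames x points, sigma-normalized

            def gamma_and_grad(mu):
                arg = -Fn @ mu / theta
                m = arg.max()
                z = self.w0 * np.exp(arg - m)
                Z = z.sum()
                w = z / Z
                mean = w @ Fn
                val = theta * (m + np.log(Z)) + mu @ (I / sig) + 0.5 * mu @ mu
                grad = I / sig - mean + mu
                return val, grad

            res = minimize(
                gamma_and_grad,
                mu,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 20000, "gtol": tol, "ftol": 1e-15},
            )
            mu = res.x
            converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-6
            n_iter += int(res.nit)
            w = self._weights_from_lambda(mu / sig, theta, scale)
            scale_new = _fit_scale(w @ self.F, exp)
            done = abs(scale_new - scale) <= 1e-9 * max(abs(scale), 1e-12)
            scale = scale_new
            if done:
                break

        w = self._weights_from_lambda(mu / sig, theta, scale)
        chi2_after = _reduced_chi2(w @ self.F, exp, scale)
        result = ReweightResult(
            weights=w,
            chi2_before=chi2_before,
            chi2_after=chi2_after,
            theta_reg=float(theta_reg),
            phi_eff=phi_eff(w),
            scale=scale,
            converged=converged,
            n_iter=n_iter,
        )
        logger.info(
            "BME theta=%g: chi2 %.4g -> %.4g, Phi=%.3f",
            theta_reg,
            chi2_before,
            chi2_after,
            result.phi_eff,
        )
        return result


def bme_fit(per_frame_curves, experiment: ScatteringCurve, theta_reg: float) -> ReweightResult:
    """Functional wrapper around :class:`BMEReweight`."""
    return BMEReweight(per_frame_curves, experiment).fit(theta_reg)


def theta_scan(per_frame_curves, experiment: ScatteringCurve, theta_grid):
    """Scan theta and tabulate (theta, reduced chi^2, Phi).

    Returns the table (list of dicts, descending theta) plus an elbow
    pick: the smallest theta beyond which chi^2 has plateaued (relative
    improvement < 5% per step).
    """
    thetas = sorted(float(t) for t in theta_grid)
    if not thetas:
        raise ValidationError("theta grid is empty")
    model = BMEReweight(per_frame_curves, experiment)
    rows = []
    for theta in thetas[::-1]:  # descending
        r = model.fit(theta)
        rows.append({"theta": theta, "chi2": r.chi2_after, "phi": r.phi_eff})
    selected = rows[-1]["theta"]
    for prev, cur in zip(rows, rows[1:]):
        if prev["chi2"] <= 0 or (prev["chi2"] - cur["chi2"]) / prev["chi2"] < 0.05:
            selected = prev["theta"]
            break
    return rows, selected
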
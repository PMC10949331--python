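"""Fiber-assembly geometry and cell-assay statistics.

The necklace model treats a gel fiber as a supercoiled bundle of
coiled-coil dimers: the number of dimers in the bundle cross-section is
the area ratio (bundle diameter / dimer diameter)^2, rounded to the
nearest integer — e.g. a ~9.4 nm bundle of ~2 nm dimers holds
round(4.7^2) = 22 dimers.

The assay-side helpers mirror the standard quantification formulas:
Welch's unequal-variance t-test, corrected total cell fluorescence
(CTCF), stressed/unstressed survival normalization, metabolic rate per
live cell, and squared Pearson correlation with its p-value.  Error
bars are offered both as SD and as mean absolute deviation ("average
deviation"), which differ and are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from gelkit.io import ValidationError


@dataclass(frozen=True)
class FiberGeometry:
    """Necklace-bundle geometry: diameters (nm) and the implied dimer count."""

    bundle_diameter: float
    dimer_diameter: float
    dimer_count: int

    def __post_init__(self):
        if self.bundle_diameter <= 0 or self.dimer_diameter <= 0:
            raise ValidationError("diameters must be positive")


def necklace_dimer_count(bundle_d: float, dimer_d: float, packing: str = "area") -> int:
    """Dimers per bundle cross-section from the diameter ratio.

    ``packing='area'`` (default) is the plain area ratio
    round((bundle_d/dimer_d)^2); ``packing='hexagonal'`` multiplies by
    the hexagonal packing fraction pi/(2*sqrt(3)) ~ 0.9069 before
    rounding.
    """
    if bundle_d <= 0 or dimer_d <= 0:
        raise ValidationError("diameters must be positive")
    if dimer_d > bundle_d:
        raise ValidationError("dimer diameter exceeds bundle diameter")
    ratio = (bundle_d / dimer_d) ** 2
    if packing == "hexagonal":
        ratio *= np.pi / (2.0 * np.sqrt(3.0))
    elif packing != "area":
        raise ValueError(f"unknown packing {packing!r}")
    return int(round(ratio))


def necklace_geometry(bundle_d: float, dimer_d: float) -> FiberGeometry:
    return FiberGeometry(
        bundle_diameter=bundle_d,
        dimer_diameter=dimer_d,
        dimer_count=necklace_dimer_count(bundle_d, dimer_d),
    )


def welch_t(sample_a, sample_b):
    """Welch's unequal-variance t-test with Satterthwaite df; two-sided p.

    Returns (t, df, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValidationError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def paired_t(sample_a, sample_b):
    """Paired two-sided t-test (for matched before/after assay designs)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValidationError("paired samples must have equal length >= 2")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(a.size - 1), float(res.pvalue)


def ctcf(integrated_density: float, area: float, mean_background: float) -> float:
    """Corrected total cell fluorescence: integrated density - area * background."""
    if area < 0:
        raise ValidationError("area must be non-negative")
    return float(integrated_density) - float(area) * float(mean_background)


def average_deviation(x) -> float:
    """Mean absolute deviation from the mean (the 'average deviation' error bar)."""
    x = np.asarray(x, dtype=float)
    return float(np.mean(np.abs(x - x.mean())))


def survival_normalize(stressed_counts, unstressed_counts):
    """Per-replicate survival fractions: stressed / unstressed.

    Returns a dict with the per-replicate fractions, their mean, and
    both error bars (average deviation and SD).
    """
    s = np.atleast_1d(np.asarray(stressed_counts, dtype=float))
    u = np.atleast_1d(np.asarray(unstressed_counts, dtype=float))
    if s.shape != u.shape:
        raise ValidationError("stressed and unstressed counts must align")
    if np.any(u <= 0):
        raise ValidationError("unstressed counts must be positive")
    frac = s / u
    return {
        "fractions": frac,
        "mean": float(frac.mean()),
        "avg_dev": average_deviation(frac),
        "sd": float(frac.std(ddof=1)) if frac.size > 1 else 0.0,
    }


def metabolic_per_live_cell(
    metabolic_signal_ratio: float, survival_fraction: float, control_ratio: float | None = None
) -> float:
    """Metabolic rate per live cell: metabolic ratio / survival fraction.

    Optionally further normalized to the same quantity for a control
    line; chaining the two divisions equals the combined ratio.
    """
    if survival_fraction <= 0:
        raise ValidationError("survival fraction must be positive")
    rate = float(metabolic_signal_ratio) / float(survival_fraction)
    if control_ratio is not None:
        if control_ratio <= 0:
            raise ValidationError("control ratio must be positive")
        rate /= float(control_ratio)
    return rate


def pearson_r2(x, y):
    """Squared Pearson correlation and its two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)


def width_summary(widths, other_widths=None):
    """Mean +/- SD of fiber widths (nm), with a Welch comparison if a
    second set is supplied.

    Returns a dict: mean, sd, n, and (when comparing) welch_t, welch_df,
    welch_p.
    """
    w = np.asarray(widths, dtype=float)
    if w.size < 2:
        raise ValidationError("need at least 2 widths")
    out = {"mean": float(w.mean()), "sd": float(w.std(ddof=1)), "n": int(w.size)}
    if other_widths is not None:
        t, df, p = welch_t(w, other_widths)
        out.update({"welch_t": t, "welch_df": df, "welch_p": p})
    return out
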
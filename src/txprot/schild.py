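"""Isothermal dose-response analysis: 4PL fits, Schild regression, Ki.

Each antagonist concentration gets its own four-parameter logistic fit;
EC50 shifts relative to the antagonist-free control give dose ratios
DR = A'/A, and the regression of log10(DR - 1) on log10[B] yields the
pA2 (its zero crossing) and Ki = 10^(-pA2).  Confidence intervals come
from a replicate-level percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ValidationError
from .simdata import CetsaDataset

__all__ = [
    "DoseResponseFit",
    "SchildFit",
    "FitError",
    "fit_4pl",
    "dose_ratios",
    "schild_regression",
    "bootstrap_ki",
    "analyze_cetsa",
]


class FitError(RuntimeError):
    """Raised when a curve fit fails to converge; carries the best iterate."""

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best


@dataclass
class DoseResponseFit:
    """Fitted 4PL curve for one antagonist concentration."""

    top: float
    bottom: float
    log10_ec50: float
    hill: float
    rss: float
    n_points: int
    antagonist_conc: float
    ec50_in_range: bool = True

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ValidationError("top must exceed bottom")

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log10_ec50

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** ((self.log10_ec50 - np.log10(dose)) * self.hill)
        )


@dataclass
class SchildFit:
    """Schild regression line and derived affinity estimates."""

    points: pd.DataFrame  # log10_b, log10_dr_minus_1 for DR > 1 rows
    n_used: int
    n_excluded: int
    slope: float
    intercept: float
    x_intercept: float
    pa2: float
    ki: float  # molar
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ValidationError("ki must be > 0")
        if not math.isclose(self.pa2, -math.log10(self.ki), rel_tol=1e-9):
            raise ValidationError("pA2 must equal -log10(Ki)")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValidationError("ci_low must be <= ci_high")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pa2": self.pa2,
            "ki_molar": self.ki,
            "ci_low_molar": self.ci_low,
            "ci_high_molar": self.ci_high,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _4pl_model(log10_dose, log10_ec50, top, bottom, hill):
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((log10_ec50 - log10_dose) * hill)
    )


def fit_4pl(
    doses,
    signals,
    antagonist_conc: float = 0.0,
    fixed_top: float | None = None,
    fixed_bottom: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of signal vs agonist dose (molar).

    Initialization takes top/bottom from the signal extremes and the
    EC50 from the dose whose mean signal is closest to the midpoint.
    ``fixed_top`` / ``fixed_bottom`` pin the respective asymptote.
    The EC50 is flagged (``ec50_in_range=False``) when it falls outside
    the tested dose range scaled by [0.01, 100].
    """
    doses = np.asarray(doses, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if doses.shape != signals.shape:
        raise ValidationError("doses and signals must align")
    if (doses <= 0).any():
        raise ValidationError("doses must be > 0")
    if np.unique(doses).size < 4:
        raise ValidationError(
            f"need >= 4 distinct doses, got {np.unique(doses).size}"
        )
    logd = np.log10(doses)

    top0 = signals.max() if fixed_top is None else fixed_top
    bot0 = signals.min() if fixed_bottom is None else fixed_bottom
    # dose whose mean response is closest to the half-maximal signal
    mid = (top0 + bot0) / 2.0
    uniq = np.unique(logd)
    mean_at = np.array([signals[logd == d].mean() for d in uniq])
    ec0 = uniq[np.argmin(np.abs(mean_at - mid))]

    if fixed_top is None and fixed_bottom is None:
        def model(x, le, t, b, h):
            return _4pl_model(x, le, t, b, h)
        p0 = [ec0, top0, bot0, 1.0]
    elif fixed_top is not None and fixed_bottom is None:
        def model(x, le, b, h):
            return _4pl_model(x, le, fixed_top, b, h)
        p0 = [ec0, bot0, 1.0]
    elif fixed_top is None and fixed_bottom is not None:
        def model(x, le, t, h):
            return _4pl_model(x, le, t, fixed_bottom, h)
        p0 = [ec0, top0, 1.0]
    else:
        def model(x, le, h):
            return _4pl_model(x, le, fixed_top, fixed_bottom, h)
        p0 = [ec0, 1.0]

    try:
        popt, _ = curve_fit(model, logd, signals, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}",
                       best={"p0": p0}) from exc

    if fixed_top is None and fixed_bottom is None:
        le, top, bottom, hill = popt
    elif fixed_top is not None and fixed_bottom is None:
        le, bottom, hill = popt
        top = fixed_top
    elif fixed_top is None and fixed_bottom is not None:
        le, top, hill = popt
        bottom = fixed_bottom
    else:
        le, hill = popt
        top, bottom = fixed_top, fixed_bottom
    if hill < 0:  # sign-flip degeneracy: refold onto positive hill
        hill = -hill
        top, bottom = bottom, top
    rss = float(((signals - _4pl_model(logd, le, top, bottom, hill)) ** 2)
                .sum())
    in_range = (
        logd.min() + math.log10(0.01) <= le <= logd.max() + math.log10(100)
    )
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        log10_ec50=float(le),
        hill=float(hill),
        rss=rss,
        n_points=int(doses.size),
        antagonist_conc=float(antagonist_conc),
        ec50_in_range=bool(in_range),
    )


def dose_ratios(fits: list[DoseResponseFit]) -> pd.DataFrame:
    """EC50 dose ratios DR = A'/A against the antagonist-free control.

    Returns one row per nonzero antagonist concentration with columns
    ``antagonist_conc``, ``ec50``, ``dr``.
    """
    controls = [f for f in fits if f.antagonist_conc == 0.0]
    if not controls:
        raise ValidationError("no control curve (antagonist_conc = 0)")
    a = controls[0].ec50
    rows = [
        {"antagonist_conc": f.antagonist_conc, "ec50": f.ec50,
         "dr": f.ec50 / a}
        for f in fits
        if f.antagonist_conc > 0
    ]
    return pd.DataFrame(rows).sort_values("antagonist_conc",
                                          ignore_index=True)


def schild_regression(table: pd.DataFrame, n_boot: int = 0,
                      seed: int | None = None) -> SchildFit:
    """OLS of log10(DR - 1) on log10[B] over rows with DR > 1.

    The x-intercept gives pA2 = -x_intercept and Ki = 10^x_intercept.
    Rows with DR <= 1 are excluded (log undefined); a non-positive
    slope is rejected as a non-competitive pattern.
    """
    usable = table[table["dr"] > 1.0]
    n_excluded = len(table) - len(usable)
    if len(usable) < 2:
        raise ValidationError(
            f"need >= 2 rows with DR > 1 (got {len(usable)})"
        )
    x = np.log10(usable["antagonist_conc"].to_numpy(dtype=float))
    y = np.log10(usable["dr"].to_numpy(dtype=float) - 1.0)
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValidationError("antagonist concentrations are all equal")
    slope = ((x - xbar) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * xbar
    if slope <= 0:
        raise ValidationError(
            f"non-positive Schild slope ({slope:.3g}): not a competitive "
            f"pattern"
        )
    x_int = -intercept / slope
    pa2 = -x_int
    ki = 10.0 ** x_int
    points = pd.DataFrame({"log10_b": x, "log10_dr_minus_1": y})
    return SchildFit(
        points=points,
        n_used=len(usable),
        n_excluded=n_excluded,
        slope=float(slope),
        intercept=float(intercept),
        x_intercept=float(x_int),
        pa2=float(pa2),
        ki=float(ki),
        n_boot=n_boot,
        seed=seed,
    )


def _fit_all_curves(table: pd.DataFrame) -> list[DoseResponseFit]:
    fits = []
    for b, sub in table.groupby("antagonist_conc"):
        fits.append(
            fit_4pl(
                sub["agonist_dose"].to_numpy(),
                sub["signal"].to_numpy(),
                antagonist_conc=float(b),
            )
        )
    return fits


def _ki_from_table(table: pd.DataFrame) -> float:
    fits = _fit_all_curves(table)
    return schild_regression(dose_ratios(fits)).ki


def bootstrap_ki(
    data: CetsaDataset,
    n_boot: int = 1000,
    seed: int = 0,
    max_fail_fraction: float = 0.2,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for Ki.

    Replicate signals are resampled with replacement within each
    (agonist dose, antagonist concentration) cell; the full
    fit -> dose-ratio -> Schild pipeline is rerun per resample and the
    2.5/97.5 percentiles of the Ki distribution are returned together
    with the number of failed refits (each dropped; more than
    ``max_fail_fraction`` failing is an error).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1 (use analyze_cetsa with "
                              "n_boot=0 for a point estimate only)")
    rng = np.random.default_rng(seed)
    table = data.table
    cells = [sub.index.to_numpy() for _, sub in
             table.groupby(["antagonist_conc", "agonist_dose"])]
    kis = []
    n_failed = 0
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(c, size=c.size, replace=True) for c in cells]
        )
        resampled = table.loc[idx]
        try:
            kis.append(_ki_from_table(resampled))
        except (FitError, ValidationError):
            n_failed += 1
    if n_failed > max_fail_fraction * n_boot:
        raise FitError(
            f"{n_failed}/{n_boot} bootstrap refits failed"
        )
    lo, hi = np.percentile(kis, [2.5, 97.5])
    return float(lo), float(hi), n_failed


def analyze_cetsa(
    data: CetsaDataset,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[list[DoseResponseFit], SchildFit]:
    """Full pipeline: per-curve 4PL fits, dose ratios, Schild fit, CI.

    With ``n_boot = 0`` only the point estimate is produced.
    """
    if 0.0 not in data.table["antagonist_conc"].to_numpy():
        raise ValidationError(
            "dataset lacks an antagonist_conc = 0 control curve"
        )
    fits = _fit_all_curves(data.table)
    schild = schild_regression(dose_ratios(fits), n_boot=n_boot, seed=seed)
    if n_boot > 0:
        lo, hi, _ = bootstrap_ki(data, n_boot=n_boot, seed=seed)
        schild.ci_low, schild.ci_high = lo, hi
    return fits, schild
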
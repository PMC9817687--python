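"""Moderated differential-abundance testing.

Per-feature group-means linear models with pooled residual variances,
an empirical-Bayes prior fitted by moment matching on log-variances
(digamma/trigamma inversion), moderated t-statistics with augmented
degrees of freedom, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import Contrast, ExpressionMatrix, SampleDesign, ValidationError

__all__ = [
    "EbayesPrior",
    "fit_gene_models",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "run_differential",
]


@dataclass
class EbayesPrior:
    """Prior degrees of freedom and variance for variance shrinkage.

    ``d0`` may be ``inf`` (complete shrinkage: every posterior variance
    equals ``s0_sq``); ``d0 = 0`` is accepted as the no-shrinkage limit
    in which the moderated t reduces to the classical pooled t.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValidationError("s0_sq must be > 0")


def fit_gene_models(
    mat: ExpressionMatrix, design: SampleDesign, contrast: Contrast
) -> pd.DataFrame:
    """Fit the two-group model per feature for one contrast.

    Returns a DataFrame indexed by feature with columns ``coef``
    (difference of group means, a vs b), ``stdev_unscaled``
    (sqrt(1/n1 + 1/n2)), ``s2`` (pooled within-group variance), ``df``
    (n1 + n2 - 2) and ``avg_abund`` (mean over both groups).
    """
    assay = None
    for a in ("rna", "protein"):
        if set(design.samples(assay=a)) & set(mat.sample_ids):
            assay = a
            break
    cols_a = [
        s
        for s in design.samples(
            assay=assay, condition=contrast.condition_a,
            timepoint=contrast.timepoint,
        )
        if s in mat.values.columns
    ]
    cols_b = [
        s
        for s in design.samples(
            assay=assay, condition=contrast.condition_b,
            timepoint=contrast.timepoint,
        )
        if s in mat.values.columns
    ]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"contrast {contrast.name}: both groups need >= 2 replicates "
            f"(got {len(cols_a)} and {len(cols_b)})"
        )
    a = mat.values[cols_a].to_numpy(dtype=float)
    b = mat.values[cols_b].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("matrix must be complete (impute first)")
    n1, n2 = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    rss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return pd.DataFrame(
        {
            "coef": mean_a - mean_b,
            "stdev_unscaled": np.sqrt(1.0 / n1 + 1.0 / n2),
            "s2": rss / df,
            "df": float(df),
            "avg_abund": np.concatenate([a, b], axis=1).mean(axis=1),
        },
        index=mat.feature_ids,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2, df) -> EbayesPrior:
    """Moment-match the scaled-F prior for residual variances.

    With e_g = log(s2_g) - digamma(df_g/2) + log(df_g/2), the prior
    degrees of freedom solve trigamma(d0/2) = var(e) - mean(trigamma
    (df/2)) and s0^2 follows from the mean of e.  When the empirical
    variance does not exceed the sampling term, d0 = inf and
    s0^2 = mean(s2).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise ValidationError(
            f"need >= 10 finite variances to fit the prior (got {s2.size})"
        )
    if (s2 < 0).any():
        raise ValidationError("variances must be >= 0")
    if (s2 == 0).any():
        # log-variance offset: clamp exact zeros to half the smallest
        # positive variance so they stay in the moment fit
        positive = s2[s2 > 0]
        if positive.size == 0:
            raise ValidationError("all variances are zero")
        s2 = np.where(s2 == 0, positive.min() / 2.0, s2)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return EbayesPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(coef, stdev_unscaled, s2, df, prior: EbayesPrior):
    """Shrink variances toward the prior and compute moderated t / p.

    s2_post = (d0*s0^2 + df*s2) / (d0 + df); t = coef / (stdev_unscaled
    * sqrt(s2_post)); two-sided p from t with df + d0 degrees of freedom
    (normal when d0 is infinite).  Returns (t, p, df_total) arrays.
    """
    coef = np.asarray(coef, dtype=float)
    stdev_unscaled = np.asarray(stdev_unscaled, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (stdev_unscaled * np.sqrt(s2_post))
    t = np.where(np.isnan(t) & (coef == 0), 0.0, t)
    if np.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, df_total


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, tie-safe)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_differential(
    mat: ExpressionMatrix,
    design: SampleDesign,
    contrasts: list[Contrast],
) -> dict[str, pd.DataFrame]:
    """Fit, moderate and adjust one DiffTable per contrast.

    Each table is indexed by feature with columns ``log2fc``,
    ``avg_abund``, ``s2``, ``df``, ``t``, ``p``, ``fdr``.  The prior is
    fitted per contrast from that contrast's residual variances.
    """
    out: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        fit = fit_gene_models(mat, design, contrast)
        prior = estimate_prior(fit["s2"], fit["df"])
        t, p, df_total = moderated_t(
            fit["coef"], fit["stdev_unscaled"], fit["s2"], fit["df"], prior
        )
        out[contrast.name] = pd.DataFrame(
            {
                "log2fc": fit["coef"],
                "avg_abund": fit["avg_abund"],
                "s2": fit["s2"],
                "df": fit["df"],
                "t": t,
                "p": p,
                "fdr": bh_adjust(p),
            },
            index=fit.index,
        )
    return out
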
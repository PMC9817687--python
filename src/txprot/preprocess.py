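"""Filters, transforms and imputation applied before differential testing.

RNA side: TPM conversion and the "expressed gene" filter (>= 1 TPM in
>= 3 samples).  Protein side: the complete-in-one-group detection
filter, left-censored imputation from the low tail of each sample,
median centering, in-silico tryptic peptide counting and the iBAQ
transform.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneLengths, SampleDesign, ValidationError

__all__ = [
    "counts_to_tpm",
    "filter_expressed_genes",
    "filter_detected_proteins",
    "impute_missing",
    "median_normalize",
    "count_theoretical_peptides",
    "ibaq_transform",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def counts_to_tpm(counts: ExpressionMatrix, lengths: GeneLengths
                  ) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    TPM_g = (count_g / length_kb_g) / sum_h(count_h / length_kb_h) * 1e6,
    per sample.  A sample with zero total rate yields an all-zero column
    and a warning.
    """
    if counts.layer != "counts":
        raise ValidationError(f"expected counts layer, got {counts.layer!r}")
    length_kb = lengths.for_features(counts.feature_ids) / 1000.0
    rate = counts.values.to_numpy(dtype=float) / length_kb[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        warnings.warn(f"samples with zero total counts: {bad}")
        totals = np.where(zero, 1.0, totals)
    tpm = rate / totals[None, :] * 1e6
    tpm[:, zero] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.feature_ids, columns=counts.sample_ids),
        layer="tpm",
    )


def filter_expressed_genes(
    tpm: ExpressionMatrix, min_tpm: float = 1.0, min_samples: int = 3
) -> list[str]:
    """Keep genes with TPM >= min_tpm in >= min_samples samples (inclusive)."""
    if tpm.layer != "tpm":
        raise ValidationError(f"expected tpm layer, got {tpm.layer!r}")
    n_samples = len(tpm.sample_ids)
    if min_samples > n_samples:
        raise ValidationError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    hits = (tpm.values.to_numpy(dtype=float) >= min_tpm).sum(axis=1)
    keep = hits >= min_samples
    return [f for f, k in zip(tpm.feature_ids, keep) if k]


def filter_detected_proteins(
    prot: ExpressionMatrix, design: SampleDesign
) -> list[str]:
    """Keep proteins observed in all replicates of >= 1 (condition, timepoint).

    The grouping unit is the (condition x timepoint) cell, i.e. each
    timepoint is treated as a separate condition.
    """
    if prot.layer not in ("log2_intensity", "intensity", "ibaq"):
        raise ValidationError(f"expected protein layer, got {prot.layer!r}")
    design.check_covers(prot.sample_ids)
    observed = ~prot.values.isna()
    keep = np.zeros(len(prot.feature_ids), dtype=bool)
    for _, samples in design.groups("protein"):
        cols = [s for s in samples if s in observed.columns]
        if not cols:
            continue
        keep |= observed[cols].all(axis=1).to_numpy()
    return [f for f, k in zip(prot.feature_ids, keep) if k]


def impute_missing(
    prot: ExpressionMatrix,
    lower_fraction: float = 0.10,
    rng: np.random.Generator | int | None = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Replace missing cells with draws from each sample's low-abundance tail.

    Per sample, missing values are drawn from Normal(mu_s, sigma_s)
    where mu_s and sigma_s are the mean and standard deviation of that
    sample's observed values at or below its ``lower_fraction`` quantile.
    Returns the completed matrix and a boolean mask of imputed cells.
    """
    if prot.layer != "log2_intensity":
        raise ValidationError(
            f"imputation expects log2_intensity layer, got {prot.layer!r}"
        )
    if not 0.0 < lower_fraction <= 1.0:
        raise ValidationError("lower_fraction must lie in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = prot.values.copy()
    mask = prot.values.isna()
    for s in values.columns:
        col = values[s]
        observed = col.dropna().to_numpy()
        if observed.size < 20:
            raise ValidationError(
                f"sample {s!r} has only {observed.size} observed values; "
                f">= 20 required to estimate the imputation distribution"
            )
        cutoff = np.quantile(observed, lower_fraction)
        tail = observed[observed <= cutoff]
        if tail.size < 2:
            raise ValidationError(
                f"sample {s!r}: lower-tail pool too small to estimate sigma"
            )
        mu, sigma = float(tail.mean()), float(tail.std(ddof=1))
        miss = mask[s].to_numpy()
        if miss.any():
            values.loc[miss, s] = rng.normal(mu, sigma, int(miss.sum()))
    return ExpressionMatrix(values, layer=prot.layer), mask


def median_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Center sample medians on the across-sample median.

    Medians are computed over the features observed in every sample, so
    partially missing matrices are centered on a shared feature set;
    missing cells are left untouched.
    """
    if mat.layer not in ("log2_intensity", "log2_tpm"):
        raise ValidationError(f"expected a log2 layer, got {mat.layer!r}")
    complete = mat.values.dropna(axis=0)
    if complete.empty:
        raise ValidationError("no feature observed in all samples")
    medians = complete.median(axis=0)
    target = float(medians.median())
    shifted = mat.values + (target - medians)
    return ExpressionMatrix(shifted, layer=mat.layer)


def count_theoretical_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Count theoretically observable tryptic peptides of a protein.

    In-silico digest: cleave after K or R unless the next residue is P,
    zero missed cleavages; count fragments with length in
    [min_len, max_len] inclusive.
    """
    if not sequence:
        raise ValidationError("empty protein sequence")
    seq = sequence.upper()
    unknown = set(seq) - STANDARD_AA
    if unknown:
        raise ValidationError(f"unknown residues: {sorted(unknown)}")
    fragments = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            fragments.append(seq[start:i + 1])
            start = i + 1
    if start < len(seq):
        fragments.append(seq[start:])
    return sum(1 for f in fragments if min_len <= len(f) <= max_len)


def ibaq_transform(
    intensities: ExpressionMatrix, peptide_counts: dict[str, int]
) -> ExpressionMatrix:
    """Divide raw intensities by theoretical peptide counts (iBAQ).

    Features with a zero peptide count are dropped with a warning;
    features without a count raise.
    """
    if intensities.layer != "intensity":
        raise ValidationError(
            f"iBAQ expects raw intensity layer, got {intensities.layer!r}"
        )
    missing = [f for f in intensities.feature_ids if f not in peptide_counts]
    if missing:
        raise ValidationError(f"peptide counts missing for: {missing[:5]}")
    counts = pd.Series(
        {f: peptide_counts[f] for f in intensities.feature_ids}, dtype=float
    )
    zero = counts[counts == 0].index.tolist()
    if zero:
        warnings.warn(f"dropping features with zero peptide count: {zero[:5]}")
    keep = counts[counts > 0].index
    ibaq = intensities.values.loc[keep].div(counts.loc[keep], axis=0)
    return ExpressionMatrix(ibaq, layer="ibaq")
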
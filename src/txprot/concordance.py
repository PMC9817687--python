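"""RNA-protein fold-change concordance and global diagnostics.

Pairs per-gene log2 fold changes across the two assays, fits the
ordinary-least-squares line with protein as response, flags discordant
genes via internally studentized residuals, and provides the
abundance-correlation, detection-overlap and PCA summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "ConcordanceFit",
    "OverlapSummary",
    "PcaResult",
    "pair_fold_changes",
    "fit_concordance",
    "studentized_residuals",
    "call_discordant",
    "abundance_correlation",
    "detection_overlap",
    "run_pca",
]


@dataclass
class ConcordanceFit:
    """OLS fit of protein log2FC on RNA log2FC with outlier diagnostics.

    ``table`` holds per-feature columns rna_lfc, prot_lfc, leverage,
    residual (raw), studentized (leverage-corrected), outlier.
    """

    table: pd.DataFrame
    slope: float
    intercept: float
    pearson_r: float
    n: int
    sigma: float  # residual scale, sqrt(RSS / (n - 2))
    threshold: float = 3.0

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValidationError("|pearson_r| must be <= 1")

    @property
    def outliers(self) -> list[str]:
        return list(self.table.index[self.table["outlier"]])

    def summary(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "sigma": self.sigma,
            "threshold": self.threshold,
            "n_outliers": int(self.table["outlier"].sum()),
        }


@dataclass
class OverlapSummary:
    n_rna_only: int
    n_protein_only: int
    n_both: int

    @property
    def fraction_genes_with_protein(self) -> float:
        total_genes = self.n_rna_only + self.n_both
        return self.n_both / total_genes if total_genes else 0.0


@dataclass
class PcaResult:
    """Sample scores, feature loadings and per-component variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def pair_fold_changes(
    rna: pd.DataFrame, prot: pd.DataFrame, id_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Inner-join RNA and protein DiffTables on (mapped) gene id.

    ``id_map`` maps protein ids to gene ids; identity by default.
    Timepoint correspondence (early RNA with early protein sampling,
    late with late) is the caller's responsibility via the contrast
    tables passed in.
    """
    prot_ids = prot.index
    if id_map is not None:
        mapped = prot_ids.map(lambda p: id_map.get(p, p))
        prot = prot.set_axis(mapped)
        if prot.index.duplicated().any():
            raise ValidationError("id_map maps several proteins to one gene")
    shared = rna.index.intersection(prot.index)
    if len(shared) == 0:
        raise ValidationError("no shared features between RNA and protein")
    return pd.DataFrame(
        {
            "rna_lfc": rna.loc[shared, "log2fc"],
            "prot_lfc": prot.loc[shared, "log2fc"],
        },
        index=shared,
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValidationError("zero variance in the RNA fold changes")
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    return float(slope), float(ybar - slope * xbar)


def fit_concordance(pairs: pd.DataFrame, threshold: float = 3.0
                    ) -> ConcordanceFit:
    """OLS of protein log2FC on RNA log2FC with studentized residuals."""
    if len(pairs) < 10:
        raise ValidationError(f"need >= 10 pairs, got {len(pairs)}")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    x = pairs["rna_lfc"].to_numpy(dtype=float)
    y = pairs["prot_lfc"].to_numpy(dtype=float)
    slope, intercept = _ols_line(x, y)
    fitted = intercept + slope * x
    resid = y - fitted
    n = x.size
    rss = float((resid ** 2).sum())
    sigma = np.sqrt(rss / (n - 2))
    sxx = ((x - x.mean()) ** 2).sum()
    leverage = 1.0 / n + (x - x.mean()) ** 2 / sxx
    # an (numerically) exact fit has no residual scale: all residuals zero
    if sigma <= 1e-12 * max(1.0, float(np.abs(y).max())):
        student = np.zeros_like(resid)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            student = resid / (sigma * np.sqrt(1.0 - leverage))
        student = np.where(np.isfinite(student), student, 0.0)
    sy = y.std()
    r = 0.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1])
    table = pd.DataFrame(
        {
            "rna_lfc": x,
            "prot_lfc": y,
            "leverage": leverage,
            "residual": resid,
            "studentized": student,
            "outlier": np.abs(student) > threshold,
        },
        index=pairs.index,
    )
    return ConcordanceFit(
        table=table,
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        n=n,
        sigma=float(sigma),
        threshold=threshold,
    )


def studentized_residuals(fit: ConcordanceFit) -> np.ndarray:
    """Internally studentized residuals r_i = e_i / (sigma*sqrt(1 - h_ii))."""
    if fit.n <= 2:
        raise ValidationError("need more than 2 points")
    return fit.table["studentized"].to_numpy(dtype=float)


def call_discordant(fit: ConcordanceFit, threshold: float = 3.0) -> list[str]:
    """Features with |studentized residual| strictly above ``threshold``."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    r = studentized_residuals(fit)
    return [f for f, ri in zip(fit.table.index, r) if abs(ri) > threshold]


def abundance_correlation(
    rna_avg: pd.Series,
    prot_avg: pd.Series,
    id_map: dict[str, str] | None = None,
) -> float:
    """Pearson R between per-gene mean RNA and protein log2 abundances."""
    if id_map is not None:
        prot_avg = prot_avg.rename(index=lambda p: id_map.get(p, p))
    shared = rna_avg.index.intersection(prot_avg.index)
    if len(shared) < 10:
        raise ValidationError(f"need >= 10 shared features, got {len(shared)}")
    x = rna_avg.loc[shared].to_numpy(dtype=float)
    y = prot_avg.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in abundance vector")
    return float(np.corrcoef(x, y)[0, 1])


def detection_overlap(gene_ids, protein_gene_ids) -> OverlapSummary:
    """Set-algebra summary of RNA-detected vs protein-detected genes."""
    genes = set(gene_ids)
    prots = set(protein_gene_ids)
    return OverlapSummary(
        n_rna_only=len(genes - prots),
        n_protein_only=len(prots - genes),
        n_both=len(genes & prots),
    )


def run_pca(
    mat: ExpressionMatrix,
    center: bool = True,
    scale: bool = False,
    n_top_features: int | None = None,
) -> PcaResult:
    """SVD-based PCA with samples as observations.

    Optionally restricts to the ``n_top_features`` highest-variance
    features first.  ``variance_explained`` covers all components and
    sums to 1.
    """
    if mat.values.isna().any().any():
        raise ValidationError("PCA requires a complete matrix (impute first)")
    values = mat.values
    if n_top_features is not None and n_top_features < len(values):
        var = values.var(axis=1)
        values = values.loc[var.nlargest(n_top_features).index]
    x = values.to_numpy(dtype=float).T  # samples x features
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var_exp = s ** 2 / (s ** 2).sum()
    comp = [f"PC{i + 1}" for i in range(s.size)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=mat.sample_ids, columns=comp),
        loadings=pd.DataFrame(vt.T, index=values.index, columns=comp),
        variance_explained=var_exp,
    )
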
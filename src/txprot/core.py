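"""Core data containers shared by every pipeline stage.

Matrices are features x samples pandas DataFrames wrapped in a thin,
validated :class:`ExpressionMatrix`; sample metadata lives in
:class:`SampleDesign`.  Missing protein measurements are encoded as NaN
and are only legal on protein layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("vehicle", "agonist", "agonist_antagonist")
TIMEPOINTS = ("early", "late")
ASSAYS = ("rna", "protein")

#: layers that may carry a missingness mask (NaN cells)
PROTEIN_LAYERS = ("intensity", "log2_intensity", "ibaq")
RNA_LAYERS = ("counts", "tpm", "log2_tpm")
LAYERS = RNA_LAYERS + PROTEIN_LAYERS


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class ExpressionMatrix:
    """Features x samples abundance matrix for a single assay layer.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    layer
        One of ``counts``, ``tpm``, ``log2_tpm`` (RNA) or ``intensity``,
        ``log2_intensity``, ``ibaq`` (protein).  NaN cells are only
        permitted on protein layers, where they mean "not detected".
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicated feature ids: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicated sample ids")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any() and self.layer not in PROTEIN_LAYERS:
            raise ValidationError(
                f"missing values are not allowed on layer {self.layer!r}"
            )
        if self.layer == "counts":
            finite = arr[np.isfinite(arr)]
            if (finite < 0).any():
                raise ValidationError("counts must be nonnegative")
        if self.layer == "tpm":
            if (arr < 0).any():
                raise ValidationError("TPM values must be nonnegative")

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_features(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)].copy(), self.layer)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(ids)].copy(), self.layer)


@dataclass
class SampleDesign:
    """Sample -> (condition, timepoint, replicate, assay) mapping.

    The table defines which columns of an :class:`ExpressionMatrix`
    belong to which experimental group and therefore which contrasts can
    be formed.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "timepoint", "replicate", "assay")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table lacks columns {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("sample ids must be unique")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions {sorted(bad)}")
        bad = set(self.table["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise ValidationError(f"unknown timepoints {sorted(bad)}")
        bad = set(self.table["assay"]) - set(ASSAYS)
        if bad:
            raise ValidationError(f"unknown assays {sorted(bad)}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive")
        sizes = self.table.groupby(
            ["condition", "timepoint", "assay"], observed=True
        ).size()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValidationError(
                f"every (condition, timepoint, assay) cell needs >= 2 "
                f"replicates; offending cells: {small}"
            )

    def samples(self, assay=None, condition=None, timepoint=None) -> list[str]:
        t = self.table
        if assay is not None:
            t = t[t["assay"] == assay]
        if condition is not None:
            t = t[t["condition"] == condition]
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return list(t["sample_id"])

    def groups(self, assay: str):
        """Yield ((condition, timepoint), sample id list) for one assay."""
        t = self.table[self.table["assay"] == assay]
        for key, sub in t.groupby(["condition", "timepoint"], observed=True):
            yield key, list(sub["sample_id"])

    def check_covers(self, sample_ids) -> None:
        known = set(self.table["sample_id"])
        orphans = [s for s in sample_ids if s not in known]
        if orphans:
            raise ValidationError(
                f"samples absent from the design table: {orphans[:5]}"
            )


@dataclass
class Contrast:
    """A two-group comparison at one timepoint: log2FC = mean(a) - mean(b)."""

    condition_a: str
    condition_b: str
    timepoint: str

    def __post_init__(self) -> None:
        for c in (self.condition_a, self.condition_b):
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.condition_a == self.condition_b:
            raise ValidationError("contrast conditions must differ")

    @property
    def name(self) -> str:
        return f"{self.condition_a}_vs_{self.condition_b}_{self.timepoint}"


#: the contrasts used throughout: antagonist effect, agonist effect, net
def default_contrasts() -> list[Contrast]:
    out = []
    for tp in TIMEPOINTS:
        out.append(Contrast("agonist", "vehicle", tp))
        out.append(Contrast("agonist_antagonist", "agonist", tp))
        out.append(Contrast("agonist_antagonist", "vehicle", tp))
    return out


@dataclass
class GeneLengths:
    """Feature id -> transcript length in bases (> 0)."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be positive")

    def for_features(self, feature_ids) -> np.ndarray:
        missing = [f for f in feature_ids if f not in self.lengths.index]
        if missing:
            raise ValidationError(
                f"lengths missing for features: {missing[:5]}"
            )
        return self.lengths.loc[list(feature_ids)].to_numpy(dtype=float)
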